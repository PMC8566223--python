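"""Reading, writing and summarising team submissions.

A team submission mirrors the community reporting template: the applied
search settings (SS1-SS13), the N- and O-glycan search spaces, and the list
of reported glycopeptide-to-spectrum matches (glycoPSMs).  On disk a report
is either a directory of CSV/TSV files::

    settings.csv         key,value pairs (team metadata + SS1-SS13)
    n_search_space.csv   one column: composition
    o_search_space.csv   one column: composition
    psms.csv             one row per glycoPSM (header contract below)

or a single XLSX workbook with sheets of the same names.  The PSM header
contract: required columns ``spectrum_id, file_id, frag_mode, analyte,
peptide, protein, composition, charge``; recognised optional columns
``mz_observed, retention_time, glycopeptide_mass, mass_error,
monoiso_correction, adduct, site_info``.  Unknown extra columns are carried
as opaque payload and written back verbatim.

Malformed PSM rows (unparseable composition, invalid peptide, bad charge,
unknown fragmentation mode) are rejected row-by-row with diagnostics rather
than failing the whole report; ``site_info`` is carried but never scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .glyco_model import (
    ADDUCTS,
    GlycanComposition,
    GlycopeptideID,
    CompositionParseError,
    PeptideError,
    make_glycopeptide_id,
    parse_composition,
)

__all__ = [
    "FRAG_MODES",
    "GlycoPSM",
    "SearchSettings",
    "TeamReport",
    "SearchOutputSummary",
    "SchemaError",
    "ReportValidationError",
    "read_team_report",
    "write_team_report",
    "summarize_outputs",
    "unique_glycopeptides",
]

logger = logging.getLogger(__name__)

FRAG_MODES = ("HCD", "EThcD", "ETciD", "CID")
_FRAG_LOOKUP = {mode.lower(): mode for mode in FRAG_MODES}

_REQUIRED_PSM_COLUMNS = (
    "spectrum_id",
    "file_id",
    "frag_mode",
    "analyte",
    "peptide",
    "protein",
    "composition",
    "charge",
)
_OPTIONAL_NUMERIC_COLUMNS = (
    "mz_observed",
    "retention_time",
    "glycopeptide_mass",
    "mass_error",
    "monoiso_correction",
)
_OPTIONAL_TEXT_COLUMNS = ("adduct", "site_info")
_KNOWN_PSM_COLUMNS = _REQUIRED_PSM_COLUMNS + _OPTIONAL_NUMERIC_COLUMNS + _OPTIONAL_TEXT_COLUMNS

#: Plausibility ranges for the numeric search settings (warnings, not errors).
_SS_PLAUSIBLE = {
    "ss1_n_space_size": (23, 381),
    "ss2_o_space_size": (3, 223),
    "ss7_missed_cleavages": (0, 2),
    "ss8_varmod_types": (0, 14),
    "ss9_max_glycans_per_peptide": (1, 5),
    "ss10_max_other_varmods": (0, 5),
}
#: Valid codes for the categorical search settings (errors when violated).
_SS_CATEGORICAL = {
    "ss4_engine_type": (0, 1),  # academic=0, commercial=1
    "ss5_recalibration": (0, 1),  # no=0, yes=1
    "ss6_protease": (0, -1),  # nontryptic=0, tryptic=-1
    "ss11_precursor_tol": (0, 1, 2),  # low/medium/high
    "ss12_product_tol": (0, 1, 2),
    "ss13_fdr_db": (0, 1, 2),  # none/one/both (decoy, contaminant)
}


class SchemaError(ValueError):
    """A report file is missing a mandatory column or sheet."""


class ReportValidationError(ValueError):
    """A report violates an internal invariant (e.g. PSM mode not in frag_modes_used)."""


def _normalize_frag_mode(text: str) -> str:
    mode = _FRAG_LOOKUP.get(str(text).strip().lower())
    if mode is None:
        raise ValueError(f"unknown fragmentation mode {text!r}; expected one of {FRAG_MODES}")
    return mode


def _normalize_adduct(text: object) -> str:
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return "none"
    value = str(text).strip()
    if value == "" or value.lower() in ("none", "nan"):
        return "none"
    for label in ADDUCTS:
        if value.lower() == label.lower():
            return label
    raise ValueError(f"unknown adduct {text!r}; expected one of {ADDUCTS}")


@dataclass(frozen=True)
class GlycoPSM:
    """One reported glycopeptide-to-spectrum match."""

    team_id: str
    file_id: str
    spectrum_id: str
    frag_mode: str
    peptide: str
    protein: str
    composition: GlycanComposition
    analyte: str
    charge: int
    mz_observed: float | None = None
    retention_time: float | None = None
    glycopeptide_mass: float | None = None
    mass_error: float | None = None
    monoiso_correction: float | None = None
    adduct: str = "none"
    site_info: str = ""
    extras: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.analyte not in ("N", "O"):
            raise ValueError(f"analyte must be 'N' or 'O', got {self.analyte!r}")
        if self.retention_time is not None and self.retention_time < 0:
            raise ValueError("retention_time must be >= 0")
        if self.monoiso_correction is not None and self.monoiso_correction < 0:
            raise ValueError("monoiso_correction must be >= 0 (positive-values convention)")

    @property
    def glycopeptide_id(self) -> GlycopeptideID:
        return make_glycopeptide_id(self.peptide, self.composition, None)


@dataclass(frozen=True)
class SearchSettings:
    """Standardised search settings SS1-SS13.

    Categorical encodings: SS4 academic=0/commercial=1; SS5 no=0/yes=1;
    SS6 nontryptic=0/tryptic=-1; SS11 and SS12 low(<5 ppm)=0, medium
    (5-10 ppm)=1, high(>10 ppm)=2; SS13 no decoy/contaminant=0, only one=1,
    both=2.  SS3 is the free-text engine label and is excluded from numeric
    design matrices.
    """

    ss1_n_space_size: int
    ss2_o_space_size: int
    ss3_engine: str
    ss4_engine_type: int
    ss5_recalibration: int
    ss6_protease: int
    ss7_missed_cleavages: int
    ss8_varmod_types: int
    ss9_max_glycans_per_peptide: int
    ss10_max_other_varmods: int
    ss11_precursor_tol: int
    ss12_product_tol: int
    ss13_fdr_db: int

    def __post_init__(self) -> None:
        for name, codes in _SS_CATEGORICAL.items():
            if getattr(self, name) not in codes:
                raise ValueError(f"{name} must be one of {codes}, got {getattr(self, name)}")

    def validate(self) -> list[str]:
        """Return plausibility warnings for numeric settings outside printed ranges."""
        notes = []
        for name, (lo, hi) in _SS_PLAUSIBLE.items():
            value = getattr(self, name)
            if not lo <= value <= hi:
                notes.append(f"{name}={value} outside plausible range [{lo}, {hi}]")
        return notes

    def numeric_vector(self) -> dict[str, float]:
        """SS values as a flat numeric mapping (SS3 engine label excluded)."""
        return {
            "SS1": self.ss1_n_space_size,
            "SS2": self.ss2_o_space_size,
            "SS4": self.ss4_engine_type,
            "SS5": self.ss5_recalibration,
            "SS6": self.ss6_protease,
            "SS7": self.ss7_missed_cleavages,
            "SS8": self.ss8_varmod_types,
            "SS9": self.ss9_max_glycans_per_peptide,
            "SS10": self.ss10_max_other_varmods,
            "SS11": self.ss11_precursor_tol,
            "SS12": self.ss12_product_tol,
            "SS13": self.ss13_fdr_db,
        }


@dataclass(frozen=True)
class TeamReport:
    """A team's full submission."""

    team_id: str
    group: str  # developer | user
    frag_modes_used: frozenset[str]
    settings: SearchSettings
    n_search_space: tuple[GlycanComposition, ...]
    o_search_space: tuple[GlycanComposition, ...]
    psms: tuple[GlycoPSM, ...]
    diagnostics: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.group not in ("developer", "user"):
            raise ValueError(f"group must be 'developer' or 'user', got {self.group!r}")
        if not self.frag_modes_used:
            raise ReportValidationError("frag_modes_used must be nonempty")
        bad_modes = self.frag_modes_used - set(FRAG_MODES)
        if bad_modes:
            raise ReportValidationError(f"unknown fragmentation modes: {sorted(bad_modes)}")
        offending = {psm.frag_mode for psm in self.psms} - self.frag_modes_used
        if offending:
            raise ReportValidationError(
                f"PSMs use fragmentation modes {sorted(offending)} not declared in "
                f"frag_modes_used={sorted(self.frag_modes_used)}"
            )

    def psms_for(self, analyte: str) -> tuple[GlycoPSM, ...]:
        return tuple(psm for psm in self.psms if psm.analyte == analyte)

    def search_space(self, analyte: str) -> tuple[GlycanComposition, ...]:
        return self.n_search_space if analyte == "N" else self.o_search_space


@dataclass(frozen=True)
class SearchOutputSummary:
    """Per-team averages of the search output variables SO1-SO8 plus the
    glycoPSM count SO9, for one analyte.  Averages are computed only over
    PSMs where the field was reported; ``None`` marks an all-missing field.
    SO4 and SO6 follow the positive-values convention (absolute values)."""

    analyte: str
    so1_retention_time: float | None
    so2_mz_observed: float | None
    so3_charge: float | None
    so4_monoiso_correction: float | None
    so5_glycopeptide_mass: float | None
    so6_mass_error: float | None
    so7_peptide_length: float | None
    so8_glycan_mass: float | None
    so9_psm_count: int

    def numeric_vector(self) -> dict[str, float | None]:
        return {
            "SO1": self.so1_retention_time,
            "SO2": self.so2_mz_observed,
            "SO3": self.so3_charge,
            "SO4": self.so4_monoiso_correction,
            "SO5": self.so5_glycopeptide_mass,
            "SO6": self.so6_mass_error,
            "SO7": self.so7_peptide_length,
            "SO8": self.so8_glycan_mass,
            "SO9": self.so9_psm_count,
        }


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_psm_row(team_id: str, row: dict) -> GlycoPSM:
    composition = parse_composition(str(row["composition"]))
    frag_mode = _normalize_frag_mode(row["frag_mode"])
    adduct = _normalize_adduct(row.get("adduct"))
    peptide_id = make_glycopeptide_id(str(row["peptide"]), composition, None if adduct == "none" else adduct)
    analyte = str(row["analyte"]).strip().upper()

    def _opt_float(name: str) -> float | None:
        value = row.get(name)
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return None
        text = str(value).strip()
        if text == "" or text.lower() == "nan":
            return None
        return float(text)

    extras = tuple(
        sorted((k, str(v)) for k, v in row.items() if k not in _KNOWN_PSM_COLUMNS and v is not None and str(v) != "" and not (isinstance(v, float) and pd.isna(v)))
    )
    return GlycoPSM(
        team_id=team_id,
        file_id=str(row["file_id"]).strip(),
        spectrum_id=str(row["spectrum_id"]).strip(),
        frag_mode=frag_mode,
        peptide=peptide_id.peptide,
        protein=str(row["protein"]).strip(),
        composition=composition,
        analyte=analyte,
        charge=int(float(row["charge"])),
        mz_observed=_opt_float("mz_observed"),
        retention_time=_opt_float("retention_time"),
        glycopeptide_mass=_opt_float("glycopeptide_mass"),
        mass_error=_opt_float("mass_error"),
        monoiso_correction=_opt_float("monoiso_correction"),
        adduct=adduct,
        site_info="" if row.get("site_info") is None or (isinstance(row.get("site_info"), float) and pd.isna(row.get("site_info"))) else str(row.get("site_info")),
        extras=extras,
    )


def _read_tables(path: Path, dialect: str | None) -> dict[str, pd.DataFrame]:
    path = Path(path)
    if dialect is None:
        if path.suffix.lower() == ".xlsx":
            dialect = "xlsx"
        elif path.is_dir():
            dialect = "tsv" if (path / "psms.tsv").exists() else "csv"
        else:
            raise SchemaError(f"cannot infer report dialect from {path}")
    tables: dict[str, pd.DataFrame] = {}
    names = ("settings", "n_search_space", "o_search_space", "psms")
    if dialect == "xlsx":
        if not path.exists():
            raise SchemaError(f"report workbook {path} does not exist")
        book = pd.read_excel(path, sheet_name=None, dtype=str)
        for name in names:
            if name not in book:
                raise SchemaError(f"workbook {path} is missing sheet {name!r}")
            tables[name] = book[name]
    elif dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        ext = dialect
        for name in names:
            file = path / f"{name}.{ext}"
            if not file.exists():
                raise SchemaError(f"report bundle {path} is missing {file.name}")
            tables[name] = pd.read_csv(file, sep=sep, dtype=str)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return tables


def _settings_from_table(frame: pd.DataFrame) -> tuple[str, str, frozenset[str], SearchSettings]:
    if not {"key", "value"} <= set(frame.columns):
        raise SchemaError("settings table must have 'key' and 'value' columns")
    mapping = dict(zip(frame["key"].astype(str), frame["value"]))
    required = {"team_id", "group", "frag_modes_used"} | {
        f"ss{i}" for i in range(1, 14)
    }
    missing = required - set(mapping)
    if missing:
        raise SchemaError(f"settings table is missing keys: {sorted(missing)}")
    modes = frozenset(_normalize_frag_mode(m) for m in str(mapping["frag_modes_used"]).split(";") if m.strip())
    settings = SearchSettings(
        ss1_n_space_size=int(float(mapping["ss1"])),
        ss2_o_space_size=int(float(mapping["ss2"])),
        ss3_engine=str(mapping["ss3"]),
        ss4_engine_type=int(float(mapping["ss4"])),
        ss5_recalibration=int(float(mapping["ss5"])),
        ss6_protease=int(float(mapping["ss6"])),
        ss7_missed_cleavages=int(float(mapping["ss7"])),
        ss8_varmod_types=int(float(mapping["ss8"])),
        ss9_max_glycans_per_peptide=int(float(mapping["ss9"])),
        ss10_max_other_varmods=int(float(mapping["ss10"])),
        ss11_precursor_tol=int(float(mapping["ss11"])),
        ss12_product_tol=int(float(mapping["ss12"])),
        ss13_fdr_db=int(float(mapping["ss13"])),
    )
    return str(mapping["team_id"]), str(mapping["group"]), modes, settings


def _space_from_table(frame: pd.DataFrame, label: str) -> tuple[GlycanComposition, ...]:
    if "composition" not in frame.columns:
        raise SchemaError(f"{label} table must have a 'composition' column")
    comps = []
    for text in frame["composition"].dropna():
        comps.append(parse_composition(str(text)))
    # de-duplicate while preserving deterministic (sorted) order
    return tuple(sorted(set(comps)))


def read_team_report(path: str | Path, dialect: str | None = None) -> TeamReport:
    """Read a team report from a CSV/TSV bundle directory or XLSX workbook.

    Malformed PSM rows are rejected with row-level diagnostics (kept on
    ``TeamReport.diagnostics`` and logged); an otherwise valid report with
    zero valid PSMs is returned with an ``empty-report`` warning.
    """
    tables = _read_tables(Path(path), dialect)
    team_id, group, modes, settings = _settings_from_table(tables["settings"])
    n_space = _space_from_table(tables["n_search_space"], "n_search_space")
    o_space = _space_from_table(tables["o_search_space"], "o_search_space")

    psm_frame = tables["psms"]
    missing = set(_REQUIRED_PSM_COLUMNS) - set(psm_frame.columns)
    if missing:
        raise SchemaError(f"psms table is missing mandatory columns: {sorted(missing)}")
    psms: list[GlycoPSM] = []
    diagnostics: list[str] = []
    for index, row in enumerate(psm_frame.to_dict(orient="records")):
        try:
            psms.append(_parse_psm_row(team_id, row))
        except (CompositionParseError, PeptideError, ValueError) as exc:
            diagnostics.append(f"psms row {index}: {exc}")
    if diagnostics:
        logger.info("%s: rejected %d malformed PSM rows", team_id, len(diagnostics))
    if not psms:
        warnings.warn(f"report {team_id}: zero valid PSMs (empty report)", stacklevel=2)
    return TeamReport(
        team_id=team_id,
        group=group,
        frag_modes_used=modes,
        settings=settings,
        n_search_space=n_space,
        o_search_space=o_space,
        psms=tuple(psms),
        diagnostics=tuple(diagnostics),
    )


def _psm_to_row(psm: GlycoPSM) -> dict:
    row = {
        "spectrum_id": psm.spectrum_id,
        "file_id": psm.file_id,
        "frag_mode": psm.frag_mode,
        "analyte": psm.analyte,
        "peptide": psm.peptide,
        "protein": psm.protein,
        "composition": psm.composition.canonical(),
        "charge": psm.charge,
        "mz_observed": psm.mz_observed,
        "retention_time": psm.retention_time,
        "glycopeptide_mass": psm.glycopeptide_mass,
        "mass_error": psm.mass_error,
        "monoiso_correction": psm.monoiso_correction,
        "adduct": psm.adduct,
        "site_info": psm.site_info,
    }
    row.update(dict(psm.extras))
    return row


def write_team_report(report: TeamReport, path: str | Path, dialect: str = "csv") -> Path:
    """Write a report in the same schema ``read_team_report`` consumes."""
    path = Path(path)
    settings_rows = [
        ("team_id", report.team_id),
        ("group", report.group),
        ("frag_modes_used", ";".join(sorted(report.frag_modes_used))),
    ]
    s = report.settings
    settings_rows += [
        ("ss1", s.ss1_n_space_size),
        ("ss2", s.ss2_o_space_size),
        ("ss3", s.ss3_engine),
        ("ss4", s.ss4_engine_type),
        ("ss5", s.ss5_recalibration),
        ("ss6", s.ss6_protease),
        ("ss7", s.ss7_missed_cleavages),
        ("ss8", s.ss8_varmod_types),
        ("ss9", s.ss9_max_glycans_per_peptide),
        ("ss10", s.ss10_max_other_varmods),
        ("ss11", s.ss11_precursor_tol),
        ("ss12", s.ss12_product_tol),
        ("ss13", s.ss13_fdr_db),
    ]
    frames = {
        "settings": pd.DataFrame(settings_rows, columns=["key", "value"]),
        "n_search_space": pd.DataFrame(
            {"composition": [c.canonical() for c in report.n_search_space]}
        ),
        "o_search_space": pd.DataFrame(
            {"composition": [c.canonical() for c in report.o_search_space]}
        ),
        "psms": pd.DataFrame([_psm_to_row(p) for p in report.psms]) if report.psms else pd.DataFrame(columns=list(_KNOWN_PSM_COLUMNS)),
    }
    if dialect == "xlsx":
        path.parent.mkdir(parents=True, exist_ok=True)
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for name, frame in frames.items():
                frame.to_excel(writer, sheet_name=name, index=False)
    elif dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        path.mkdir(parents=True, exist_ok=True)
        for name, frame in frames.items():
            frame.to_csv(path / f"{name}.{dialect}", sep=sep, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# summaries


def _mean_or_none(values: Iterable[float | None]) -> float | None:
    present = [v for v in values if v is not None]
    if not present:
        return None
    return float(sum(present)) / len(present)


def summarize_outputs(report: TeamReport, analyte: str) -> SearchOutputSummary:
    """Per-team averages of the search output variables for one analyte.

    SO8 (glycan mass) is recomputed from the canonical composition with fixed
    monoisotopic residue masses rather than taken from a reported column, so
    it is comparable across heterogeneously reported submissions.
    """
    psms = report.psms_for(analyte)
    return SearchOutputSummary(
        analyte=analyte,
        so1_retention_time=_mean_or_none(p.retention_time for p in psms),
        so2_mz_observed=_mean_or_none(p.mz_observed for p in psms),
        so3_charge=_mean_or_none(float(p.charge) for p in psms),
        so4_monoiso_correction=_mean_or_none(
            None if p.monoiso_correction is None else abs(p.monoiso_correction) for p in psms
        ),
        so5_glycopeptide_mass=_mean_or_none(p.glycopeptide_mass for p in psms),
        so6_mass_error=_mean_or_none(
            None if p.mass_error is None else abs(p.mass_error) for p in psms
        ),
        so7_peptide_length=_mean_or_none(float(len(p.peptide)) for p in psms),
        so8_glycan_mass=_mean_or_none(p.composition.residue_mass for p in psms),
        so9_psm_count=len(psms),
    )


def unique_glycopeptides(report: TeamReport, analyte: str) -> frozenset[GlycopeptideID]:
    """Distinct glycopeptide identities (peptide + canonical composition) after
    adduct merging, for one analyte."""
    return frozenset(psm.glycopeptide_id for psm in report.psms_for(analyte))
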