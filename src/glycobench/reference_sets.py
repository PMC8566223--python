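"""Literature-style reference bundle consumed by the performance tests.

The bundle holds four editable CSV fixtures plus bundle-level metadata:

* ``glycan_reference_{N,O}.csv`` — expected relative abundance of glycan
  compositions on human serum glycoproteins (columns: composition, fraction);
* ``protein_weights_{N,O}.csv`` — UniProtKB accessions of serum glycoproteins
  with an integer literature-support weight (columns: accession, weight);
* ``reference_spectra.csv`` — the annotated MS/MS spectra of the spiked
  synthetic glycopeptide EVFVHPNYSK + HexNAc4Hex5NeuAc2 (columns:
  spectrum_id, file_id, frag_mode, charge, adduct);
* ``site_glycoforms.csv`` — site-specific glycoform distributions of the four
  validation glycoproteins A1AT/CP/HP/IgG1 (columns: protein, site, peptide,
  composition, actual_fraction, expected);
* ``meta.csv`` — key/value pairs (consensus thresholds per analyte).

The default bundle shipped under ``data/synthetic_serum_bundle/`` is a
constructed (synthetic) stand-in for the cited serum glycomics literature: it
reproduces the scale and shape of the published serum references
(composition-level distributions, two-tier N and three-tier O protein
weights, the 12-spectrum synthetic-glycopeptide set) without copying any
published table.  Users benchmarking real submissions against real literature
replace these CSVs; the tests are parameterised by the bundle, not hard-coded
to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .glyco_model import GlycanComposition, GlycopeptideID, make_glycopeptide_id, parse_composition

__all__ = [
    "FixtureError",
    "ReferenceGlycanDistribution",
    "ProteinWeightTable",
    "ReferenceSpectrumEntry",
    "ReferenceSpectrumSet",
    "SiteGlycoformTable",
    "ReferenceBundle",
    "load_bundle",
    "default_bundle_path",
]

_FRACTION_TOL = 1e-6  # renormalise when |sum - 1| <= tol, error beyond

#: Target of the synthetic-glycopeptide test: a tryptic peptide of human
#: vitamin-K-dependent protein C carrying a disialylated biantennary N-glycan.
SYNTHETIC_TARGET = make_glycopeptide_id("EVFVHPNYSK", parse_composition("HexNAc4Hex5NeuAc2"))


class FixtureError(ValueError):
    """A reference CSV is internally inconsistent."""


@dataclass(frozen=True)
class ReferenceGlycanDistribution:
    """Expected relative abundance of glycan compositions for one analyte."""

    analyte: str
    entries: Mapping[GlycanComposition, float]

    def fraction(self, comp: GlycanComposition) -> float:
        return self.entries.get(comp, 0.0)

    @property
    def compositions(self) -> frozenset[GlycanComposition]:
        return frozenset(self.entries)


@dataclass(frozen=True)
class ProteinWeightTable:
    """Literature-support weights of serum glycoproteins for one analyte.

    ``reference_universe_size`` is the count of unique glycoproteins in the
    reference literature, the denominator of the source-protein sensitivity.
    """

    analyte: str
    weights: Mapping[str, int]
    max_weight: int
    reference_universe_size: int

    def weight(self, accession: str) -> int:
        return self.weights.get(accession, 0)


@dataclass(frozen=True)
class ReferenceSpectrumEntry:
    spectrum_id: str
    file_id: str
    frag_mode: str
    charge: int
    adduct: str


@dataclass(frozen=True)
class ReferenceSpectrumSet:
    """Annotated spectra of the spiked synthetic glycopeptide."""

    entries: tuple[ReferenceSpectrumEntry, ...]
    target: GlycopeptideID = SYNTHETIC_TARGET

    def eligible(self, frag_modes) -> tuple[ReferenceSpectrumEntry, ...]:
        """Entries acquired with a fragmentation mode the team actually searched."""
        modes = set(frag_modes)
        return tuple(e for e in self.entries if e.frag_mode in modes)


@dataclass(frozen=True)
class SiteGlycoformTable:
    """Site-specific glycoform distributions of the validation glycoproteins.

    ``frame`` columns: protein, site, peptide, composition (canonical string),
    actual_fraction (sums to 1 within each site), expected (0/1 flag marking
    membership of the literature-expected glycoform list for that site).
    The ``peptide`` column is the representative tryptic peptide covering the
    site and is the key used to map reported PSMs to sites.
    """

    frame: pd.DataFrame = field(repr=False)

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["protein"].unique()))

    @property
    def n_sites(self) -> int:
        return self.frame.groupby(["protein", "site"]).ngroups

    def sites_for(self, protein: str) -> tuple[str, ...]:
        return tuple(sorted(self.frame.loc[self.frame["protein"] == protein, "site"].unique()))


@dataclass(frozen=True)
class ReferenceBundle:
    """Everything the performance tests consume, loaded and validated."""

    n_glycans: ReferenceGlycanDistribution
    o_glycans: ReferenceGlycanDistribution
    n_proteins: ProteinWeightTable
    o_proteins: ProteinWeightTable
    spectra: ReferenceSpectrumSet
    site_glycoforms: SiteGlycoformTable
    consensus_threshold_n: float = 0.50
    consensus_threshold_o: float = 0.30

    def glycans(self, analyte: str) -> ReferenceGlycanDistribution:
        return self.n_glycans if analyte == "N" else self.o_glycans

    def proteins(self, analyte: str) -> ProteinWeightTable:
        return self.n_proteins if analyte == "N" else self.o_proteins

    def consensus_threshold(self, analyte: str) -> float:
        return self.consensus_threshold_n if analyte == "N" else self.consensus_threshold_o


def default_bundle_path() -> Path:
    """Path of the packaged synthetic serum bundle."""
    return Path(resources.files("glycobench") / "data" / "synthetic_serum_bundle")


def _load_distribution(path: Path, analyte: str) -> ReferenceGlycanDistribution:
    frame = pd.read_csv(path)
    entries: dict[GlycanComposition, float] = {}
    for _, row in frame.iterrows():
        comp = parse_composition(str(row["composition"]))
        if comp in entries:
            raise FixtureError(f"{path.name}: duplicate composition {comp}")
        fraction = float(row["fraction"])
        if fraction < 0:
            raise FixtureError(f"{path.name}: negative fraction for {comp}")
        entries[comp] = fraction
    total = sum(entries.values())
    if abs(total - 1.0) > _FRACTION_TOL:
        raise FixtureError(
            f"{path.name}: fractions sum to {total:.6f}, expected 1 within {_FRACTION_TOL}"
        )
    entries = {comp: fraction / total for comp, fraction in entries.items()}
    return ReferenceGlycanDistribution(analyte=analyte, entries=entries)


def _load_weights(path: Path, analyte: str, default_max: int) -> ProteinWeightTable:
    frame = pd.read_csv(path)
    weights: dict[str, int] = {}
    for _, row in frame.iterrows():
        accession = str(row["accession"]).strip()
        weight = int(row["weight"])
        if accession in weights and weights[accession] != weight:
            raise FixtureError(
                f"{path.name}: accession {accession} listed with conflicting weights "
                f"{weights[accession]} and {weight}"
            )
        weights[accession] = weight
    if not weights:
        raise FixtureError(f"{path.name}: empty weight table")
    max_weight = max(default_max, max(weights.values()))
    if min(weights.values()) < 1:
        raise FixtureError(f"{path.name}: weights must be >= 1")
    return ProteinWeightTable(
        analyte=analyte,
        weights=weights,
        max_weight=max_weight,
        reference_universe_size=len(weights),
    )


def _load_spectra(path: Path) -> ReferenceSpectrumSet:
    frame = pd.read_csv(path)
    entries = tuple(
        ReferenceSpectrumEntry(
            spectrum_id=str(row["spectrum_id"]),
            file_id=str(row["file_id"]),
            frag_mode=str(row["frag_mode"]),
            charge=int(row["charge"]),
            adduct=str(row["adduct"]),
        )
        for _, row in frame.iterrows()
    )
    if len({(e.file_id, e.spectrum_id, e.frag_mode) for e in entries}) != len(entries):
        raise FixtureError(f"{path.name}: duplicate spectrum entries")
    return ReferenceSpectrumSet(entries=entries)


def _load_site_glycoforms(path: Path) -> SiteGlycoformTable:
    frame = pd.read_csv(path)
    required = {"protein", "site", "peptide", "composition", "actual_fraction", "expected"}
    missing = required - set(frame.columns)
    if missing:
        raise FixtureError(f"{path.name}: missing columns {sorted(missing)}")
    frame = frame.copy()
    frame["composition"] = [parse_composition(str(c)).canonical() for c in frame["composition"]]
    for (protein, site), group in frame.groupby(["protein", "site"]):
        total = group["actual_fraction"].sum()
        if abs(total - 1.0) > _FRACTION_TOL:
            raise FixtureError(
                f"{path.name}: fractions for {protein}/{site} sum to {total:.6f}, expected 1"
            )
        frame.loc[group.index, "actual_fraction"] = group["actual_fraction"] / total
    return SiteGlycoformTable(frame=frame)


def load_bundle(dir_path: str | Path | None = None) -> ReferenceBundle:
    """Load and validate a reference bundle directory (default: packaged bundle).

    Distributions whose fractions sum to 1 within 1e-6 are renormalised;
    larger deviations, conflicting duplicate weights and duplicate spectra
    raise :class:`FixtureError`.
    """
    root = Path(dir_path) if dir_path is not None else default_bundle_path()
    if not root.is_dir():
        raise FixtureError(f"reference bundle directory {root} does not exist")
    meta: dict[str, str] = {}
    meta_path = root / "meta.csv"
    if meta_path.exists():
        frame = pd.read_csv(meta_path)
        meta = dict(zip(frame["key"].astype(str), frame["value"].astype(str)))
    return ReferenceBundle(
        n_glycans=_load_distribution(root / "glycan_reference_N.csv", "N"),
        o_glycans=_load_distribution(root / "glycan_reference_O.csv", "O"),
        n_proteins=_load_weights(root / "protein_weights_N.csv", "N", default_max=2),
        o_proteins=_load_weights(root / "protein_weights_O.csv", "O", default_max=3),
        spectra=_load_spectra(root / "reference_spectra.csv"),
        site_glycoforms=_load_site_glycoforms(root / "site_glycoforms.csv"),
        consensus_threshold_n=float(meta.get("consensus_threshold_N", 0.50)),
        consensus_threshold_o=float(meta.get("consensus_threshold_O", 0.30)),
    )
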