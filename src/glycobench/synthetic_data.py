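"""Simulated team-report cohorts with the statistical structure the scoring
pipeline assumes.

The generator draws a serum-like ground truth — glycosylation sites on a
protein pool whose accessions and abundances echo the reference bundle, each
site carrying glycoforms sampled from the reference glycan distribution —
and then synthesises one report per team.  A team samples glycoPSMs from the
ground truth proportional to abundance and distorts them through explicit
error channels:

* fidelity ``f``: each sampled PSM is reported unchanged with probability
  ``f``; otherwise it is corrupted, by a near-isobaric glycan substitution
  (NeuAc <-> Fuc2, delta-m 1.0204 Da; NeuAc1Hex1 <-> NeuGc1Fuc1, delta-m 0 —
  the classic confusable pairs) or by source-protein misassignment;
* NeuGc / multi-Fuc injection: independent per-PSM rates planting the two
  false-positive proxy glycofeatures;
* synthetic-glycopeptide detection: each annotated reference spectrum in a
  fragmentation mode and file the team searched is recovered with
  probability ``ref_detection_prob * f``, and spurious target claims appear
  at rate ``spurious_target_rate * (1 - f)``.

Default parameters reproduce the community-study conditions: 22 teams
(9 developers, 13 users), 49-2,122 N- and 5-578 O-glycoPSMs per team, glycan
search spaces of 23-381 (N) and 3-223 (O) compositions, 2 teams returning no
O-glycopeptide data, a collective pool of 2,556 N- and 1,192 O-glycopeptides
over 320 / 231 source proteins.  All randomness flows from one seed;
per-team substreams are derived by stable hashing of the team identifier, so
reports are reproducible and independent of cohort-size changes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .glyco_model import GlycanComposition, GlycopeptideID, make_glycopeptide_id
from .reference_sets import ReferenceBundle, load_bundle
from .report_io import FRAG_MODES, GlycoPSM, SearchSettings, TeamReport

__all__ = ["CohortConfig", "GroundTruth", "SimulatedCohort", "ConfigError",
           "simulate_cohort", "simulate_strategy_grid", "SS_ALIASES"]

_AA_POOL = np.array(list("ADEFGHILMQSVWY"))  # no K/R/N/P/C/T: controlled placement
_PROTON = 1.00728
_MEAN_RESIDUE_MASS = 110.0  # coarse average residue mass, Da
_RT_WINDOWS = {"N": (41.7, 57.2), "O": (26.2, 55.8)}
_FILE_MODES = {"A": ("HCD", "ETciD", "CID"), "B": ("HCD", "EThcD", "CID")}

#: cohort-level knobs addressable by search-setting analogue in strategy grids
SS_ALIASES = {
    "SS1": "n_space_range",
    "SS2": "o_space_range",
    "SS13": "decoy_level",
}


class ConfigError(ValueError):
    """The cohort configuration is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated team cohort.  ``seed`` is mandatory."""

    seed: int
    n_teams: int = 22
    n_developers: int | None = None  # default: the study's 9/22 developer share
    # ground-truth pool (study-scale collective counts)
    n_pool_size: int = 2556
    o_pool_size: int = 1192
    n_protein_pool: int = 320
    o_protein_pool: int = 231
    # per-team behaviour
    fidelity: tuple[float, ...] | None = None
    fidelity_range: tuple[float, float] = (0.3, 1.0)
    neugc_rate: float | tuple[float, ...] = 0.02
    multifuc_rate: float | tuple[float, ...] = 0.02
    glycan_substitution_weight: float = 0.7
    protein_misassignment_weight: float = 0.3
    n_psm_range: tuple[int, int] = (49, 2122)
    o_psm_range: tuple[int, int] = (5, 578)
    n_space_range: tuple[int, int] = (23, 381)
    o_space_range: tuple[int, int] = (3, 223)
    include_neugc_in_space: bool = True
    include_multifuc_in_space: bool = True
    ref_detection_prob: float = 1.0
    spurious_target_rate: float = 0.5
    n_teams_without_o: int = 2
    n_teams_without_a: int = 2
    adduct_rate: float = 0.03
    # strategy-grid couplings (neutral by default)
    decoy_level: int | None = None  # SS13 analogue: 0 none / 1 one / 2 both
    space_fdr_coupling: float = 0.0  # >0 couples search-space breadth to FDR/coverage

    def validate(self) -> None:
        if self.n_teams < 2:
            raise ConfigError("n_teams must be >= 2")
        if not 0 <= self.resolved_developers <= self.n_teams:
            raise ConfigError("n_developers must be between 0 and n_teams")
        for name in ("n_psm_range", "o_psm_range", "n_space_range", "o_space_range",
                     "fidelity_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ConfigError(f"{name}={getattr(self, name)} is not a valid range")
        if self.n_psm_range[0] < 1 or self.o_psm_range[0] < 0:
            raise ConfigError("PSM ranges must be positive")
        for name in ("ref_detection_prob", "spurious_target_rate", "adduct_rate",
                     "space_fdr_coupling"):
            if not 0 <= getattr(self, name) <= (10 if name == "space_fdr_coupling" else 1):
                raise ConfigError(f"{name} out of bounds")
        for rates, flag, label in (
            (self._per_team("neugc_rate"), self.include_neugc_in_space, "NeuGc"),
            (self._per_team("multifuc_rate"), self.include_multifuc_in_space, "multi-Fuc"),
        ):
            if any(not 0 <= r <= 1 for r in rates):
                raise ConfigError(f"{label} injection rates must lie in [0, 1]")
            if any(r > 0 for r in rates) and not flag:
                raise ConfigError(
                    f"{label} injection rate > 0 but {label} excluded from search space"
                )
        if self.fidelity is not None:
            if len(self.fidelity) != self.n_teams:
                raise ConfigError("fidelity must list one value per team")
            if any(not 0 <= f <= 1 for f in self.fidelity):
                raise ConfigError("fidelity values must lie in [0, 1]")
        if self.decoy_level not in (None, 0, 1, 2):
            raise ConfigError("decoy_level must be None, 0, 1 or 2")
        if self.n_teams_without_o + self.n_teams_without_a > self.n_teams:
            pass  # overlapping sets are permitted; no constraint

    @property
    def resolved_developers(self) -> int:
        if self.n_developers is not None:
            return self.n_developers
        return max(1, round(self.n_teams * 9 / 22))

    def _per_team(self, name: str) -> tuple[float, ...]:
        value = getattr(self, name)
        if isinstance(value, (int, float)):
            return (float(value),) * self.n_teams
        if len(value) != self.n_teams:
            raise ConfigError(f"{name} must be a scalar or one value per team")
        return tuple(float(v) for v in value)


@dataclass(frozen=True)
class GroundTruth:
    """The simulated serum glycoproteome: one row per true glycopeptide."""

    n_records: pd.DataFrame = field(repr=False)  # peptide, protein, site, composition, abundance
    o_records: pd.DataFrame = field(repr=False)

    def records(self, analyte: str) -> pd.DataFrame:
        return self.n_records if analyte == "N" else self.o_records

    def unique_ids(self, analyte: str) -> frozenset[GlycopeptideID]:
        frame = self.records(analyte)
        return frozenset(
            make_glycopeptide_id(p, c)
            for p, c in zip(frame["peptide"], frame["composition"])
        )


@dataclass(frozen=True)
class SimulatedCohort:
    config: CohortConfig
    reports: tuple[TeamReport, ...]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# ground-truth construction


def _random_peptide(rng: np.random.Generator, analyte: str) -> str:
    length = int(rng.integers(8, 26))
    body = "".join(rng.choice(_AA_POOL, size=length))
    if analyte == "N":
        # insert an N-glycosylation sequon N-X(!=P)-S/T
        pos = int(rng.integers(0, length - 1))
        sequon = "N" + str(rng.choice(list("ASGLV"))) + str(rng.choice(["S", "T"]))
        body = body[:pos] + sequon + body[pos:]
    else:
        pos = int(rng.integers(0, length))
        body = body[:pos] + str(rng.choice(["S", "T"])) + body[pos:]
    return body + str(rng.choice(["K", "R"]))


def _build_ground_truth(cfg: CohortConfig, bundle: ReferenceBundle,
                        rng: np.random.Generator) -> GroundTruth:
    frames = {}
    for analyte, pool_size, protein_pool in (
        ("N", cfg.n_pool_size, cfg.n_protein_pool),
        ("O", cfg.o_pool_size, cfg.o_protein_pool),
    ):
        weights = bundle.proteins(analyte)
        accessions = sorted(weights.weights)
        extra = [f"GB{analyte}{i:05d}" for i in range(max(0, protein_pool - len(accessions)))]
        proteins = accessions + extra
        # literature-supported proteins dominate serum abundance
        multiplier = np.array(
            [3.0 if weights.weight(p) == weights.max_weight
             else 1.5 if weights.weight(p) > 0 else 0.3 for p in proteins]
        )
        abundance = np.exp(rng.normal(0.0, 1.0, size=len(proteins))) * multiplier
        comp_items = sorted(bundle.glycans(analyte).entries.items())
        comps = [c for c, _ in comp_items]
        comp_frac = np.array([f for _, f in comp_items])

        rows: list[dict] = []
        seen_peptides: set[str] = set()
        if analyte == "N":
            # the validation glycoproteins enter with their fixture site profiles
            site_frame = bundle.site_glycoforms.frame
            for (protein, _site), group in site_frame.groupby(["protein", "site"]):
                peptide = group["peptide"].iloc[0]
                seen_peptides.add(peptide)
                base = 8.0 * np.exp(rng.normal(0.0, 0.2))  # high-abundance serum proteins
                for _, row in group.iterrows():
                    rows.append({
                        "peptide": peptide,
                        "protein": protein,
                        "site": row["site"],
                        "composition": row["composition"],
                        "abundance": base * float(row["actual_fraction"]),
                    })
        site_index = 0
        while len(rows) < pool_size:
            j = int(rng.choice(len(proteins), p=abundance / abundance.sum()))
            peptide = _random_peptide(rng, analyte)
            if peptide in seen_peptides:
                continue
            seen_peptides.add(peptide)
            n_forms = int(rng.integers(1, 7))
            form_idx = rng.choice(len(comps), size=min(n_forms, len(comps)),
                                  replace=False, p=comp_frac)
            site_index += 1
            for k in form_idx:
                if len(rows) >= pool_size:
                    break
                rows.append({
                    "peptide": peptide,
                    "protein": proteins[j],
                    "site": f"site{site_index}",
                    "composition": comps[int(k)].canonical(),
                    "abundance": abundance[j] * comp_frac[int(k)],
                })
        frames[analyte] = pd.DataFrame(rows)
    return GroundTruth(n_records=frames["N"], o_records=frames["O"])


# ---------------------------------------------------------------------------
# error channels


def _near_mass_substitute(comp: GlycanComposition, rng: np.random.Generator,
                          alternatives: Sequence[GlycanComposition]) -> GlycanComposition:
    """Confusable-composition substitution (the near-isobaric pairs)."""
    options = []
    if comp.neuac >= 1:
        options.append(comp.replace(neuac=comp.neuac - 1, fuc=comp.fuc + 2))
        if comp.hex >= 1:
            options.append(comp.replace(neuac=comp.neuac - 1, hex=comp.hex - 1,
                                        neugc=comp.neugc + 1, fuc=comp.fuc + 1))
    if comp.fuc >= 2:
        options.append(comp.replace(fuc=comp.fuc - 2, neuac=comp.neuac + 1))
    if options:
        return options[int(rng.integers(0, len(options)))]
    others = [c for c in alternatives if c != comp]
    if not others:
        return comp
    return others[int(rng.integers(0, len(others)))]


def _inject_neugc(comp: GlycanComposition) -> GlycanComposition:
    if comp.neuac >= 1:
        return comp.replace(neuac=comp.neuac - 1, neugc=comp.neugc + 1)
    return comp.replace(neugc=comp.neugc + 1)


def _inject_multifuc(comp: GlycanComposition) -> GlycanComposition:
    return comp.replace(fuc=comp.fuc + 2) if comp.fuc < 2 else comp


# ---------------------------------------------------------------------------
# per-team synthesis


def _team_rng(seed: int, team_id: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(team_id.encode())])


def _pick_frag_modes(rng: np.random.Generator, files: Sequence[str]) -> frozenset[str]:
    modes = {"HCD"}
    if "B" in files and rng.random() < 0.8:
        modes.add("EThcD")
    if rng.random() < 0.3:
        modes.add("CID")
    if "A" in files and rng.random() < 0.25:
        modes.add("ETciD")
    return frozenset(modes)


def _glycopeptide_mass(peptide: str, comp: GlycanComposition) -> float:
    return _MEAN_RESIDUE_MASS * len(peptide) + comp.residue_mass + 18.0106 + _PROTON


def _synthesize_team(
    cfg: CohortConfig,
    bundle: ReferenceBundle,
    truth: GroundTruth,
    team_index: int,
    team_id: str,
    group: str,
    fidelity: float,
    neugc_rate: float,
    multifuc_rate: float,
) -> TeamReport:
    rng = _team_rng(cfg.seed, team_id)
    files = ("B",) if team_index < cfg.n_teams_without_a else ("A", "B")
    frag_modes = _pick_frag_modes(rng, files)
    n_dev = cfg.resolved_developers
    has_o = team_index < n_dev - cfg.n_teams_without_o or team_index >= n_dev

    # decoy-stringency and search-space couplings (neutral unless configured)
    rate_scale = 1.0
    psm_scale = 1.0
    if cfg.decoy_level is not None:
        rate_scale *= {0: 2.5, 1: 1.0, 2: 0.5}[cfg.decoy_level]
        psm_scale *= {0: 1.4, 1: 1.0, 2: 0.85}[cfg.decoy_level]

    psms: list[GlycoPSM] = []
    spaces: dict[str, tuple[GlycanComposition, ...]] = {}
    scan_counter = {f: int(rng.integers(10_000, 20_000)) for f in files}

    for analyte in ("N", "O"):
        comp_ref = sorted(bundle.glycans(analyte).entries)
        space_lo, space_hi = cfg.n_space_range if analyte == "N" else cfg.o_space_range
        space_target = int(rng.integers(space_lo, space_hi + 1))
        breadth = (space_target - space_lo) / max(1, space_hi - space_lo)
        eff_rate_scale = rate_scale
        eff_psm_scale = psm_scale
        if cfg.space_fdr_coupling > 0:
            eff_rate_scale *= 1.0 + cfg.space_fdr_coupling * breadth
            eff_psm_scale *= 1.0 + 0.5 * cfg.space_fdr_coupling * breadth

        reported_comps: set[GlycanComposition] = set()
        if analyte == "O" and not has_o:
            spaces[analyte] = ()
            continue

        records = truth.records(analyte)
        abundance = records["abundance"].to_numpy()
        prob = abundance / abundance.sum()
        lo, hi = cfg.n_psm_range if analyte == "N" else cfg.o_psm_range
        n_psms = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi))) * eff_psm_scale))
        n_psms = max(1, n_psms)
        chosen = rng.choice(len(records), size=n_psms, p=prob)
        eff_neugc = min(1.0, neugc_rate * eff_rate_scale)
        eff_multifuc = min(1.0, multifuc_rate * eff_rate_scale)

        rt_lo, rt_hi = _RT_WINDOWS[analyte]
        protein_pool = sorted(records["protein"].unique())
        corruption_cache: dict[int, tuple[str, object]] = {}
        for idx in chosen:
            record = records.iloc[int(idx)]
            peptide = record["peptide"]
            protein = record["protein"]
            comp = make_glycopeptide_id(peptide, record["composition"]).composition
            if rng.random() > fidelity:
                # a search engine misassigns a given precursor consistently, so
                # the corruption of a ground-truth record is drawn once per team
                if int(idx) not in corruption_cache:
                    total = cfg.glycan_substitution_weight + cfg.protein_misassignment_weight
                    if total <= 0 or rng.random() < cfg.glycan_substitution_weight / total:
                        corruption_cache[int(idx)] = (
                            "comp", _near_mass_substitute(comp, rng, comp_ref))
                    else:
                        corruption_cache[int(idx)] = (
                            "protein", protein_pool[int(rng.integers(0, len(protein_pool)))])
                kind, value = corruption_cache[int(idx)]
                if kind == "comp":
                    comp = value
                else:
                    protein = value
            if rng.random() < eff_neugc:
                comp = _inject_neugc(comp)
            if rng.random() < eff_multifuc:
                comp = _inject_multifuc(comp)
            file_id = str(rng.choice(files))
            available = [m for m in frag_modes if m in _FILE_MODES[file_id]]
            if not available:
                file_id = "B" if "HCD" in frag_modes else files[0]
                available = [m for m in frag_modes if m in _FILE_MODES[file_id]]
            mode_weights = np.array([{"HCD": 0.55, "EThcD": 0.30,
                                      "ETciD": 0.08, "CID": 0.07}[m] for m in available])
            frag_mode = str(rng.choice(available, p=mode_weights / mode_weights.sum()))
            scan_counter[file_id] += int(rng.integers(1, 9))
            charge = int(rng.choice([2, 3, 4, 5], p=[0.1, 0.3, 0.45, 0.15]))
            mass = _glycopeptide_mass(peptide, comp)
            adduct = "none"
            if rng.random() < cfg.adduct_rate:
                adduct = str(rng.choice(["Na", "K"]))
            reported_comps.add(comp)
            psms.append(GlycoPSM(
                team_id=team_id,
                file_id=file_id,
                spectrum_id=f"{file_id}:scan={scan_counter[file_id]}",
                frag_mode=frag_mode,
                peptide=peptide,
                protein=protein,
                composition=comp,
                analyte=analyte,
                charge=charge,
                mz_observed=round((mass + (charge - 1) * _PROTON) / charge, 4),
                retention_time=round(float(rng.uniform(rt_lo, rt_hi)), 2),
                glycopeptide_mass=round(mass, 4),
                mass_error=round(abs(float(rng.normal(0.0, 1.5))), 3),
                monoiso_correction=0.0 if rng.random() < 0.9 else 1.00335,
                adduct=adduct,
            ))

        # synthetic-glycopeptide detections and spurious claims (N only)
        if analyte == "N":
            target = bundle.spectra.target
            eligible = [e for e in bundle.spectra.entries
                        if e.frag_mode in frag_modes and e.file_id in files]
            for entry in eligible:
                if rng.random() < cfg.ref_detection_prob * fidelity:
                    mass = _glycopeptide_mass(target.peptide, target.composition)
                    reported_comps.add(target.composition)
                    psms.append(GlycoPSM(
                        team_id=team_id,
                        file_id=entry.file_id,
                        spectrum_id=entry.spectrum_id,
                        frag_mode=entry.frag_mode,
                        peptide=target.peptide,
                        protein="P04070",
                        composition=target.composition,
                        analyte="N",
                        charge=entry.charge,
                        mz_observed=round((mass + (entry.charge - 1) * _PROTON) / entry.charge, 4),
                        retention_time=round(float(rng.uniform(*_RT_WINDOWS["N"])), 2),
                        glycopeptide_mass=round(mass, 4),
                        mass_error=round(abs(float(rng.normal(0.0, 1.0))), 3),
                        monoiso_correction=0.0,
                        adduct=entry.adduct,
                    ))
            n_spurious = int(rng.binomial(len(eligible), min(1.0, cfg.spurious_target_rate * (1 - fidelity)))) if eligible else 0
            for _ in range(n_spurious):
                file_id = str(rng.choice(files))
                available = [m for m in frag_modes if m in _FILE_MODES[file_id]] or ["HCD"]
                scan_counter.setdefault(file_id, 30_000)
                scan_counter[file_id] += int(rng.integers(1, 9))
                mass = _glycopeptide_mass(target.peptide, target.composition)
                reported_comps.add(target.composition)
                psms.append(GlycoPSM(
                    team_id=team_id,
                    file_id=file_id,
                    spectrum_id=f"{file_id}:scan={scan_counter[file_id]}",
                    frag_mode=available[int(rng.integers(0, len(available)))],
                    peptide=target.peptide,
                    protein="P04070",
                    composition=target.composition,
                    analyte="N",
                    charge=4,
                    mz_observed=round((mass + 3 * _PROTON) / 4, 4),
                    retention_time=round(float(rng.uniform(*_RT_WINDOWS["N"])), 2),
                    glycopeptide_mass=round(mass, 4),
                    mass_error=round(abs(float(rng.normal(0.0, 1.5))), 3),
                    monoiso_correction=0.0,
                    adduct="none",
                ))

        # search space: everything reported, padded with reference compositions
        # and (when enabled) NeuGc / multi-Fuc decoy variants
        space = set(reported_comps)
        for comp in comp_ref:
            if len(space) >= space_target:
                break
            space.add(comp)
        if cfg.include_neugc_in_space:
            for comp in comp_ref:
                if comp.neuac >= 1:
                    space.add(_inject_neugc(comp))
                if len(space) >= max(space_target, len(reported_comps) + 2):
                    break
        if cfg.include_multifuc_in_space:
            for comp in comp_ref:
                space.add(_inject_multifuc(comp))
                if len(space) >= max(space_target, len(reported_comps) + 4):
                    break
        filler = 0
        while len(space) < space_target:
            filler += 1
            space.add(GlycanComposition(
                hex=int(rng.integers(1, 10)), hexnac=int(rng.integers(1, 8)),
                fuc=int(rng.integers(0, 2)), neuac=int(rng.integers(0, 5)),
            ))
            if filler > 10 * space_target:
                break
        spaces[analyte] = tuple(sorted(space))

    settings = _draw_settings(rng, spaces)
    return TeamReport(
        team_id=team_id,
        group=group,
        frag_modes_used=frag_modes,
        settings=settings,
        n_search_space=spaces["N"],
        o_search_space=spaces["O"],
        psms=tuple(psms),
    )


def _draw_settings(rng: np.random.Generator,
                   spaces: dict[str, tuple[GlycanComposition, ...]]) -> SearchSettings:
    engines = ["Byonic", "Protein Prospector", "GlycoPAT", "glyXtoolMS", "GPQuest",
               "IQ-GPA", "Mascot", "SugarQb", "Glycopeptide Search"]
    engine = str(rng.choice(engines, p=[0.5, 0.09, 0.05, 0.05, 0.05, 0.05, 0.08, 0.08, 0.05]))
    return SearchSettings(
        ss1_n_space_size=len(spaces["N"]),
        ss2_o_space_size=len(spaces["O"]),
        ss3_engine=engine,
        ss4_engine_type=1 if engine in ("Byonic", "Mascot") else 0,
        ss5_recalibration=int(rng.random() < 4 / 22),
        ss6_protease=-1 if rng.random() < 14 / 22 else 0,
        ss7_missed_cleavages=int(rng.integers(0, 3)),
        ss8_varmod_types=int(rng.integers(0, 15)),
        ss9_max_glycans_per_peptide=int(rng.integers(1, 6)),
        ss10_max_other_varmods=int(rng.integers(0, 6)),
        ss11_precursor_tol=int(rng.choice([0, 1, 2], p=[6 / 22, 14 / 22, 2 / 22])),
        ss12_product_tol=int(rng.choice([0, 1, 2], p=[0.0, 9 / 22, 13 / 22])),
        ss13_fdr_db=int(rng.choice([0, 1, 2], p=[3 / 22, 9 / 22, 10 / 22])),
    )


# ---------------------------------------------------------------------------
# public API


def simulate_cohort(cfg: CohortConfig, bundle: ReferenceBundle | None = None) -> SimulatedCohort:
    """Simulate a full team cohort plus its ground truth.

    Fully reproducible from ``cfg.seed``; two calls with equal configs return
    identical cohorts.
    """
    cfg.validate()
    if bundle is None:
        bundle = load_bundle()
    master = np.random.default_rng(cfg.seed)
    truth = _build_ground_truth(cfg, bundle, master)
    neugc_rates = cfg._per_team("neugc_rate")
    multifuc_rates = cfg._per_team("multifuc_rate")
    reports = []
    for i in range(cfg.n_teams):
        team_id = f"team{i + 1:02d}"
        group = "developer" if i < cfg.resolved_developers else "user"
        if cfg.fidelity is not None:
            fidelity = float(cfg.fidelity[i])
        else:
            fidelity = float(_team_rng(cfg.seed ^ 0x5F5E5F, team_id).uniform(*cfg.fidelity_range))
        reports.append(
            _synthesize_team(cfg, bundle, truth, i, team_id, group,
                             fidelity, neugc_rates[i], multifuc_rates[i])
        )
    return SimulatedCohort(config=cfg, reports=tuple(reports), ground_truth=truth)


def simulate_strategy_grid(
    base_cfg: CohortConfig,
    varied_setting: str,
    levels: Sequence,
    bundle: ReferenceBundle | None = None,
) -> list[tuple[object, SimulatedCohort]]:
    """One cohort per level of a single varied setting, all else held at base.

    ``varied_setting`` is a :class:`CohortConfig` field name or a
    search-setting analogue from :data:`SS_ALIASES` (SS1/SS2: glycan-space
    breadth; SS13: decoy-database stringency, modelled through the
    false-positive injection and coverage scales).  The shared seed makes the
    cohorts differ only through the varied level.
    """
    field_name = SS_ALIASES.get(varied_setting.upper(), varied_setting)
    if field_name not in CohortConfig.__dataclass_fields__:
        raise ConfigError(f"unknown setting {varied_setting!r}")
    out = []
    for level in levels:
        cfg = replace(base_cfg, **{field_name: level})
        out.append((level, simulate_cohort(cfg, bundle)))
    return out
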