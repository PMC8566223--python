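"""The eleven glycopeptide performance tests and consensus derivation.

Six tests score N-glycopeptide analysis and five score O-glycopeptide
analysis; each returns a raw score, with separate sensitivity/specificity
components where the test defines them:

==========  =====================================================
test id     what it measures
==========  =====================================================
N1          recovery and accuracy of the spiked synthetic
            glycopeptide's annotated reference spectra, adjusted
            to the fragmentation modes the team searched
N2 / O1     squared Pearson correlation between the reported
            glycan-composition distribution (spectral counts) and
            the expected serum distribution
N3 / O2     specificity and sensitivity of reported source
            glycoproteins against literature weight tables
N4 / O3     glycoproteome coverage: unique glycopeptides reported
            (raw count; normalised downstream)
N5 / O4     proportion of the consensus glycopeptide list (IDs
            reported by >= the threshold fraction of teams) that
            the team recovered
N6 / O5     absence of NeuGc and multi-Fuc (>= 2 Fuc) glycoPSMs,
            false-positive proxies in human serum; applicable only
            to teams whose search space contained those classes
==========  =====================================================

Raw scores of bounded tests lie in [0, 1]; the coverage tests are
nonnegative counts.  A result with ``applicable=False`` is excluded from all
downstream averaging.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .glyco_model import GlycanComposition, GlycopeptideID, classify
from .report_io import TeamReport, unique_glycopeptides
from .reference_sets import (
    ProteinWeightTable,
    ReferenceBundle,
    ReferenceGlycanDistribution,
    ReferenceSpectrumSet,
)

__all__ = [
    "TestResult",
    "ConsensusSet",
    "score_synthetic_glycopeptide",
    "score_glycan_composition",
    "score_source_protein",
    "score_coverage",
    "derive_consensus",
    "score_consensus_recovery",
    "score_neugc_multifuc",
    "run_all_tests",
    "TEST_IDS",
]

#: test identifiers per analyte, in scoring order
TEST_IDS = {
    "N": ("N1", "N2", "N3", "N4", "N5", "N6"),
    "O": ("O1", "O2", "O3", "O4", "O5"),
}


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest collection target

    test_id: str
    team_id: str
    raw_score: float
    sensitivity: float | None = None
    specificity: float | None = None
    applicable: bool = True
    details: Mapping[str, object] = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class ConsensusSet:
    """Glycopeptide identities reported by at least ``threshold_fraction`` of
    the teams that returned data for the analyte, with companion consensus
    sets for source proteins and glycan compositions."""

    analyte: str
    threshold_fraction: float
    n_teams: int
    members: frozenset[GlycopeptideID]
    proteins: frozenset[str]
    compositions: frozenset[GlycanComposition]
    support: Mapping[GlycopeptideID, int] = field(default_factory=dict, compare=False)


# ---------------------------------------------------------------------------
# N1: synthetic glycopeptide


def score_synthetic_glycopeptide(report: TeamReport, ref: ReferenceSpectrumSet) -> TestResult:
    """Score recovery (sensitivity) and accuracy (specificity) of the spiked
    synthetic glycopeptide, adjusted to the team's fragmentation modes.

    Only reference spectra acquired with a mode the team searched are
    eligible.  Sensitivity is the fraction of eligible reference spectra the
    team reported (matched on file, scan and mode, claiming the target
    identity); specificity is the fraction of the team's target-identity
    claims (in eligible modes) that match an eligible reference spectrum.
    The raw score is their product.
    """
    eligible = ref.eligible(report.frag_modes_used)
    test_id = "N1"
    if not eligible:
        return TestResult(test_id, report.team_id, 0.0, applicable=False,
                          details={"reason": "no reference spectra in searched modes"})
    eligible_keys = {(e.file_id, e.spectrum_id, e.frag_mode) for e in eligible}
    claims = [
        psm
        for psm in report.psms_for("N")
        if psm.glycopeptide_id == ref.target and psm.frag_mode in report.frag_modes_used
    ]
    matched_keys = {
        (psm.file_id, psm.spectrum_id, psm.frag_mode)
        for psm in claims
        if (psm.file_id, psm.spectrum_id, psm.frag_mode) in eligible_keys
    }
    sensitivity = len(matched_keys) / len(eligible_keys)
    details: dict[str, object] = {
        "eligible_spectra": len(eligible_keys),
        "matched_spectra": len(matched_keys),
        "target_claims": len(claims),
    }
    if not claims:
        details["specificity_undefined"] = True
        return TestResult(test_id, report.team_id, 0.0, sensitivity=0.0,
                          specificity=None, details=details)
    matching_claims = sum(
        1 for psm in claims if (psm.file_id, psm.spectrum_id, psm.frag_mode) in eligible_keys
    )
    specificity = matching_claims / len(claims)
    return TestResult(
        test_id,
        report.team_id,
        raw_score=sensitivity * specificity,
        sensitivity=sensitivity,
        specificity=specificity,
        details=details,
    )


# ---------------------------------------------------------------------------
# N2 / O1: glycan composition distribution


def observed_composition_distribution(
    report: TeamReport, analyte: str
) -> dict[GlycanComposition, float]:
    """Relative spectral-count abundance of each glycan composition."""
    counts = Counter(psm.composition for psm in report.psms_for(analyte))
    total = sum(counts.values())
    if total == 0:
        return {}
    return {comp: count / total for comp, count in counts.items()}


def score_glycan_composition(
    report: TeamReport, ref: ReferenceGlycanDistribution, analyte: str
) -> TestResult:
    """Squared Pearson correlation between the expected and observed glycan
    distribution, aligned on the union of compositions (absent entries 0).

    Compositions observed but absent from the reference enter as reference-0
    entries, so reporting off-reference glycans lowers the score rather than
    being silently dropped.
    """
    test_id = "N2" if analyte == "N" else "O1"
    observed = observed_composition_distribution(report, analyte)
    if len(observed) < 2:
        return TestResult(test_id, report.team_id, 0.0, applicable=False,
                          details={"reason": "fewer than two distinct compositions"})
    union = sorted(set(ref.entries) | set(observed))
    expected_vec = np.array([ref.fraction(c) for c in union])
    observed_vec = np.array([observed.get(c, 0.0) for c in union])
    if np.ptp(expected_vec) == 0 or np.ptp(observed_vec) == 0:
        return TestResult(test_id, report.team_id, 0.0, applicable=False,
                          details={"reason": "zero variance in aligned distributions"})
    r = stats.pearsonr(expected_vec, observed_vec).statistic
    return TestResult(test_id, report.team_id, float(r * r),
                      details={"n_union": len(union), "pearson_r": float(r)})


# ---------------------------------------------------------------------------
# N3 / O2: source glycoproteins


def score_source_protein(
    report: TeamReport,
    weights: ProteinWeightTable,
    analyte: str,
    *,
    specificity_variant: str = "psm_weighted",
    combine: str = "mean",
) -> TestResult:
    """Score accuracy and coverage of reported source glycoproteins against a
    literature weight table.

    Specificity (default ``psm_weighted``): summed per-PSM protein weight over
    the maximum attainable (every PSM on a top-weight protein).  The
    ``unique_protein`` variant averages weights over distinct proteins
    instead; both appear in ``details``.  Sensitivity: fraction of the
    literature protein universe the team covered with weight > 0 proteins.
    The raw score is the mean (or, via ``combine="product"``, the product) of
    the two components.
    """
    test_id = "N3" if analyte == "N" else "O2"
    psms = report.psms_for(analyte)
    if not psms:
        return TestResult(test_id, report.team_id, 0.0, applicable=False,
                          details={"reason": "zero PSMs"})
    psm_counts = Counter(psm.protein for psm in psms)
    total_psms = sum(psm_counts.values())
    weighted_psms = sum(count * weights.weight(p) for p, count in psm_counts.items())
    spec_psm = weighted_psms / (total_psms * weights.max_weight)
    n_unique = len(psm_counts)
    spec_unique = sum(weights.weight(p) for p in psm_counts) / (n_unique * weights.max_weight)
    covered = sum(1 for p in psm_counts if weights.weight(p) > 0)
    sensitivity = covered / weights.reference_universe_size
    specificity = spec_psm if specificity_variant == "psm_weighted" else spec_unique
    if combine == "mean":
        raw = (specificity + sensitivity) / 2
    elif combine == "product":
        raw = specificity * sensitivity
    else:
        raise ValueError(f"unknown combine {combine!r}")
    return TestResult(
        test_id,
        report.team_id,
        raw_score=raw,
        sensitivity=sensitivity,
        specificity=specificity,
        details={
            "specificity_psm_weighted": spec_psm,
            "specificity_unique_protein": spec_unique,
            "unique_proteins": n_unique,
            "covered_reference_proteins": covered,
        },
    )


# ---------------------------------------------------------------------------
# N4 / O3: glycoproteome coverage


def score_coverage(report: TeamReport, analyte: str) -> TestResult:
    """Glycoproteome coverage: the count of unique glycopeptides reported.

    The raw score is an unnormalised count; cross-team normalisation happens
    in the scoring module.
    """
    test_id = "N4" if analyte == "N" else "O3"
    count = len(unique_glycopeptides(report, analyte))
    return TestResult(test_id, report.team_id, float(count),
                      details={"unique_glycopeptides": count})


# ---------------------------------------------------------------------------
# consensus derivation and N5 / O4


def derive_consensus(
    reports: Sequence[TeamReport],
    analyte: str,
    threshold_fraction: float,
    *,
    strict: bool = False,
) -> ConsensusSet:
    """Derive the consensus glycopeptide/protein/composition sets.

    The team universe is the set of teams that returned any data for the
    analyte.  Membership requires team support / universe >= the threshold
    (``strict=True`` switches to a strictly-greater comparison).
    """
    if len(reports) < 2:
        raise ValueError("consensus derivation needs at least two reports")
    if not 0 < threshold_fraction <= 1:
        raise ValueError(f"threshold_fraction must be in (0, 1], got {threshold_fraction}")
    participating = [r for r in reports if r.psms_for(analyte)]
    n_teams = len(participating)
    id_support: Counter[GlycopeptideID] = Counter()
    protein_support: Counter[str] = Counter()
    comp_support: Counter[GlycanComposition] = Counter()
    for report in participating:
        psms = report.psms_for(analyte)
        id_support.update(unique_glycopeptides(report, analyte))
        protein_support.update({psm.protein for psm in psms})
        comp_support.update({psm.composition for psm in psms})

    def _passes(count: int) -> bool:
        fraction = count / n_teams if n_teams else 0.0
        return fraction > threshold_fraction if strict else fraction >= threshold_fraction

    return ConsensusSet(
        analyte=analyte,
        threshold_fraction=threshold_fraction,
        n_teams=n_teams,
        members=frozenset(i for i, c in id_support.items() if _passes(c)),
        proteins=frozenset(p for p, c in protein_support.items() if _passes(c)),
        compositions=frozenset(c for c, n in comp_support.items() if _passes(n)),
        support=dict(id_support),
    )


def score_consensus_recovery(report: TeamReport, consensus: ConsensusSet) -> TestResult:
    """Fraction of the consensus glycopeptide list the team recovered.

    The score only counts consensus members, so reporting additional
    non-consensus identities neither helps nor hurts.
    """
    test_id = "N5" if consensus.analyte == "N" else "O4"
    if not consensus.members:
        return TestResult(test_id, report.team_id, 0.0, applicable=False,
                          details={"reason": "empty consensus set"})
    reported = unique_glycopeptides(report, consensus.analyte)
    hits = len(reported & consensus.members)
    return TestResult(
        test_id,
        report.team_id,
        raw_score=hits / len(consensus.members),
        details={"consensus_size": len(consensus.members), "recovered": hits},
    )


# ---------------------------------------------------------------------------
# N6 / O5: NeuGc and multi-Fuc false-positive proxies


def score_neugc_multifuc(report: TeamReport, analyte: str) -> TestResult:
    """Score the absence of NeuGc and multi-Fuc glycoPSMs.

    The raw score is the mean of the non-NeuGc and non-multi-Fuc PSM
    fractions.  The test only applies to teams whose glycan search space for
    the analyte contained at least one NeuGc and one multi-Fuc composition —
    a team that never searched those classes could not have reported them,
    so its absence carries no information.  If exactly one class was
    searchable the score is the corresponding single fraction, flagged in
    ``details``.
    """
    test_id = "N6" if analyte == "N" else "O5"
    psms = report.psms_for(analyte)
    if not psms:
        return TestResult(test_id, report.team_id, 0.0, applicable=False,
                          details={"reason": "zero PSMs"})
    space = report.search_space(analyte)
    space_classes = [classify(comp, analyte) for comp in space]
    neugc_searchable = any(c.has_neugc for c in space_classes)
    multifuc_searchable = any(c.is_multi_fuc for c in space_classes)
    if not neugc_searchable and not multifuc_searchable:
        return TestResult(test_id, report.team_id, 0.0, applicable=False,
                          details={"reason": "search space free of NeuGc and multi-Fuc"})
    n = len(psms)
    frac_non_neugc = sum(1 for p in psms if p.composition.neugc == 0) / n
    frac_non_multifuc = sum(1 for p in psms if p.composition.fuc < 2) / n
    details: dict[str, object] = {
        "fraction_non_neugc": frac_non_neugc,
        "fraction_non_multifuc": frac_non_multifuc,
        "neugc_searchable": neugc_searchable,
        "multifuc_searchable": multifuc_searchable,
    }
    if neugc_searchable and multifuc_searchable:
        raw = (frac_non_neugc + frac_non_multifuc) / 2
    elif neugc_searchable:
        raw = frac_non_neugc
        details["single_class"] = "NeuGc"
    else:
        raw = frac_non_multifuc
        details["single_class"] = "multiFuc"
    return TestResult(test_id, report.team_id, raw, details=details)


# ---------------------------------------------------------------------------
# orchestration


def run_all_tests(
    reports: Sequence[TeamReport],
    bundle: ReferenceBundle,
    *,
    analytes: Iterable[str] = ("N", "O"),
    n3_specificity_variant: str = "psm_weighted",
    strict_consensus: bool = False,
) -> tuple[list[TestResult], dict[str, ConsensusSet]]:
    """Run every performance test for every report.

    Returns the flat result list plus the derived consensus set per analyte.
    """
    results: list[TestResult] = []
    consensus: dict[str, ConsensusSet] = {}
    for analyte in analytes:
        consensus[analyte] = derive_consensus(
            reports, analyte, bundle.consensus_threshold(analyte), strict=strict_consensus
        )
    for report in reports:
        if "N" in analytes:
            results.append(score_synthetic_glycopeptide(report, bundle.spectra))
        for analyte in analytes:
            results.append(
                score_glycan_composition(report, bundle.glycans(analyte), analyte)
            )
            results.append(
                score_source_protein(
                    report,
                    bundle.proteins(analyte),
                    analyte,
                    specificity_variant=n3_specificity_variant,
                )
            )
            results.append(score_coverage(report, analyte))
            results.append(score_consensus_recovery(report, consensus[analyte]))
            results.append(score_neugc_multifuc(report, analyte))
    return results, consensus
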