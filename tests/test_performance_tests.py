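"""The eleven performance tests and consensus derivation, checked against
hand arithmetic and brute-force oracles."""

import math
from collections import Counter

import numpy as np
import pytest

from glycobench.glyco_model import make_glycopeptide_id, parse_composition
from glycobench.performance_tests import (
    derive_consensus,
    score_consensus_recovery,
    score_coverage,
    score_glycan_composition,
    score_neugc_multifuc,
    score_source_protein,
    score_synthetic_glycopeptide,
)
from glycobench.reference_sets import (
    ProteinWeightTable,
    ReferenceGlycanDistribution,
)

from conftest import make_psm, make_report

TARGET_COMP = "HexNAc4Hex5NeuAc2"


def _target_psm(entry, **overrides):
    base = dict(
        spectrum_id=entry.spectrum_id, file_id=entry.file_id,
        frag_mode=entry.frag_mode, charge=entry.charge, adduct=entry.adduct,
        peptide="EVFVHPNYSK", composition=TARGET_COMP, protein="P04070",
    )
    base.update(overrides)
    return make_psm(**base)


class TestSyntheticGlycopeptide:
    def test_perfect_recovery(self, bundle):
        report = make_report(psms=[_target_psm(e) for e in bundle.spectra.entries])
        got = score_synthetic_glycopeptide(report, bundle.spectra)
        assert (got.sensitivity, got.specificity, got.raw_score) == (1.0, 1.0, 1.0)

    def test_partial_recovery_with_spurious_claims(self, bundle):
        # EThcD + CID cover 6 of the 12 reference spectra
        eligible = [e for e in bundle.spectra.entries if e.frag_mode in ("EThcD", "CID")]
        assert len(eligible) == 6
        psms = [_target_psm(e) for e in eligible[:3]]
        psms += [_target_psm(eligible[0], spectrum_id=f"B:scan=9999{i}", frag_mode="CID",
                             file_id="B") for i in range(2)]
        report = make_report(modes=("EThcD", "CID"), psms=psms)
        got = score_synthetic_glycopeptide(report, bundle.spectra)
        assert got.sensitivity == pytest.approx(3 / 6)
        assert got.specificity == pytest.approx(3 / 5)
        assert got.raw_score == pytest.approx(0.3)

    def test_no_claims_scores_zero_with_undefined_specificity(self, bundle):
        report = make_report(psms=[make_psm(peptide="LVNEVTEFAK")])
        got = score_synthetic_glycopeptide(report, bundle.spectra)
        assert got.raw_score == 0.0 and got.sensitivity == 0.0
        assert got.specificity is None
        assert got.details["specificity_undefined"]

    def test_mode_adjustment_restricts_denominator(self, bundle):
        hcd_entries = [e for e in bundle.spectra.entries if e.frag_mode == "HCD"]
        report = make_report(modes=("HCD",), psms=[_target_psm(e) for e in hcd_entries])
        got = score_synthetic_glycopeptide(report, bundle.spectra)
        assert got.details["eligible_spectra"] == len(hcd_entries)
        assert got.raw_score == 1.0


class TestGlycanComposition:
    def test_identical_distribution_gives_unity(self):
        ref = ReferenceGlycanDistribution("N", {
            parse_composition("Hex5HexNAc4NeuAc2"): 0.5,
            parse_composition("Hex5HexNAc4NeuAc1"): 0.3,
            parse_composition("Hex9HexNAc2"): 0.2,
        })
        psms = []
        for comp, count in [("Hex5HexNAc4NeuAc2", 5), ("Hex5HexNAc4NeuAc1", 3), ("Hex9HexNAc2", 2)]:
            psms += [make_psm(spectrum_id=f"{comp}{i}", composition=comp) for i in range(count)]
        got = score_glycan_composition(make_report(psms=psms), ref, "N")
        assert got.raw_score == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_correlation(self):
        # reference (0.5, 0.3, 0.2) against observed counts (1, 1, 2):
        # r = -2/sqrt(7), so R^2 = 4/7 by the product-moment formula
        ref = ReferenceGlycanDistribution("N", {
            parse_composition("Hex5HexNAc4NeuAc2"): 0.5,
            parse_composition("Hex5HexNAc4NeuAc1"): 0.3,
            parse_composition("Hex9HexNAc2"): 0.2,
        })
        psms = [
            make_psm(spectrum_id="a", composition="Hex5HexNAc4NeuAc2"),
            make_psm(spectrum_id="b", composition="Hex5HexNAc4NeuAc1"),
            make_psm(spectrum_id="c", composition="Hex9HexNAc2"),
            make_psm(spectrum_id="d", composition="Hex9HexNAc2"),
        ]
        got = score_glycan_composition(make_report(psms=psms), ref, "N")
        assert got.raw_score == pytest.approx(4 / 7, abs=1e-12)

    def test_disjoint_support_uses_union_alignment(self):
        ref = ReferenceGlycanDistribution("N", {
            parse_composition("Hex5HexNAc4NeuAc2"): 0.6,
            parse_composition("Hex5HexNAc4NeuAc1"): 0.4,
        })
        psms = [
            make_psm(spectrum_id="a", composition="Hex9HexNAc2"),
            make_psm(spectrum_id="b", composition="Hex2HexNAc2"),
        ]
        got = score_glycan_composition(make_report(psms=psms), ref, "N")
        # independent oracle on the 4-entry union vectors
        expected_vec = np.array([0.0, 0.4, 0.6, 0.0])
        observed_vec = np.array([0.5, 0.0, 0.0, 0.5])
        r = np.corrcoef(expected_vec, observed_vec)[0, 1]
        assert got.raw_score == pytest.approx(r * r, abs=1e-12)
        assert got.details["n_union"] == 4

    def test_single_composition_inapplicable(self):
        ref = ReferenceGlycanDistribution("N", {parse_composition("Hex5HexNAc4NeuAc2"): 1.0})
        got = score_glycan_composition(
            make_report(psms=[make_psm()]), ref, "N"
        )
        assert not got.applicable

    def test_matches_independent_correlation_on_simulated_reports(self, small_cohort, bundle):
        for report in small_cohort.reports:
            got = score_glycan_composition(report, bundle.n_glycans, "N")
            if not got.applicable:
                continue
            counts = Counter(p.composition for p in report.psms_for("N"))
            total = sum(counts.values())
            union = sorted(set(bundle.n_glycans.entries) | set(counts))
            x = np.array([bundle.n_glycans.fraction(c) for c in union])
            y = np.array([counts.get(c, 0) / total for c in union])
            r = np.corrcoef(x, y)[0, 1]
            assert got.raw_score == pytest.approx(r * r, abs=1e-12)


class TestSourceProtein:
    WEIGHTS = ProteinWeightTable("N", {"P1": 2}, max_weight=2, reference_universe_size=4)

    def test_forced_arithmetic(self):
        psms = [make_psm(spectrum_id=f"p1-{i}", protein="P1") for i in range(3)]
        psms.append(make_psm(spectrum_id="p3", protein="P3"))
        got = score_source_protein(make_report(psms=psms), self.WEIGHTS, "N")
        assert got.specificity == pytest.approx(0.75)  # (3*2) / (4*2)
        assert got.sensitivity == pytest.approx(0.25)  # 1 of 4 reference proteins
        assert got.raw_score == pytest.approx(0.5)

    def test_max_weight_only_team_has_unit_specificity(self):
        psms = [make_psm(spectrum_id=f"s{i}", protein="P1") for i in range(5)]
        for variant in ("psm_weighted", "unique_protein"):
            got = score_source_protein(make_report(psms=psms), self.WEIGHTS, "N",
                                      specificity_variant=variant)
            assert got.specificity == 1.0

    def test_variants_agree_at_one_psm_per_protein(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            weights = {f"P{j}": int(w) for j, w in enumerate(rng.integers(1, 3, size=6))}
            table = ProteinWeightTable("N", weights, max_weight=2,
                                       reference_universe_size=10)
            chosen = rng.choice(8, size=int(rng.integers(1, 6)), replace=False)
            psms = [make_psm(spectrum_id=f"s{j}", protein=f"P{j}") for j in chosen]
            a = score_source_protein(make_report(psms=psms), table, "N",
                                    specificity_variant="psm_weighted")
            b = score_source_protein(make_report(psms=psms), table, "N",
                                    specificity_variant="unique_protein")
            assert a.specificity == pytest.approx(b.specificity, abs=1e-12)

    def test_zero_psms_inapplicable(self):
        got = score_source_protein(make_report(psms=[]), self.WEIGHTS, "N")
        assert not got.applicable


class TestCoverage:
    def test_empty_report(self):
        assert score_coverage(make_report(psms=[]), "N").raw_score == 0.0

    def test_five_psms_two_ids(self):
        psms = [make_psm(spectrum_id=f"a{i}") for i in range(3)]
        psms += [make_psm(spectrum_id=f"b{i}", composition="Hex9HexNAc2") for i in range(2)]
        assert score_coverage(make_report(psms=psms), "N").raw_score == 2.0


class TestConsensus:
    def _cohort(self, memberships):
        reports = []
        for t, comps in enumerate(memberships):
            psms = [make_psm(team_id=f"t{t}", spectrum_id=f"s{i}", composition=c)
                    for i, c in enumerate(comps)]
            reports.append(make_report(team_id=f"t{t}", psms=psms))
        return reports

    def test_threshold_is_inclusive_by_default(self):
        reports = self._cohort([
            ["Hex5HexNAc4NeuAc2"], ["Hex5HexNAc4NeuAc2"],
            ["Hex9HexNAc2"], ["Hex2HexNAc2"],
        ])
        shared = make_glycopeptide_id("EVFVHPNYSK", parse_composition("Hex5HexNAc4NeuAc2"))
        assert shared in derive_consensus(reports, "N", 0.5).members
        assert shared not in derive_consensus(reports, "N", 0.75).members
        assert shared not in derive_consensus(reports, "N", 0.5, strict=True).members

    def test_agrees_with_exhaustive_counting_oracle(self, small_cohort):
        reports = small_cohort.reports
        for threshold in (0.3, 0.5, 0.75):
            got = derive_consensus(reports, "N", threshold)
            participating = [r for r in reports if r.psms_for("N")]
            support = Counter()
            protein_support = Counter()
            comp_support = Counter()
            for report in participating:
                ids = {p.glycopeptide_id for p in report.psms_for("N")}
                support.update(ids)
                protein_support.update({p.protein for p in report.psms_for("N")})
                comp_support.update({p.composition for p in report.psms_for("N")})
            n = len(participating)
            assert got.members == {i for i, c in support.items() if c / n >= threshold}
            assert got.proteins == {p for p, c in protein_support.items() if c / n >= threshold}
            assert got.compositions == {c for c, k in comp_support.items() if k / n >= threshold}

    def test_needs_at_least_two_reports(self):
        with pytest.raises(ValueError):
            derive_consensus(self._cohort([["Hex2HexNAc2"]]), "N", 0.5)

    def test_recovery_fraction(self, small_cohort):
        consensus = derive_consensus(small_cohort.reports, "N", 0.5)
        members = sorted(consensus.members, key=str)[:10]
        psms = [make_psm(spectrum_id=f"s{i}", peptide=m.peptide, composition=m.composition)
                for i, m in enumerate(members[:4])]
        got = score_consensus_recovery(make_report(psms=psms), consensus)
        assert got.raw_score == pytest.approx(4 / len(consensus.members))

    def test_recovery_invariant_to_nonconsensus_additions(self, small_cohort):
        consensus = derive_consensus(small_cohort.reports, "N", 0.5)
        members = sorted(consensus.members, key=str)
        base_psms = [make_psm(spectrum_id=f"s{i}", peptide=m.peptide, composition=m.composition)
                     for i, m in enumerate(members[:3])]
        extra = [make_psm(spectrum_id=f"x{i}", peptide="LVNEVTEFAK",
                          composition=f"Hex{i + 1}HexNAc2") for i in range(5)]
        a = score_consensus_recovery(make_report(psms=base_psms), consensus)
        b = score_consensus_recovery(make_report(psms=base_psms + extra), consensus)
        assert a.raw_score == b.raw_score


class TestNeuGcMultiFuc:
    def _mixed_report(self, n_total=100, n_neugc=10, n_multifuc=5, **kwargs):
        psms = []
        for i in range(n_neugc):
            psms.append(make_psm(spectrum_id=f"g{i}", composition="Hex5HexNAc4NeuAc1NeuGc1"))
        for i in range(n_multifuc):
            psms.append(make_psm(spectrum_id=f"f{i}", composition="Hex3HexNAc4Fuc2"))
        for i in range(n_total - n_neugc - n_multifuc):
            psms.append(make_psm(spectrum_id=f"c{i}", composition="Hex5HexNAc4NeuAc2"))
        return make_report(psms=psms, **kwargs)

    def test_forced_arithmetic(self):
        got = score_neugc_multifuc(self._mixed_report(), "N")
        assert got.raw_score == pytest.approx((0.90 + 0.95) / 2)

    def test_clean_report_scores_one(self):
        got = score_neugc_multifuc(self._mixed_report(n_neugc=0, n_multifuc=0), "N")
        assert got.raw_score == 1.0

    def test_clean_search_space_is_inapplicable(self):
        report = self._mixed_report(n_neugc=0, n_multifuc=0,
                                    n_space=("Hex5HexNAc4NeuAc2", "Hex9HexNAc2"))
        assert not score_neugc_multifuc(report, "N").applicable

    def test_single_searchable_class_uses_single_fraction(self):
        report = self._mixed_report(
            n_multifuc=0,
            n_space=("Hex5HexNAc4NeuAc2", "Hex5HexNAc4NeuAc1NeuGc1"),
        )
        got = score_neugc_multifuc(report, "N")
        assert got.raw_score == pytest.approx(0.90)
        assert got.details["single_class"] == "NeuGc"

    def test_injecting_neugc_never_raises_score(self):
        report = self._mixed_report()
        base = score_neugc_multifuc(report, "N").raw_score
        previous = base
        for k in (1, 5, 20):
            extra = [make_psm(spectrum_id=f"inj{i}", composition="Hex5HexNAc4NeuGc2")
                     for i in range(k)]
            worse = score_neugc_multifuc(
                make_report(psms=list(report.psms) + extra), "N"
            ).raw_score
            assert worse <= previous + 1e-12
            previous = worse


def test_spurious_target_claims_never_raise_n1_specificity(bundle):
    eligible = [e for e in bundle.spectra.entries if e.frag_mode in ("HCD", "EThcD")]
    base_psms = [_target_psm(e) for e in eligible[:4]]
    previous = None
    for n_spurious in (0, 1, 3, 8):
        spurious = [_target_psm(eligible[0], spectrum_id=f"B:scan=5550{i}")
                    for i in range(n_spurious)]
        report = make_report(modes=("HCD", "EThcD"), psms=base_psms + spurious)
        got = score_synthetic_glycopeptide(report, bundle.spectra)
        if previous is not None:
            assert got.specificity <= previous + 1e-12
        previous = got.specificity


def test_bounded_scores_lie_in_unit_interval(small_cohort, bundle):
    from glycobench.performance_tests import run_all_tests

    results, _ = run_all_tests(small_cohort.reports, bundle)
    for result in results:
        if result.test_id in ("N4", "O3"):
            assert result.raw_score >= 0
        elif result.applicable:
            assert 0.0 <= result.raw_score <= 1.0
            for component in (result.sensitivity, result.specificity):
                if component is not None:
                    assert 0.0 <= component <= 1.0
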