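"""Shared fixtures: the packaged reference bundle, hand-built reports and
small simulated cohorts."""

from __future__ import annotations

import itertools

import pytest

from glycobench.glyco_model import parse_composition
from glycobench.reference_sets import load_bundle
from glycobench.report_io import GlycoPSM, SearchSettings, TeamReport
from glycobench.synthetic_data import CohortConfig, simulate_cohort

_counter = itertools.count(1)

DEFAULT_N_SPACE = (
    "Hex5HexNAc4NeuAc2",
    "Hex5HexNAc4Fuc1NeuAc2",
    "Hex5HexNAc4NeuAc1NeuGc1",  # NeuGc decoy class
    "Hex3HexNAc4Fuc2",  # multi-Fuc decoy class
    "Hex2HexNAc2",
    "Hex9HexNAc2",
)
DEFAULT_O_SPACE = (
    "Hex1HexNAc1NeuAc1",
    "Hex1HexNAc1NeuAc1NeuGc1",
    "Hex1HexNAc1Fuc2",
    "Hex1HexNAc1",
)


def make_settings(**overrides) -> SearchSettings:
    base = dict(
        ss1_n_space_size=30, ss2_o_space_size=10, ss3_engine="Byonic",
        ss4_engine_type=1, ss5_recalibration=0, ss6_protease=-1,
        ss7_missed_cleavages=2, ss8_varmod_types=2, ss9_max_glycans_per_peptide=1,
        ss10_max_other_varmods=1, ss11_precursor_tol=1, ss12_product_tol=2,
        ss13_fdr_db=2,
    )
    base.update(overrides)
    return SearchSettings(**base)


def make_psm(team_id="t1", **overrides) -> GlycoPSM:
    base = dict(
        team_id=team_id,
        file_id="B",
        spectrum_id=f"B:scan={next(_counter)}",
        frag_mode="HCD",
        peptide="EVFVHPNYSK",
        protein="P01009",
        composition=parse_composition("Hex5HexNAc4NeuAc2"),
        analyte="N",
        charge=3,
    )
    base.update(overrides)
    if isinstance(base["composition"], str):
        base["composition"] = parse_composition(base["composition"])
    return GlycoPSM(**base)


def make_report(team_id="t1", group="developer",
                modes=("HCD", "EThcD", "ETciD", "CID"),
                psms=(), n_space=DEFAULT_N_SPACE, o_space=DEFAULT_O_SPACE,
                **settings_overrides) -> TeamReport:
    return TeamReport(
        team_id=team_id,
        group=group,
        frag_modes_used=frozenset(modes),
        settings=make_settings(**settings_overrides),
        n_search_space=tuple(sorted(parse_composition(c) for c in n_space)),
        o_search_space=tuple(sorted(parse_composition(c) for c in o_space)),
        psms=tuple(psms),
    )


@pytest.fixture(scope="session")
def bundle():
    return load_bundle()


@pytest.fixture(scope="session")
def small_cohort(bundle):
    """Six teams over reduced pools: fast, full pipeline coverage."""
    cfg = CohortConfig(
        seed=20250930, n_teams=6, n_pool_size=300, o_pool_size=150,
        n_protein_pool=60, o_protein_pool=40,
        n_psm_range=(49, 400), o_psm_range=(5, 100),
    )
    return simulate_cohort(cfg, bundle)


@pytest.fixture(scope="session")
def perfect_cohort(bundle):
    """Error-free cohort: fidelity 1, no injections, both files processed."""
    cfg = CohortConfig(
        seed=11, n_teams=4, fidelity=(1.0,) * 4, neugc_rate=0.0, multifuc_rate=0.0,
        n_pool_size=200, o_pool_size=100, n_protein_pool=50, o_protein_pool=30,
        n_psm_range=(100, 200), o_psm_range=(20, 50),
        n_teams_without_a=0, n_teams_without_o=0, adduct_rate=0.0,
    )
    return simulate_cohort(cfg, bundle)
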