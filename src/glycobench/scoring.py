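"""Score normalisation, overall scores, ranking, global sensitivity/
specificity, and the glycoprotein-centric validation score.

Raw test scores are normalised to [0, 1] across teams per test (default:
divide by the best team's score, so at least one team attains 1; a min-max
variant is available).  The overall N and O scores are the means of a team's
normalised applicable tests, ranked within the developer and user groups
separately (normalisation is joint across all teams).

The global sensitivity/specificity scores regroup normalised test components
for search-strategy comparison: for N-glycopeptides, sensitivity averages the
synthetic-glycopeptide (N1) and source-protein (N3) sensitivity components
with the coverage (N4) and consensus (N5) scores; specificity averages the N1
and N3 specificity components with the glycan-composition (N2) and
NeuGc/multi-Fuc (N6) scores.  For O-glycopeptides, sensitivity averages the
O2 sensitivity component with O3 and O4, and specificity the O1 score, the O2
specificity component and O5.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .performance_tests import TEST_IDS, TestResult
from .reference_sets import SiteGlycoformTable
from .report_io import TeamReport

__all__ = [
    "Scorecard",
    "normalize_scores",
    "build_scorecard",
    "global_perf",
    "glycoprotein_validation",
    "pearson_r2",
    "heatmap_table",
]

_GLOBAL_COMPONENTS = {
    # analyte -> side -> list of (test_id, column) pairs entering the mean
    "N": {
        "sensitivity": [("N1", "norm_sensitivity"), ("N3", "norm_sensitivity"),
                        ("N4", "normalized"), ("N5", "normalized")],
        "specificity": [("N1", "norm_specificity"), ("N2", "normalized"),
                        ("N3", "norm_specificity"), ("N6", "normalized")],
    },
    "O": {
        "sensitivity": [("O2", "norm_sensitivity"), ("O3", "normalized"),
                        ("O4", "normalized")],
        "specificity": [("O1", "normalized"), ("O2", "norm_specificity"),
                        ("O5", "normalized")],
    },
}


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson_r2 needs two equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r2 undefined for zero-variance input")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def _normalize_column(frame: pd.DataFrame, source: str, target: str, method: str) -> None:
    """Normalise ``source`` within each test across applicable teams into ``target``."""
    frame[target] = np.nan
    for test_id, group in frame.groupby("test_id"):
        mask = group["applicable"] & group[source].notna()
        if not mask.any():
            continue
        values = group.loc[mask, source].astype(float)
        peak = values.max()
        if method == "divide_by_max":
            if peak == 0:
                warnings.warn(f"{test_id}: all {source} scores are 0; normalised to 0",
                              stacklevel=2)
                normed = values * 0.0
            else:
                normed = values / peak
        elif method == "min_max":
            low = values.min()
            if peak == low:
                normed = values * 0.0 + (1.0 if peak > 0 else 0.0)
            else:
                normed = (values - low) / (peak - low)
        else:
            raise ValueError(f"unknown normalization method {method!r}")
        frame.loc[normed.index, target] = normed


def normalize_scores(
    results: Sequence[TestResult], method: str = "divide_by_max"
) -> pd.DataFrame:
    """Long-format score table with cross-team normalised columns.

    Columns: team_id, test_id, raw, sensitivity, specificity, applicable,
    normalized, norm_sensitivity, norm_specificity.  Inapplicable results
    keep NaN in every normalised column.
    """
    frame = pd.DataFrame(
        {
            "team_id": [r.team_id for r in results],
            "test_id": [r.test_id for r in results],
            "raw": [r.raw_score for r in results],
            "sensitivity": [r.sensitivity for r in results],
            "specificity": [r.specificity for r in results],
            "applicable": [r.applicable for r in results],
        }
    )
    if frame.duplicated(["team_id", "test_id"]).any():
        raise ValueError("duplicate (team, test) results")
    _normalize_column(frame, "raw", "normalized", method)
    _normalize_column(frame, "sensitivity", "norm_sensitivity", method)
    _normalize_column(frame, "specificity", "norm_specificity", method)
    frame.loc[~frame["applicable"], ["normalized", "norm_sensitivity", "norm_specificity"]] = np.nan
    return frame


@dataclass(frozen=True)
class Scorecard:
    """Per-team scores: the long normalised table plus the per-team summary
    (overall N/O scores, within-group ranks and high-performance band)."""

    scores: pd.DataFrame = field(repr=False)
    summary: pd.DataFrame = field(repr=False)
    normalization: str = "divide_by_max"

    def overall(self, team_id: str, analyte: str) -> float:
        return float(self.summary.loc[team_id, f"overall_{analyte.lower()}"])


def build_scorecard(
    results: Sequence[TestResult],
    groups: Mapping[str, str],
    *,
    normalization: str = "divide_by_max",
) -> Scorecard:
    """Normalise results, compute overall N/O scores and within-group ranks.

    Normalisation is joint across all teams; ranking is separate for the
    developer and user groups, descending overall score, ties sharing the
    better (minimum) rank.  The top third (ceil(n/3)) of each group forms the
    high-performance band.  A team with no applicable test for an analyte is
    left unranked (NaN) there.
    """
    scores = normalize_scores(results, method=normalization)
    teams = sorted(groups)
    rows = []
    for team in teams:
        row: dict[str, object] = {"team_id": team, "group": groups[team]}
        mine = scores[scores["team_id"] == team]
        for analyte in ("N", "O"):
            subset = mine[mine["test_id"].isin(TEST_IDS[analyte]) & mine["applicable"]]
            row[f"overall_{analyte.lower()}"] = (
                float(subset["normalized"].mean()) if len(subset) else np.nan
            )
            row[f"n_applicable_{analyte.lower()}"] = int(len(subset))
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("team_id")
    for analyte in ("n", "o"):
        summary[f"rank_{analyte}"] = np.nan
        summary[f"high_band_{analyte}"] = False
        for _, members in summary.groupby("group").groups.items():
            overall = summary.loc[members, f"overall_{analyte}"]
            ranks = overall.rank(method="min", ascending=False)
            summary.loc[members, f"rank_{analyte}"] = ranks
            band = math.ceil(overall.notna().sum() / 3)
            summary.loc[members, f"high_band_{analyte}"] = ranks <= band
    # deterministic display order: by group, rank, then team id
    summary = summary.sort_values(["group", "rank_n", "overall_n"],
                                  ascending=[True, True, False], kind="stable")
    return Scorecard(scores=scores, summary=summary, normalization=normalization)


def heatmap_table(scorecard: Scorecard, analyte: str = "N") -> pd.DataFrame:
    """Wide team x test table of normalised scores (heatmap layout)."""
    subset = scorecard.scores[scorecard.scores["test_id"].isin(TEST_IDS[analyte])]
    return subset.pivot(index="team_id", columns="test_id", values="normalized")


def global_perf(scores: pd.DataFrame) -> pd.DataFrame:
    """Global sensitivity and specificity scores per team and analyte.

    ``scores`` is the output of :func:`normalize_scores`.  Each side averages
    its normalised components; missing components (inapplicable tests) are
    dropped from the mean and counted in the ``*_n_components`` columns.
    """
    teams = sorted(scores["team_id"].unique())
    indexed = scores.set_index(["team_id", "test_id"])
    rows = []
    for team in teams:
        row: dict[str, object] = {"team_id": team}
        for analyte, sides in _GLOBAL_COMPONENTS.items():
            for side, components in sides.items():
                values = []
                for test_id, column in components:
                    try:
                        value = indexed.loc[(team, test_id), column]
                    except KeyError:
                        continue
                    if pd.notna(value):
                        values.append(float(value))
                key = f"{analyte.lower()}_{side}"
                row[key] = float(np.mean(values)) if values else np.nan
                row[f"{key}_n_components"] = len(values)
        rows.append(row)
    return pd.DataFrame(rows).set_index("team_id")


def glycoprotein_validation(
    reports: Sequence[TeamReport],
    table: SiteGlycoformTable,
    *,
    normalization: str = "divide_by_max",
) -> pd.DataFrame:
    """Orthogonal glycoprotein-centric validation score.

    For every validation site, the team's reported glycoform distribution
    (spectral counts over PSMs matching the site's protein and representative
    peptide) is dotted with the actual distribution (specificity) and its
    unique glycoforms are intersected with the expected list (sensitivity).
    Site scores are summed within each protein, normalised across teams (best
    team set to 1) and averaged over the proteins; the combined score is the
    mean of the overall specificity and sensitivity.  A team reporting none
    of the validation proteins scores 0, flagged by ``n_proteins_reported``.
    """
    proteins = table.proteins
    site_groups = {
        key: group for key, group in table.frame.groupby(["protein", "site"])
    }
    per_team_protein_spec: dict[str, dict[str, float]] = {}
    per_team_protein_sens: dict[str, dict[str, float]] = {}
    reported_proteins: dict[str, set[str]] = {}
    for report in reports:
        spec_by_protein = {p: 0.0 for p in proteins}
        sens_by_protein = {p: 0.0 for p in proteins}
        seen: set[str] = set()
        psms = report.psms_for("N")
        for (protein, _site), group in site_groups.items():
            peptide = group["peptide"].iloc[0]
            site_psms = [p for p in psms if p.protein == protein and p.peptide == peptide]
            actual = dict(zip(group["composition"], group["actual_fraction"]))
            expected = set(group.loc[group["expected"] == 1, "composition"])
            if not site_psms:
                continue
            seen.add(protein)
            counts = Counter(p.composition.canonical() for p in site_psms)
            total = sum(counts.values())
            reported_dist = {comp: n / total for comp, n in counts.items()}
            spec_by_protein[protein] += sum(
                fraction * actual.get(comp, 0.0) for comp, fraction in reported_dist.items()
            )
            if expected:
                sens_by_protein[protein] += len(set(counts) & expected) / len(expected)
        per_team_protein_spec[report.team_id] = spec_by_protein
        per_team_protein_sens[report.team_id] = sens_by_protein
        reported_proteins[report.team_id] = seen

    def _normalise_and_average(per_team: dict[str, dict[str, float]]) -> dict[str, float]:
        overall = {team: 0.0 for team in per_team}
        for protein in proteins:
            values = {team: per_team[team][protein] for team in per_team}
            peak = max(values.values(), default=0.0)
            for team, value in values.items():
                if normalization == "divide_by_max":
                    normed = value / peak if peak > 0 else 0.0
                elif normalization == "min_max":
                    low = min(values.values())
                    normed = (value - low) / (peak - low) if peak > low else (1.0 if peak > 0 else 0.0)
                else:
                    raise ValueError(f"unknown normalization method {normalization!r}")
                overall[team] += normed / len(proteins)
        return overall

    overall_spec = _normalise_and_average(per_team_protein_spec)
    overall_sens = _normalise_and_average(per_team_protein_sens)
    rows = []
    for report in reports:
        team = report.team_id
        combined = (overall_spec[team] + overall_sens[team]) / 2
        rows.append(
            {
                "team_id": team,
                "specificity": overall_spec[team],
                "sensitivity": overall_sens[team],
                "combined": combined,
                "n_proteins_reported": len(reported_proteins[team]),
            }
        )
    return pd.DataFrame(rows).set_index("team_id")
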