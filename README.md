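# glycobench

A community-evaluation framework for glycoproteomics informatics.

Large-scale glycopeptide identification — assigning an intact glycopeptide
(peptide carrier + glycan composition) to each tandem mass spectrum — is
error-prone, and different search engines and search strategies disagree
substantially on the same raw data. `glycobench` implements the benchmarking
machinery used in multi-team evaluations of such software: it ingests
per-team glycopeptide identification reports, scores every team with a
battery of orthogonal performance tests, normalises and ranks the scores,
derives high-confidence consensus glycopeptide lists, validates the ranking
with an independent glycoprotein-centric score, and identifies which search
settings and output characteristics are statistically associated with high
performance. It is aimed at search-engine developers and benchmarking
consortia who need a reproducible, editable scoring pipeline rather than a
one-off spreadsheet analysis.

## The scoring model

Each team *t* submits glycopeptide-to-spectrum matches (glycoPSMs) for
N- and O-glycopeptides plus its glycan search spaces and search settings
(SS1–SS13). Eleven performance tests produce raw scores (six for
N-glycopeptides, N1–N6; five for O, O1–O5), each probing identification
**specificity** (accuracy) or **sensitivity** (coverage):

- **N1 — synthetic glycopeptide.** A spiked synthetic N-glycopeptide
  (EVFVHPNYSK + Hex₅HexNAc₄NeuAc₂) has 12 manually annotated reference
  spectra. With E(t) the reference spectra acquired in fragmentation modes
  team *t* searched, sens = |reported ∩ E(t)| / |E(t)|, spec = |claims
  matching E(t)| / |all target claims|, and raw = sens × spec.
- **N2 / O1 — glycan composition.** Squared Pearson correlation R² between
  the team's spectral-count glycan distribution and the expected serum
  glycan distribution, aligned on the union of compositions.
- **N3 / O2 — source glycoprotein.** Reported source proteins are weighted
  by literature support (two tiers for N, three for O); specificity is the
  PSM-weighted attained fraction of the maximal weight, sensitivity the
  covered fraction of the literature protein universe; raw = their mean.
- **N4 / O3 — glycoproteome coverage.** The count of unique glycopeptides
  (unique peptide sequence + glycan composition, alkali adducts merged).
- **N5 / O4 — consensus recovery.** Fraction recovered of the consensus
  glycopeptides, i.e. those reported by ≥ 50 % (N) or ≥ 30 % (O) of the
  teams returning data for the analyte.
- **N6 / O5 — NeuGc / multi-Fuc absence.** NeuGc and multi-fucosylated
  (Fuc ≥ 2) glycans are essentially absent from human serum, so reporting
  them proxies false positives: raw = mean of the non-NeuGc and
  non-multi-Fuc PSM fractions, applicable only to teams whose search space
  contained those classes.

Raw scores are normalised to [0, 1] across teams (divide-by-best by
default), the overall N and O scores are the per-team means of the
applicable normalised tests, and teams are ranked within the developer and
user groups separately. For strategy comparison, normalised sensitivity
components (N1, N3, N4, N5 / O2, O3, O4) and specificity components
(N1, N2, N3, N6 / O1, O2, O5) are averaged into global sensitivity and
specificity scores. An orthogonal validation score dots each team's
site-specific glycoform distributions (spectral counts at nine sites of
A1AT, CP, HP and IgG1) against the measured "ground-truth" distributions.

Finally, `associate` tests every search setting (SS1–SS13) and search
output variable (SO1–SO9) against every performance score with seven
statistical methods (OLS, permutation-calibrated ridge, cross-validated
lasso, LARS and forward stepwise with multi-split selective inference, and
two tree ensembles with noise-augmented importance cutoffs); only
associations supported by **at least three methods with a consistent
direction** are reported.

Because real team submissions are external data, the package ships a seeded
synthetic cohort generator (`glycobench.synthetic_data`) that emulates the
statistical structure the scoring assumes — per-team reporting fidelity,
near-isobaric glycan confusions (NeuAc ↔ Fuc₂, Δm = 1.0204 Da;
NeuAc₁Hex₁ ↔ NeuGc₁Fuc₁, Δm = 0), NeuGc/multi-Fuc injection and
synthetic-glycopeptide detection — so the full pipeline is testable
end-to-end and parameter recovery can be demonstrated.

## Worked example

Simulate a six-team cohort and score it:

```sh
glycobench simulate --seed 5 --config demo.yaml --out demo
glycobench score --reports demo/teams --out demo/scores
```

with `demo.yaml`:

```yaml
n_teams: 6
n_pool_size: 200
o_pool_size: 100
n_protein_pool: 40
o_protein_pool: 30
n_psm_range: [50, 150]
o_psm_range: [10, 40]
```

`demo/scores/scorecard_summary.csv` then contains:

```
             group  overall_n  overall_o  rank_n  rank_o  high_band_n
team_id
team02   developer      0.761      0.000     1.0     1.0         True
team01   developer      0.727      0.000     2.0     1.0        False
team03        user      0.944      0.948     1.0     1.0         True
team06        user      0.828      0.860     2.0     2.0         True
team05        user      0.751      0.633     3.0     4.0        False
team04        user      0.687      0.794     4.0     3.0        False
```

Each `overall_n` is the mean of that team's normalised N1–N6 scores, ranked
within its group (the two simulated developers returned no O-glycopeptide
data, so their O scores are zero). The companion `heatmap_N.csv` holds the
normalised team × test matrix behind the ranking:

```
           N1    N2    N3    N4    N5    N6
team_id
team01   0.21  0.85  0.93  0.61  0.81  0.95
team02   0.11  0.65  1.00  1.00  1.00  0.80
team03   1.00  0.96  0.94  0.81  0.97  0.98
...
```

Reading team03's row: it recovered every eligible reference spectrum of the
spiked synthetic glycopeptide without spurious claims (N1 = 1.00), its
glycan distribution correlates best-in-cohort with the serum reference
(N2 = 0.96), and its reports are nearly free of NeuGc/multi-Fuc false-
positive proxies (N6 = 0.98). The `score` command also writes the consensus
lists (`consensus_N.csv`, `consensus_O.csv`), the global
sensitivity/specificity table (`global_perf.csv`) and the glycoprotein-
centric validation score (`validation.csv`).

The library surface mirrors the CLI: `read_team_report`, `run_all_tests`,
`build_scorecard`, `derive_consensus`, `global_perf`,
`glycoprotein_validation`, `associate` and `simulate_cohort` compose the
same pipeline in Python.

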