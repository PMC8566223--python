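# Methods

This note documents the scoring model, the design choices made where the
design was genuinely open, the synthetic-data model and its limits, and the
numerical conventions used throughout `glycobench`.

## Identifiers and glycan model

A glycan is a residue-count composition over Hex, HexNAc, Fuc (dHex), NeuAc
and NeuGc; linkage, topology and site localisation are out of scope. The
canonical string is `Hex<h>HexNAc<n>Fuc<f>NeuAc<a>` with `NeuGc<g>` appended
only when g > 0; the parser accepts tokens in any order, underscores and
whitespace, and the `dHex`→Fuc and `Sia`→NeuAc dialect aliases, and rejects
anything else (including xylose and substituted glycans, which the reporting
template excludes by design). A glycopeptide identity is the pair
(uppercased peptide, canonical composition); Na⁺/K⁺-adducted precursors
collapse to the nonadducted identity before any counting, since an adduct
changes the ion, not the analyte.

N-glycan structural classification: *oligomannose* = exactly 2 HexNAc,
≥ 4 Hex, no Fuc and no sialic acid (the Man4+ biosynthetic series);
*truncated* = Hex < 4 **and** HexNAc < 3 **and** Fuc < 2 (the compound
bound is read as a conjunction); *complex* = everything else, hybrid-type
glycans included — a three-way split cannot separate them at composition
level. The oligomannose bound is configurable (`oligomannose_min_hex`), and
oligomannose wins in the (empty under the defaults) overlap with truncated.
Feature labels are assigned with the priority multiFuc > NeuGc > NeuAc >
neutral, so multi-feature glycans are binned exactly once.

## Performance tests

Choices that the test definitions leave open, and how they were resolved:

- **N1 mode adjustment.** "Adjusting for fragmentation modes" is
  implemented as an eligibility filter: only reference spectra acquired in a
  mode the team declared searched enter either denominator. A team claiming
  the target zero times scores 0 with its specificity recorded as undefined
  rather than inventing a 0/0 value.
- **N2/O1 alignment.** The expected and observed distributions are aligned
  on the union of their compositions, zero-filled. Dropping off-reference
  observations instead would *reward* reporting glycans absent from serum;
  zero-filling penalises them. Reports with fewer than two distinct
  compositions (no variance) are inapplicable.
- **N3/O2 specificity.** The natural-language definition mixes PSM-level
  weighting with a unique-protein denominator and is dimensionally
  ambiguous. The default (`psm_weighted`) divides the summed per-PSM protein
  weight by `n_PSMs × max_weight`, which is bounded, abundance-aware and
  reduces to the literal unique-protein reading when every protein carries
  one PSM; the `unique_protein` variant is selectable and both values appear
  in the result details. The raw score combines specificity and sensitivity
  by arithmetic mean (product available via `combine="product"`): the mean
  keeps the two [0, 1] components commensurate.
- **Consensus threshold.** Membership uses an inclusive comparison
  (support/universe ≥ threshold), with a strict mode in the API. The team
  universe is the set of teams that returned any data for the analyte, so
  teams skipping O-glycopeptide analysis do not deflate O consensus support.
- **N6/O5 applicability.** The test only applies when the team's search
  space contained at least one NeuGc and one multi-Fuc composition — a team
  that never searched those classes provides no evidence either way. When
  exactly one class was searchable the score is that single fraction,
  flagged in the details.

## Scoring, ranking, validation

Normalisation is divide-by-best by default (the only scheme the validation
scoring verbalises: "best set to 1"); min–max is available. Normalisation is
joint across all teams; ranking is separate within the developer and user
groups because the groups operated under different instructions and are not
comparable. Ties share the better (minimum) rank; display order breaks ties
by team id only. The top ⌈n/3⌉ of each group forms the high-performance
band. A team with no applicable test for an analyte has no overall score
there and is left unranked. Inapplicable tests never enter any mean.

Global sensitivity averages the N1 and N3 sensitivity components with the
normalised N4 and N5 scores (O: O2-sens, O3, O4); global specificity
averages the N1 and N3 specificity components with normalised N2 and N6
(O: O1, O2-spec, O5). Tests without separate components contribute their
single normalised score to the side their construction supports.

The glycoprotein-centric validation maps reported PSMs to the nine
validation sites via each site's representative tryptic peptide (site
free-text in reports is too inconsistent to score, so peptide identity is
the mapping key — a documented fixture column, editable per site). Site
specificity is the dot product of the reported spectral-count glycoform
distribution with the actual distribution; site sensitivity is the covered
fraction of the expected glycoform list. Both are summed within protein,
normalised across teams per protein and averaged over the four proteins;
the combined score is the mean of the two.

## Association analysis

Team-level predictors (the numeric search settings SS1–SS13, excluding the
free-text engine label, plus the search-output averages SO1–SO9) are
standardised; constant predictors are dropped with a warning. Seven methods
flag (predictor, response, direction) candidates; an association is
*reported* only when ≥ 3 methods agree with a consistent direction
(conflicting directions drop the candidate with a conflict flag). The
methods are deliberately calibrated so that each controls its own error at
the 0.05 level on the full predictor family:

1. OLS with per-coefficient p < 0.05 (the one method whose criterion is
   fixed by convention);
2. ridge at a cross-validated penalty with a max-statistic response-
   permutation test (family-wise), 199 permutations;
3. lasso at the cross-validated penalty chosen by the one-standard-error
   rule;
4. LARS (≤ 3 active terms) with selective inference approximated by
   multi-split sample splitting — 20 random half-splits, selection on one
   half, OLS testing on the held-out half with Bonferroni correction for
   the selected-model size, median-p aggregation;
5. forward stepwise (BIC-guided) with the same multi-split scheme;
6. random forest and 7. gradient-boosted trees (100 trees) with a
   noise-augmented importance cutoff: a permuted shadow copy of every
   predictor is appended and a real predictor must beat both the largest
   shadow importance and the 95th percentile of the maximum real-feature
   importance over 20 response-permutation refits. Tree importances are
   unsigned; direction comes from the predictor–response Spearman sign.

Sample splitting and permutation calibration replace exact post-selection
machinery (induced smoothing, exact LARS inference, selective inference)
with standard, verifiable constructions; the consensus-of-≥3 filter, not
any single method, is the reported surface. Everything is deterministic
given the seed. At least 8 teams are required; OLS is skipped with a
warning when teams ≤ predictors + 1.

## Synthetic cohort generator

The generator emulates the statistical structure the scoring assumes, at
the scale of the motivating community study. Defaults: 22 teams (9
developers, 13 users), per-team N-glycoPSM counts log-uniform in 49–2,122
and O counts in 5–578, glycan search spaces of 23–381 (N) and 3–223 (O)
compositions, 2 developer teams returning no O data, 2 teams processing
only File B, reference-spectrum detection probability 1.0 scaled by team
fidelity, spurious target-claim rate 0.5 scaled by (1 − fidelity), 3 %
alkali-adducted PSMs, and NeuGc / multi-Fuc injection rates of 2 % each —
mid-range values for the heterogeneous per-team rates observed in practice.

Ground truth: a pool of 2,556 N- and 1,192 O-glycopeptide records (the
collective counts of the motivating study) on 320 / 231 source proteins
whose accessions and literature weights come from the reference bundle;
high-weight proteins receive proportionally higher abundance, and the nine
validation sites enter with their fixture glycoform distributions at
high-abundance-protein levels. Peptides are random tryptic-like sequences
(C-terminal K/R) containing an N-sequon (N-X≠P-S/T) or an S/T.

Error channels: each sampled PSM is reported faithfully with probability
*f* (the team's fidelity); otherwise it is corrupted — by a near-isobaric
composition substitution (NeuAc ↔ Fuc₂, Δm = 1.0204 Da; NeuAc₁Hex₁ ↔
NeuGc₁Fuc₁, Δm = 0) or by source-protein misassignment, at 0.7/0.3
conditional weights. The corruption of a given ground-truth record is drawn
once per team and reused, because a search engine misassigns a given
precursor consistently rather than independently per spectrum. NeuGc and
multi-Fuc injections are independent per-PSM Bernoulli events on top,
modelling search-space-driven false positives; consistently, a nonzero
injection rate requires the corresponding decoy class in the team's search
space. All randomness flows from a single seed, with per-team substreams
keyed by a stable hash of the team id, so a report is reproducible
independent of cohort size.

For strategy grids, `decoy_level` (an SS13 analogue) scales the injection
rates and PSM yield in opposite directions (no decoy database → more
identifications, more false positives), and `space_fdr_coupling` optionally
couples glycan-search-space breadth to both; both are neutral by default so
ordinary cohorts are not affected.

What the generator does **not** emulate: spectra and fragment evidence,
retention-time or mass-error structure beyond plausible ranges, engine-
specific score distributions, chimeric spectra, and site-localisation
ambiguity. Passing tests therefore demonstrate that the *scoring pipeline*
recovers structure that is genuinely present in reports; they say nothing
about how well any real search engine identifies glycopeptides.

## Parameter recovery and problem sizes

Parameter-recovery experiments hold nuisance variation fixed so that the
varied parameter is the only systematic difference between teams: the
fidelity sweep uses 20 teams at a fixed 1,000 N-PSM depth with fidelity on
a 0.3–1.0 grid, and the NeuGc calibration uses fidelity 1 with a 10 %
injection rate at 1,000 PSMs, where the expected score is (0.9 + 1)/2 =
0.95 with a binomial standard error of ≈ 0.005. Association experiments use
22 teams × 10 standardised predictors with a planted coefficient ten times
the noise standard deviation, and pure-noise responses for the null; 20
seeds per condition. Oracle-equivalence checks run on 8 teams over a pool
of ≤ 50 identities so exhaustive enumeration stays instant. These sizes
keep the full suite and the acceptance script within a few minutes on one
CPU while leaving the statistical margins comfortable.

## Numerical conventions and degenerate inputs

Units: retention time minutes, masses Da ([M+H]⁺ for glycopeptide mass),
mass errors ppm; SO4/SO6 use absolute values. Monosaccharide residue
masses (Da): Hex 162.0528, HexNAc 203.0794, Fuc 146.0579, NeuAc 291.0954,
NeuGc 307.0903. SO8 is recomputed from the canonical composition rather
than trusted from reports. Reference distributions must sum to 1 within
1e-6 (then renormalised exactly); site glycoform fractions likewise per
site. Correlation-based scores require nonzero variance on both sides and
are inapplicable otherwise; divide-by-max normalisation of an all-zero test
column yields zeros with a warning. Missing per-PSM numeric fields are
skipped in averages, never imputed. Malformed PSM rows are rejected
individually with row-level diagnostics; a report with zero valid PSMs is
returned with a warning so cohort-level accounting still sees the team.

## Known limitations

- Site localisation is carried as free text and never scored.
- O-glycans receive no structural classification (feature labels only);
  multi-fucosylation on multi-glycan O-peptides cannot be distinguished
  from genuine multi-Fuc single glycans at composition level.
- The shipped reference bundle is a constructed, composition-level stand-in
  for the serum glycomics literature (see `reference_sets`); conclusions
  about real submissions require replacing it with curated tables.
- The N3 specificity ambiguity is resolved by choosing one bounded reading;
  neither variant is asserted to be the motivating study's exact
  computation.
- Scores are relative within a cohort (normalised to its best team), so
  they are not comparable across cohorts scored separately.
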