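# Methods

## Overview

`tertscape` implements a cohort-level transcriptomic comparison keyed to the
expression status of a marker gene (telomerase reverse transcriptase, TERT,
by default). The pipeline is: sample QC → gene-identifier aggregation →
library-size normalization → case-to-normal ratios (CNR) → pathway
activation levels (PAL) → marker stratification → Spearman correlation
screens → differential genes/pathways → retroelement subfamily comparison.
Each stage is an importable function; the CLI and `run_pipeline` only
orchestrate.

## Normalization and CNR

Size factors use the median-of-ratios method: for sample *j*,
s<sub>j</sub> = median over genes *g* (restricted to genes with strictly
positive counts in every sample) of c<sub>gj</sub> / geomean(c<sub>g·</sub>).
When no gene is positive everywhere, an explicit fallback uses genes
positive in ≥ 50% of samples with geometric means over the positive entries;
the default raises instead, because silently changing the reference set can
move every downstream ratio. Median-of-ratios factors are defined only up
to a common rescaling of the reference, so the meaningful invariants —
asserted as property tests — are that size-factor *ratios* scale linearly
with per-sample count scaling and that normalized values are invariant up
to one global scalar.

CNR is computed on normalized values (normalization before ratio removes
library-size artifacts from the case/control comparison; the alternative
orders are not equivalent and the choice is deliberate). The control
average is the arithmetic mean of the same-tumor-type controls (a
geometric-mean option exists). A pseudocount of 1 on both numerator and
denominator keeps ratios finite and maps "zero everywhere" to CNR = 1,
i.e. zero log-ratio — the neutral value. Every tumor type must have at
least one control; 4–6 controls per type is the intended regime.

## Pathway activation level

PAL<sub>p</sub> = 100 · Σ<sub>n</sub> ARR<sub>np</sub> · log10(CNR<sub>n</sub>)
/ Σ<sub>n</sub> |ARR<sub>np</sub>|, summed over the pathway's member genes
present in the CNR matrix. The denominator uses |ARR|: with the raw signed
sum the quantity is not a weighted mean (the denominator can be zero or
negative for inhibitor-rich pathways), so the modulus is the only reading
under which PAL is a convex combination of signed log-ratios. An
"as-printed" signed-denominator mode is provided for comparison but is not
the default. Cells where no member gene with a non-zero role is present
are *undefined* — reported as NaN in memory and the literal token `NA` on
disk, never silently zero — and a coverage sidecar records how many member
genes were found per cell. `min_coverage` (default 1) can further mask
thinly covered cells.

## Statistics

- **Spearman** rho on average ranks with the two-sided t-approximation
  p-value for all n; |rho| within 1e-12 of 1 is snapped to ±1 with p = 0.
- **Mann-Whitney U**, two-sided: exact by enumeration when both groups have
  ≤ 8 observations and the pooled data are tie-free, otherwise the normal
  approximation with tie and continuity corrections. Pooled-constant input
  returns the null-expectation U with p = 1.
- **BH-FDR** step-up adjustment; genes and pathways are corrected as
  separate families because they are reported separately (a single-family
  mode is a caller choice — pass the combined vector).
- **Over-representation**: upper-tail hypergeometric probability of the
  observed overlap, BH-adjusted across terms.

These wrap scipy/statsmodels; the test suite checks them against
independent oracles (full enumeration of labelings for the exact U branch,
hand-computed step-up vectors, combinatorial tail sums).

## Stratification and screens

TERT+ is defined as raw marker count > 0. This is deliberately crude: with
a true zero mode, any positive read count is evidence of transcription, and
the synthetic-cohort confusion matrix quantifies the residual
misclassification (marker-positive samples whose negative-binomial draw
happened to be 0). A `norm_threshold` mode (normalized value > τ) exists
for cohorts where the zero mode is contaminated.

Screens correlate each feature with the marker's *normalized* expression
across tumor samples — Spearman is invariant to monotone per-feature
transforms but not to per-sample scaling, so the unit matters and is kept
consistent with the differential stage. A feature passes at |rho| > 0.3
(strict, literal reading of "more than") and BH p < 0.05; the strong tier
is |rho| ≥ 0.4 (inclusive, literal reading of "starting from"). Undefined
PAL cells are handled pairwise-complete with per-feature n recorded;
features with fewer than 3 complete pairs or constant values are flagged
untestable and excluded from the BH family.

## Differential activation

Genes: per-gene Mann-Whitney between strata on normalized values, BH across
genes, significance requiring adjusted p < 0.05 *and* |log2 fold change| >
1 (fold change 2), with fold changes computed on group means with
pseudocount 1. The threshold is configurable because both "FC > 2" and
"|log2FC| > 2" appear in the literature for this kind of analysis; fold
change 2 is the default. The rank test is a deliberate surrogate for a
negative-binomial GLM Wald test: it needs no dispersion model, is robust to
the heavy tails of FFPE-derived counts, and nothing downstream depends on
matching GLM coefficients.

Pathways: the same test on PAL values with no fold-change rule (PAL is
already an effect-size-like quantity on a symmetric scale); reported with
per-group mean PAL and their difference. Pathways whose defined cells
leave a group below 2 samples are excluded and listed.

Promoter-mutation contrasts (TERTmut vs TERTwt) reuse `differential_genes`
restricted to the genes of interest; there is no special code path.

## Retroelements

TE instance counts are summed into subfamily totals (L1HS, L1PA2 expected).
Size factors come from the *gene* matrix only and are then applied to the
TE rows — a handful of high-count TE features must not influence the
library-size estimate — and the per-sample rank order of TE features is
unchanged by this scaling (tested). Subfamily-level rather than
instance-level testing is used throughout.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline targets, not
any particular dataset:

- **Cohort shape** (defaults): 5 tumor types × 40 tumors = 200 tumor
  samples, 5 controls per type, 1000 genes + the marker. These sizes keep
  a full pipeline run in seconds while leaving the screens well-powered.
- **Marker**: latent activity t<sub>j</sub> = 0 with probability 0.27
  (the bimodal zero mode), else lognormal(μ = 3, σ = 1) — median ≈ 20
  counts, far enough from zero that negative-binomial zeros among true
  positives are rare. Marker counts are NB around t<sub>j</sub> and exactly
  0 when t<sub>j</sub> = 0. Controls do not express the marker.
- **Correlated modules**: 30 positive + 30 negative genes load on the
  standardized *rank* of t<sub>j</sub> with loading 0.6 on the natural-log
  scale. Planting through a rank-based latent factor guarantees the
  monotone association a Spearman screen is designed for; 0.6 gives true
  |rho| comfortably above 0.5 at n = 200 under the NB noise.
- **Pathways**: 50 pathways of 5–15 members; 30% are "active" — their
  members are dedicated genes whose expression shifts by ±1 log2 unit
  (sign matching the member's ARR role) in marker-positive samples, so
  active pathways have positive expected PAL in marker-positive tumors and
  ≈ 0 in marker-negative ones. Null pathways draw members from null genes
  with random roles (10% ambiguous).
- **Noise**: negative binomial with variance μ + μ²/k, k = 10 shared across
  genes; per-gene lognormal baselines (median ≈ 100 counts) and per-type
  lognormal factors (σ = 0.3) so CNR against same-type controls is
  exercised nontrivially. Synthetic library sizes are ~10⁵ reads, so
  pipeline runs on synthetic data use a correspondingly scaled QC
  threshold.
- **Mutation labels**: 13% of marker-positive tumors get a promoter
  mutation label (C228T 70% / C250T 30%) with *no* expression effect — a
  planted null emulating the finding that promoter mutations do not raise
  marker expression among expressing tumors.
- **Retroelements**: 4 instances each of L1HS and L1PA2, elevated 3-fold
  in marker-negative tumors.

Everything derives from one `numpy` Generator seeded from `SimConfig.seed`;
same seed ⇒ byte-identical output files.

What the generator does **not** emulate: batch/FFPE artifacts, gene-length
effects, realistic pathway topologies or overlapping pathway membership,
between-gene correlation beyond the single latent factor, and cohort-scale
pathway libraries (real libraries have thousands of pathways). Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct under its own model assumptions — not that those assumptions hold
for any particular real cohort.

## Recovery evaluation

`truth_eval` scores outputs against the planted truth: recall/precision and
null false-discovery proportion of the correlated-gene screen, recall and
null FDP of active-pathway detection, the stratum confusion matrix, and the
TE direction. Active-pathway detection is evaluated on the PAL correlation
screen: the between-strata rank test at cohort scale can pick up a small
normalization composition effect on null pathways (planted shifted genes
perturb all normalized values slightly — a real phenomenon, not a bug),
whereas the screen's |rho| > 0.3 requirement is the planted-structure
criterion the generator is calibrated to.

## Bundled reference tables

`tertscape.datasets` ships the aggregate tables of the published
pan-cancer cohort the pipeline targets (per-type stratum counts, the
strong-tier TF correlation table, promoter-assay margins, published
discovery counts). The patient-level data are access-restricted, so these
aggregates are bookkeeping inputs only. `load_promoter_assay` is a
synthetic per-sample expansion: its per-type margins are exact, but the
assignment of expression status to individual wild-type cases is not
identifiable from published aggregates and is made arbitrarily subject to
the published totals (81 expressing wild-type, 12 expressing mutant).

## Numerical and degenerate-input choices

- QC threshold boundary is inclusive (≥ 3.5 × 10⁶ gene-mapped reads by
  default).
- Gene-id aggregation sums counts of sources sharing a target symbol,
  preserving total gene-mapped reads; unmapped sources are dropped by
  default.
- Merged count matrices order genes lexicographically for deterministic
  output files.
- Undefined values serialize as `NA`; tables are TSV, UTF-8, `.` decimal.
- p-values are capped at 1; BH inputs outside [0, 1] are rejected rather
  than clipped.
- Enumerations in sample tables are strict: unknown strings are errors,
  only the empty string coerces (to `unset`/`unknown`).
- Exit codes: 0 success, 2 configuration error, 3 data-contract error.

## Known limitations

- The rank-test differential stage has less power than a parametric NB
  model at small n and does not shrink dispersions; counts close between
  groups need larger cohorts.
- PAL treats member genes as exchangeable (no topology or importance
  weighting).
- The raw-zero stratification rule is sensitive to library size at very
  low marker expression; use the normalized-threshold mode for shallow
  libraries.
- BH families are per screen; running many screens still multiplies
  family-level error.
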