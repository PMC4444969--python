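# Methods

## Model

Each genomic position carries a latent binary indicator of function `Z` with
prior `π = P(Z = 1)`. Conditional on `Z`, the `m` annotations are independent
("all annotations are consequences of function, and are connected only
through it"), so each class-conditional joint density factorizes into
per-annotation terms: Normal(μ_{i,z}, σ_{i,z}²) for continuous conservation
scores, Bernoulli(p_{i,z}) for binarized biochemical indicators. The observed
data distribution is the two-component mixture `π f₁ + (1 − π) f₀`, and the
functional score of a position is the posterior `P(Z = 1 | Y)`.

The default schema fixes 22 annotations — GERP and PhyloP (continuous,
conservation), DNase and FAIRE (open chromatin), eight histone marks, ten
TFBS indicators — giving 49 free parameters (`1 + 4·2 + 2·20`). The schema is
an explicit, ordered object: it defines the matrix column order, the
parameter layout, and the group structure used for group-conditional
posteriors, so non-default layouts are first-class.

### Assumptions and their consequences

* **Conditional independence given Z.** Correlation between annotations
  beyond class membership (e.g. between two histone marks) is not modelled;
  it inflates confidence rather than biasing the class means. The
  supported robustness check is refitting after removing annotations
  (`AnnotationSchema.subset_schema`), which in tests moves shared estimates
  by < 0.05.
* **Positionwise independence.** No spatial smoothing; any along-chromosome
  structure in scores comes entirely from the data.
* **Binarized biochemistry.** Peak strength is discarded; a position is 1
  for an annotation iff it falls in a peak of at least one cell line
  (union rule, implemented as membership in the merged union of all
  cell-line interval sets).

## Estimation

Parameters are fitted by EM on unlabelled rows.

* **E-step**: responsibilities are the posterior scores under current
  parameters; the observed-data log-likelihood is accumulated with
  `logaddexp`.
* **M-step**: closed-form weighted moments — `π` is the mean responsibility,
  Bernoulli rates are responsibility-weighted frequencies, Normal moments
  are responsibility-weighted means/SDs computed over observed cells only.
* **Initialization** (`quantile_split`, default): rows are ranked by the mean
  of their standardized observed continuous values; the top 40% seed class 1,
  moments come from that hard split, and π starts at 0.4. Conservation
  carries the strongest marginal class signal, which makes this start both
  deterministic and close to the basin of the dominant optimum. A seeded
  `random_responsibilities` strategy (uniform weights on (0.25, 0.75), one
  M-step) is available for restart studies.
* **Convergence**: relative log-likelihood change below 1e-8 (default), at
  most 1000 iterations; non-convergence is reported in the result, not
  raised. With several restarts the highest final log-likelihood wins, ties
  to the lowest restart index. All randomness flows through one recorded
  seed.
* **Component anchoring**: mixtures are label-exchangeable, so after fitting,
  components are swapped (and `π ↦ 1 − π`, responsibilities complemented) if
  the mean of `μ₁ − μ₀` over continuous annotations is negative. An exact tie
  leaves labels unchanged and records a warning. EM started from mirrored
  parameters follows the mirrored trajectory exactly, so anchored scores are
  identical across mirrored restarts (tested to 1e-6).

### Missing data

Only continuous (conservation) columns may be missing; binary columns are
validated as complete. Three policies are implemented and selectable:

* `marginalize` (fitting default) — a missing cell drops out of the
  factorized product; statistically clean under conditional independence.
* `impute_neutral_zero` (scoring default in the CLI) — missing conservation
  is replaced by the neutral score 0, matching how genome-wide scores are
  produced when a constraint track has no value at a base.
* `complete_case` — rows with any missing cell are removed before fitting;
  retained row indices are recorded in the result.

All three agree exactly when nothing is missing (tested).

## Numerical choices

* All densities are computed as sums of logs; with 22 factors, raw products
  underflow doubles. The posterior uses a stabilized Bayes ratio on the log
  density difference, arranged so that `log f₁ = log f₀` yields exactly `π`
  and degenerate priors yield exactly 0 or 1.
* Bernoulli estimates are clamped to `[1e-6, 1 − 1e-6]` and standard
  deviations floored at `1e-3` to keep the log-likelihood finite on
  degenerate columns; an odds ratio computed at a clamp boundary carries a
  warning.
* Dispersion is stored as a standard deviation (unit-consistent with the
  score scale, unambiguous in serialization); parameter files print floats
  with `repr`, making the text round trip bit-exact.
* The functional-proportion cutoff counts ties as functional (`≥`); ties have
  measure zero for continuous scores, and this choice keeps call rates
  conservative-upward at the conventional 0.5 cutoff.
* AUC is the Mann–Whitney rank statistic with midrank ties — exact on small
  inputs, unlike trapezoidal ROC integration.
* Interval arithmetic is uniform: stored intervals are 0-based half-open,
  user-facing SNP and matrix positions 1-based, with one conversion helper
  pair. "Removing overlapping coordinates" of an interval collection is
  implemented as interval union (merge); deduplicating repeated bases gives
  the same coverage, so the distinction is immaterial for coverage
  statistics. A SNP at 1-based `p` expands to the 0-based window
  `[p − 501, p + 499)` — exactly 1 kb spanning 500 bp upstream through 499 bp
  downstream — and windows overlapping the chromosome start are clipped and
  flagged.

## Synthetic data

The generator draws from exactly the model the estimator assumes. Defaults
(`default_parameters`): `π = 0.4`; continuous annotations Normal(0, 1) in the
background class and Normal(1.5, 1) in the functional class — a 1.5 SD shift,
the qualitative separation real constraint scores show; binary background
rates in [0.02, 0.3] and functional rates in [0.3, 0.9], fixed per
annotation, with one deliberately near-uninformative repressive mark
(H3K27me3: 0.72 background vs 0.80 functional, odds ratio ≈ 1.556) so that
marginal-effect summaries have a known near-null case.

`simulate_toy_genome` adds interval-level structure: non-overlapping
functional segments (200–1500 bp) placed uniformly on a toy chromosome,
per-position annotations drawn conditional on segment membership, each binary
annotation's positive runs split randomly but union-preservingly across cell
lines (so the binarization rule is exercised nontrivially), and SNPs sampled
inside and outside the truth segments. Fixtures are written as plain BED /
bedGraph / TSV.

What the generator does **not** emulate: inter-annotation correlation beyond
class membership, spatial autocorrelation of scores within segments,
annotation-specific missingness patterns, and the heavy tails / bimodality of
real conservation-score distributions. Passing tests therefore demonstrate
correctness of the machinery and self-consistency of estimation under the
model's own assumptions — not calibration on real genomes.

## Problem sizes

The test suite and the acceptance script use 200,000 rows for parameter
recovery (recovery errors there are an order of magnitude below the asserted
bounds: prior and Bernoulli rates within 0.02, Normal means within 0.05, SDs
within 10% relative), a 50 kb toy chromosome for the end-to-end pipeline, and
1,000 random instances for posterior/oracle equivalence at 1e-10 relative
tolerance. These sizes were chosen so the full suite completes in well under
a minute while keeping Monte-Carlo error far from the asserted margins;
fitting is vectorized and comfortably handles ~1M rows in memory, though
genome-scale out-of-core fitting is out of scope.

## Known limitations

* No standard errors or confidence intervals on fitted parameters.
* No modelling of signal strength for biochemical annotations, and no
  graphical-model extensions with inter-annotation edges.
* The EM likelihood surface is multimodal in principle; the default
  deterministic initialization targets the conservation-separated optimum,
  and restarts are the supported hedge.
* Region mean scores are computed per supplied interval; no transcript-union
  logic for genes with multiple isoforms.
* The fitted prior reflects the training positions, which need not represent
  the whole genome; the prior-substitution utility (`rescore_with_prior`)
  exists precisely to probe that sensitivity, and under well-separated
  classes the 0.5-cutoff call rate moves by < 0.01 between priors 0.3
  and 0.5.
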