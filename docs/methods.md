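# Methods

## The model and what the pipeline assumes

The pipeline addresses a two-cohort discovery design.  Cohort one is a
single staged cohort (blood, in the motivating DKD setting) whose
samples carry an ordered clinical stage; the scientific hypothesis is
monotone dose–response — expression that rises or falls with disease
severity — and the screen is deliberately nonparametric: the
Jonckheere–Terpstra test uses only the ranks of the values across the
ordered groups, so it is invariant to any strictly increasing transform
of the expression scale and makes no linearity or normality assumption
about the alternative.  Cohort two is a collection of case/control
datasets measured on different platforms with different probe sets; no
attempt is made to merge the expression values themselves.  Instead
each dataset is reduced to per-gene signed evidence (a z-score) and the
evidence is pooled by the weighted Z-method, which assumes only that
each dataset's z is standard normal under its own null and that
datasets are independent.  The cross-cohort claim — that the same genes
surface in both compartments — is quantified by the hypergeometric
upper tail over the universe of genes testable in *both* cohorts; that
intersection universe is the only universe in which membership of both
lists is defined.

## Trend testing

* Statistic: J = Σ_{i<j} Σ pairs [1(x<y) + ½·1(x=y)]; ties contribute
  half a count.
* Null moments: E[J] = (N² − Σn_i²)/4; the variance uses the standard
  tie-corrected three-term formula computed from the pooled
  multiplicities of tied values.  The formula is exact: the test suite
  checks it against full-enumeration moments to 1e-10, with and without
  ties.
* p-values: `exact` enumerates all distinct assignments of the observed
  values to the group sizes (refused above 10⁶ partitions, with Monte
  Carlo suggested); `montecarlo` permutes labels and uses the add-one
  estimator (b+1)/(B+1) so p = 0 is never reported; `asymptotic` uses
  the normal approximation with tie-corrected variance and no
  continuity correction.  `auto` falls back to Monte Carlo when more
  than 20% of values are tied and N ≤ 25, where the normal
  approximation degrades.
* Direction: every gene is tested one-sided both ways and assigned the
  direction with the smaller p (ties toward increasing); it enters the
  up or down list when that p < α.  For α < 0.5 this is identical to
  listing genes with p_direction < α (p_inc + p_dec ≥ 1 makes double
  membership impossible), and at α = 1 it still partitions the genes —
  convenient for exhaustive ranking.
* The screen reports raw p (the discovery convention the design
  follows) plus BH-adjusted columns for information.  Degenerate genes
  (zero tie-corrected variance) are flagged and given p = 1.

The default screening stage set in `AnalysisConfig` is D1 < D2 < D3 —
the three albuminuria stages — with the full five-stage ordering
available by configuration.  In real cohorts the extremes can behave
non-monotonically (healthy controls and end-stage patients may resemble
each other transcriptionally), which is why the conservative three-stage
default exists; the synthetic generator, by contrast, plants a clean
monotone trend across all five stages and is screened with the full
ordering.

## Meta-analysis

* Per-probe test: Welch (unequal-variance) t by default — the robust
  choice when platforms differ — with the pooled-variance variant
  available by flag.  The upper one-tailed p₊ = P(T > t) is mapped to
  z = Φ⁻¹(1 − p₊) (computed through the survival function on the small
  tail to preserve precision), so direction is encoded in the sign of z
  with no separate step: case > control gives z > 0.
* Probes with fewer than 2 finite values in either group return NA;
  probes with no variance and equal means return z = 0 (degenerate).
* Probe→gene collapse happens before combination.  Default rule
  `max_abs_z` keeps the best probe per gene (ties broken by the
  lexically smallest probe id, for determinism); `median_z` is the
  robust alternative for sensitivity analysis.  Note that best-probe
  collapse is anticonservative at the probe level: with several probes
  per gene the null gene-level z is the extreme of several correlated
  normals, so exact N(0,1) calibration of Z_meta holds under a
  one-probe-per-gene map (how the calibration tests run it); with the
  default two-probes-per-gene map the |Z| > 5 screen remains far below
  one expected false call per 10⁴ genes.
* Combination: Z_meta = Σ w_i z_i / √(Σ w_i²) with w_i = √(dataset
  sample size), the standard sample-size-weighted Stouffer choice;
  equal weights by flag.  Genes absent from some platforms are combined
  over the datasets observing them, with the count reported.
* Screen: |Z_meta| > 5 by default — a deliberately stringent
  genome-wide style threshold (2·Φ(−5) ≈ 5.7×10⁻⁷ two-sided).

## Overlap and over-representation

* Hypergeometric upper tail P(X ≥ k) is evaluated through the log-space
  survival function; the suite checks it against exact combinatorial
  sums (Fraction arithmetic) to 1e-12 relative error for universes up
  to 200.
* The ranked overlap table sorts by trend p ascending with meta p as
  tiebreak, and is written with p-values in scientific notation at four
  significant digits.
* ORA intersects each gene set with the universe before testing, skips
  sets with no universe members, applies BH across all tested sets, and
  flags sets with q ≤ fdr_limit (default 0.05).  Default direction for
  the cross-cohort intersection is up-in-blood × up-in-tissue;
  down/down and cross-direction modes are arguments away.

## Normalization and QC

* Within-array: M′ = M − f(A), with f a least-squares natural cubic
  spline with knots at A-quantiles (df ≈ 2/span + 2; default span 0.3
  → 9 df).  A projection smoother was chosen deliberately over
  classical locally weighted fitting: normalization is then exactly
  idempotent (re-normalizing a normalized array is a no-op to floating
  point), which makes pipeline re-runs safe, whereas re-applying a
  loess fit re-chases ~SE-sized wiggles in the residuals.  Constant A
  falls back to median-centering with a warning; fewer than 50 finite
  probes is an error.
* Between-array: each array's sorted A is replaced by the across-array
  mean of sorted A (ties resolved by average ranks); M is untouched.
  After this step the A-quantile functions are identical across arrays
  by construction.
* PCA outliers: genes centered/unit-scaled (zero-variance genes
  dropped, missing values mean-imputed for the PCA only), samples
  projected on (PC1, PC2), and a sample flagged when its robust
  distance — per-PC deviation from the median scaled by 1.4826·MAD —
  exceeds threshold_sd (default 4).  Flagging is a report; removal is
  the caller's separate, logged action.  The robust rule replaces
  by-inspection outlier removal with a reproducible criterion.
* ANOVA filter: classical equal-variance one-way F per gene; genes
  constant across all samples have undefined F and are excluded; genes
  constant within groups but differing between them get p = 0.
* Clustering: scipy agglomerative linkage on samples processed in
  lexical sample-id order, so topology and tie-breaking are invariant
  to input column order.

## Synthetic data

The generator emulates the study conditions, not the platform physics:

* Blood cohort: five ordered stages at sizes HC 10 / D1 11 / D2 7 /
  D3 5 / ESRD 7 (40 samples).  Gene baselines ~ N(8, 1) on the log2
  scale; i.i.d. Gaussian noise with SD 1 (log2 units); trend genes
  shift linearly by ±0.5 noise-SD per stage step (50 genes of 5000 by
  default).  Linear-in-stage is the natural planted form for the
  monotone alternative; the free parameters (baseline spread,
  noise SD, effect sizes) are calibration choices at the scale typical
  of log2 microarray data.
* Tissue collection: three datasets totalling 25 cases vs 26 controls
  (8/9, 9/9, 8/8), each with its own probe universe (1 + Poisson(1)
  probes per gene, so many-to-one maps that differ across platforms), a
  per-gene per-dataset additive platform offset (SD 0.5), probe offsets
  (SD 0.25), and 100 DE genes shifted by ±2 noise-SD case-minus-control.
* Overlap study: 30 genes planted in both cohorts with consistent up
  sign (the discovery design of interest is up/up); remaining trend and
  DE genes are disjoint with random signs.  Ground truth (gene → sign
  maps, overlap list, effects, seed) serializes to JSON beside the
  data.

What the generator does *not* model: mean–variance trends and
heteroscedasticity, correlated gene modules, batch structure within a
dataset, clinical covariates, or raw two-color intensities (the M/A
inputs used by the normalization tests are constructed directly).
Passing tests therefore demonstrate correctness and calibration of the
statistical machinery under clean Gaussian conditions, not robustness
to every artifact of real arrays.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` seeds;
  simulation functions derive child seeds via `SeedSequence.spawn`, so
  cohorts are independently reproducible.
* Exact JT enumeration returns p as a partition count ratio;
  comparisons use a 1e-9 tolerance when matching the observed J inside
  the enumerated distribution to absorb float summation of half-tie
  counts.
* Degenerate inputs are first-class: complete ties (p = 1, flagged),
  zero-variance probes (z = 0), genes observed in no dataset
  (excluded), empty overlap (k = 0, p = 1 report).
* Problem sizes in the test and acceptance runs — 10⁴ genes for
  calibration checks, 5×10³ genes × 20 seeds for end-to-end recovery,
  500 small datasets for exact-vs-enumeration equivalence — were chosen
  to give binomial/KS resolution well inside the asserted bands while
  keeping a full run to a few minutes on one CPU.

## Known limitations

* The JT asymptotic p is a normal approximation; for N ≲ 15 with heavy
  ties prefer `method="auto"` or `montecarlo`.
* Best-probe collapse inflates probe-level nulls (see above); gene-level
  conclusions at |Z| > 5 are unaffected at default multiplicities, but
  users testing at lenient thresholds should use `median_z`.
* The weighted Z-method pools evidence, not effect sizes: no
  heterogeneity statistics (I²) or random-effects structure are
  computed.
* Stage ordering is taken as given; the pipeline does not infer stages
  or handle partial orders.
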