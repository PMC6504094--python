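# Methods

This note documents the statistical model behind `mirdrug`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do and
do not establish.

## Data model and transformations

Expression matrices are features × samples with an explicit scale flag; raw
intensities are log10-transformed exactly once (double transformation is an
error). IC50 vectors are in molar units with the drug's maximum tested
concentration attached; an IC50 counts as *at maximum* (right-censored) when
it is within relative tolerance 1e-9 of that maximum, which absorbs float
noise in stored tables without misclassifying genuinely lower values.
Responses are analysed as −log10 IC50, so censored lines share the minimum of
the transformed vector and larger values mean greater sensitivity. Missing
IC50s are excluded pairwise from every test and from the censoring counts, so
each drug's effective n is explicit. A hierarchical-clustering utility
(average linkage on uncentered-correlation distance,
d = 1 − x·y/(‖x‖‖y‖) ∈ [0, 2]) is provided for deriving subtype labels from
expression, but the cluster→subtype naming is deliberately left to the caller:
labels are a pipeline input.

## Branch selection and the three tests

Branch choice depends only on two counts over non-missing lines — censored
(`n_at_max`) and variable (`n_variable`) — checked in the order: fewer than 10
variable → Mann–Whitney; at most 5 censored → Spearman; otherwise 2-step.
Checking the censoring-dominated condition first makes the three published
conditions exhaustive and mutually exclusive even for degenerate inputs
(missing data, tiny panels) where they could otherwise overlap; with a full
36-line panel the order never matters.

* **Spearman.** ρ is the Pearson correlation of mid-ranks; the two-sided p
  uses the t-approximation on n−2 df (the `psych::corr.test` convention);
  |ρ| = 1 maps to p = 0. This approximation is known to be slightly liberal in
  the far tail (we measure ≈1.18× the nominal level at p ≈ 3·10⁻⁴ for n = 36
  under the null); it is retained because it is the field-standard convention
  for this analysis, and its effect on realized error rates is quantified
  below.
* **Mann–Whitney.** U is reported for the censored ("resistant") group; p is
  exact by enumeration when n₁+n₂ ≤ 20 with no ties, otherwise the normal
  approximation with tie and continuity correction (the `wilcox.test`
  convention). Direction is resistance iff the censored group's median miRNA
  rank exceeds the variable group's; an exact tie resolves to sensitivity.
* **2-step.** Step 1 screens by Spearman on the variable lines at unadjusted
  p < 0.05 — the screening threshold is not dictated by the procedure itself,
  and 0.05 was chosen to match the alpha used for the correlation test.
  Step 2 confirms by Mann–Whitney with censored = resistant; the confirmation
  p is the pair's final p, and the direction comes from the step-1 ρ sign
  (step 2 confirms the same contrast). A degenerate step 1 (constant values)
  marks the pair "not screenable" instead of erroring, so one bad pair cannot
  abort a panel-wide run.

## Multiple testing

Q-values are computed within each branch's pooled p-values (all drugs of the
branch together): the two-sided p-values of the Spearman pool, the step-2
p-values of *screened* 2-step pairs, and the Mann–Whitney pool. Unscreened
2-step pairs carry no q-value and are never significant; the `screened` flag
is written to the output so the pooling can be audited. π₀ is estimated by the
smoother: π₀̂(λ) = #{p > λ}/(m(1−λ)) on the grid λ = 0.05, …, 0.95, a cubic
smoothing spline through (λ, π₀̂) read off at λ = 0.95, clamped to
[1e-8, 1]. Below m = 20 p-values the estimate falls back to the conservative
π₀ = 1 with a logged warning (the spline is unstable there; real pools are
thousands of tests). With π₀ = 1 the q-values coincide with BH-adjusted
p-values exactly, which the tests assert.

Two caveats are inherent to this design and documented rather than patched:
the step-2 p-values of screened pairs are selection-biased (step 1 and step 2
test the same contrast on overlapping data), so q-values in that pool are
approximate; and the Spearman t-approximation's tail liberality propagates
into realized false-discovery proportions slightly above the nominal q cut
(see Benchmarks).

## Subtype confounding

Each significant pair is refit in three OLS models, one per binary contrast
(basal/luminal/normal-like vs rest): −log10 IC50 on intercept, miRNA, and the
subtype indicator. The retention rule had to be made explicit here: a subtype
confounds the pair iff, in its model, the subtype coefficient has p < α while
the miRNA coefficient has p ≥ α (default α = 0.05, configurable); a pair is
retained iff no contrast confounds it. This is one deterministic reading of
"the subtype associated more strongly than the drug"; the per-contrast
coefficients and p-values are all written out so a different rule can be
applied post hoc. A contrast whose indicator is constant among the analysed
lines (no such subtype drawn) is recorded as not evaluable instead of
aborting; rank-deficient designs otherwise raise, naming the collinear
column. Only Spearman-branch ("linear"-profile) drugs feed this and later
stages by default, since a linear model of the response is only meaningful
when the response actually varies; a flag lifts the restriction.

## Pathway screen

For each retained miRNA, lines are sorted by its expression (ties broken by
sample id, so groups are deterministic) and the bottom/top floor(0.25·n) form
the two groups — 9 vs 9 at n = 36. For a gene set with m genes present in the
matrix (absent genes are dropped and counted), the statistic is
Q = y_cᵀ(X_cᵀX_c/m)y_c / s² with genes and labels centered and s² = y_cᵀy_c/n.
Genes are centered but not variance-standardized by default (the statistic is
covariance-based); a flag enables standardization. Q is invariant to label
swap, gene order, and constant shifts, and is zero iff every gene is
orthogonal to the grouping.

Two tail probabilities are computed. The Monte-Carlo permutation p uses the
add-one estimator (1 + #{Q_perm ≥ Q_obs})/(1 + B) over B uniformly permuted
labels with an explicit seed; a relative tolerance of 1e-12 on the comparison
keeps re-draws of the observed arrangement in the tail despite float noise.
The analytic p exploits that for binary labels Q depends on the labels only
through the group indicator z: when C(n, g) ≤ 100 000 (the 9-vs-9 screen has
C(18,9) = 48 620) the exact permutation tail is enumerated outright;
otherwise Q is matched to a scaled χ² via the exact permutation mean and
variance of the quadratic form zᵀAz, computed in closed form from the
inclusion probabilities of sampling g positions without replacement (A is
doubly centered, which collapses the fourth-order combinatorics to a handful
of trace terms; the formulas are verified against enumeration in the tests).
Zero permutation variance yields p = 1. BH adjustment of the analytic p is
pooled across all sets tested for one miRNA (all sources together — the
screen is one family per miRNA), and a set is significant iff BH p < 0.1 and
permutation p < 0.05. Under a global null this dual rule rejects somewhere in
a screen with probability ≈ 0.1 (the Simes equality for BH; the permutation
clause cannot bind because any BH-passing set already has a far smaller
permutation p) — a property to keep in mind when reading "zero significant
sets" expectations for null screens.

## Synthetic panels

The generator emulates the study conditions: 36 lines, 411 miRNAs, 34 drugs.
Subtypes are drawn with probabilities 0.50/0.35/0.15 (basal/luminal/
normal-like), loosely mirroring such panels. miRNA log10 expression is
Normal(μ_f, σ_f²) per feature with μ_f ~ U(1, 3), σ_f ~ U(0.2, 0.5) (typical
log10-intensity ranges). Latent −log10 IC50 is intercept ~ U(5, 7) (nM–µM
potencies) plus Normal noise with sd 0.4 decades, a realistic between-line
spread for a drug with real but imperfect response structure. Planted direct
associations add β·miRNA with β = ±(noise_sd/σ_f)·r/√(1−r²), making the
population Pearson correlation on the latent scale exactly the target r
(default 0.75, ten pairs). Confounded associations shift the miRNA by 4σ_f
and the response by 4·noise_sd for one subtype with no direct term, inducing
a correlation near 0.78 that is entirely subtype-mediated. Because the three
subtype indicators are mutually exclusive, every subtype-shifted miRNA is
dependent on every subtype-shifted drug; the ground truth records these
cross pairs explicitly so the recovery report does not miscount them as false
discoveries. Censoring is specified as the at-max *fraction*: the drug's
maximum tested concentration is set to the corresponding latent quantile and
larger IC50s are truncated there. The default profile places 20 drugs at
fraction 0.05 (Spearman branch), 8 at 0.40 (2-step), 6 at 0.85
(Mann–Whitney). Planted gene sets build each member gene as
loading·z(target miRNA row) + N(0, 1); the target row is standardized first
so `loading` sets the gene-level signal-to-noise directly (gene–miRNA
correlation loading/√(1+loading²) ≈ 0.71 at the default 1.0) instead of
inheriting the arbitrary per-feature variance draw — without standardization
the planted signal strength would vary threefold across targets for no
modelled reason.

What the generator does **not** emulate: probe-level microarray noise,
normalization artifacts, correlated miRNA families, dose-response curve-fit
uncertainty in IC50s, or non-linear miRNA–response relationships. Passing
benchmarks therefore demonstrates that the pipeline recovers the *assumed*
statistical structure at the study's scale, not that it is robust to every
failure mode of real array data.

## Benchmarks and problem sizes

The test suite validates every statistic against an independent oracle (full
enumeration for Mann–Whitney and permutation tails, the O(m²) min-formula for
q-values, normal equations for OLS, the dense quadratic form for Q) and runs
two simulation benchmarks: association/confounding recovery on 20 full-scale
panels (36×411×34), and pathway-screen validity on 20 reduced panels (30
miRNAs, 260 genes, 12 sets, 1000 permutations) plus a 500-set null
calibration of the analytic p at the screen's 9-vs-9 group size. These sizes
keep the complete suite in a few minutes on one CPU while leaving each
estimate's Monte-Carlo error well below the margins being asserted. Measured
behavior at q ≤ 0.3 on the default panels: mean sensitivity ≈ 0.95, realized
false-discovery proportion ≈ 0.35–0.38 — above the nominal 0.30 by exactly
the mechanisms described under Multiple testing (t-approximation tail
liberality, adaptive-threshold ratio bias, and the selection-biased 2-step
pool), which users should weigh when interpreting q ≤ 0.3 calls from the
published procedure.

## Known limitations

* The retention rule for confounding is a reasonable formalization, not the
  only one; conclusions about individual borderline pairs can flip with α.
* The analytic set p-value is a stand-in for the original global-test
  package's asymptotic p; the two agree in permutation moments but not
  necessarily in the extreme tail for very small gene sets.
* Mann–Whitney branch drugs contribute no direction-free effect size
  comparable to ρ; their U statistics are not comparable across drugs with
  different group sizes.
* The pipeline assumes probe-deduplicated input matrices and does no
  normalization.
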