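# Methods

## The prediction model

The working assumption is that in vitro drug sensitivity is a dense
function of baseline transcription: every gene may carry a small amount of
information, and no sparse marker set is presumed. For a cell-line panel
with expression matrix X (lines × genes, log2 scale) and phenotype y
(log IC50, lower = more sensitive), the linear pathway fits

  z = t_λpt(y),    β̂ = argmin_β ‖z − ȳ − X̃β‖² + λ‖β‖²,

where t is a parametric power transform pulling the skewed IC50 panel
toward normality, X̃ is the per-gene standardized expression, and the
intercept (the mean transformed IC50) is unpenalized. A patient's predicted
sensitivity is ȳ + x̃ᵀβ̂ on the transformed scale; ranking, group tests and
ROC analysis are invariant to the monotone back-transform, which is
available when absolute IC50 units are wanted.

Ridge rather than a sparse penalty is a deliberate bias: expression is
dominated by broad co-expression programs, so shrinking all genes a little
transfers better across platforms and tissues than selecting a few.

### Automatic penalty

λ is chosen without user input by exact leave-one-out generalized
cross-validation: with the thin SVD X̃ = UDVᵀ computed once,
GCV(λ) = n·RSS(λ) / (n − df(λ))², df(λ) = Σ dⱼ²/(dⱼ²+λ) + 1,
is evaluated in closed form over 50 log-spaced penalties in [1e−3, 1e6]
(no refitting), ties resolved toward the smaller penalty. A
principal-component moment estimator (regress y on the PCs explaining 90%
of predictor variance; λ = r·σ̂²/‖α̂‖²) is available as
`lambda_method="cule_deiorio"` for fidelity to the automatic-ridge lineage.
The solver itself is the SVD form, algebraically identical to both the p×p
primal and the n×n dual solutions; tests verify agreement with direct dense
solves to 1e−8.

### Phenotype transform

Default family is Yeo–Johnson, because log IC50 values from micromolar
screens are frequently negative, which classic Box–Cox cannot accept. A
`boxcox_offset` family (shift by max(0, 1 − min y) so all values ≥ 1, then
Box–Cox) is provided for compatibility with pipelines that shift the
phenotype; note the shift itself moves the ML exponent, so the two families
are not interchangeable on sub-unit data. The exponent maximizes the normal
profile log-likelihood on a grid over [−3, 3] (step 0.01) with bounded
local refinement; by construction the fitted exponent is never worse than
no transform. In leave-one-out cross-validation the transform is
re-estimated inside each fold by default (no leakage); a flag freezes it.

### Targeted agents: the logistic pathway

For most targeted agents only an extreme-sensitive tail of the panel
responds within the screened concentration window; remaining IC50s are
extrapolated far beyond it with very wide confidence intervals. Fitting a
linear model to those values mostly fits noise. The alternative keeps only
the trustworthy rank information: label the 15 lowest-IC50 lines sensitive
and the 55 highest resistant (counts configurable; ties broken by sample
id), select the 1,000 most differentially expressed genes by pooled-variance
two-sample t-test (Welch by flag), and maximize the L2-penalized Bernoulli
likelihood by damped Newton/IRLS — in the kernel dual parametrization when
genes outnumber lines, which is exact and reduces every step to an
(n+1)-dimensional solve. The penalty keeps coefficients finite even on
separable data and is chosen by 10-fold cross-validated deviance by
default. Output is the log-odds of sensitivity and its logistic map.

## Homogenization

Cell-line and clinical cohorts come from different platforms and sites, so
the two matrices are intersected on their common gene symbols (duplicate
probes per symbol are collapsed by their mean on the log2 scale), column-
concatenated with cohort as the batch label, and adjusted with the
parametric empirical-Bayes location/scale model: per-gene batch effects are
estimated, standardized data Z = (Y − α̂_g)/σ̂_g are shrunk using a Normal
prior on batch locations and an inverse-gamma prior on batch scales
(hyperparameters by method of moments across genes), the conditional
posterior means are iterated to a 1e−4 relative tolerance (cap 100), and
the data are reassembled as Y* = σ̂_g(Z − γ*)/δ* + α̂_g. Genes constant
within a batch are dropped with a warning before adjustment — they carry no
usable signal and would otherwise divide by zero. The implementation is
validated against Bioconductor's reference parametric implementation on
small fixtures (agreement to ~1e−6) and satisfies the exact shrinkage
geometry (every posterior location lies between the raw estimate and the
prior mean).

After adjustment, the 20% of genes with the lowest unbiased sample variance
across all samples of the merged matrix are removed (exactly ⌊0.2·G⌋
genes; ties broken lexicographically by gene id): where technical
variability exceeds biological variability a gene can only add noise.
Filtering on the merged matrix mildly couples train and test; this follows
the method's published description and is recorded as such. The filter
statistic, fraction, EB tolerances and batch granularity are all exposed in
the configuration.

## Evaluation machinery

- **LOOCV** on the once-homogenized panel: each line is predicted by a
  model (transform + penalty + fit) re-estimated on the remaining n−1
  lines; agreement is the Pearson correlation of back-transformed
  predictions with measured IC50s. A stricter fold-wise re-homogenization
  is intentionally not the default, matching the method's description.
  Caveat: under a true null the LOO predictions collapse toward the
  leave-one-out means, which are exactly anti-correlated with the held-out
  values, so null panels show strongly *negative* r rather than 0 — a known
  artifact of cross-validated correlation, worth remembering when reading
  near-zero results.
- **ROC/AUC** by the Mann–Whitney construction (ties count one half), with
  orientation explicit at every call site: linear predictions enter with
  `positive_orientation="lower"`, probabilities with `"higher"`.
- **Permutation p-values**: labels are permuted B times (default 100,000)
  and p = #{AUC_perm ≥ AUC_obs}/B, one-sided toward sensitivity
  discrimination; the add-one estimate (#+1)/(B+1) is co-reported since the
  raw proportion can be exactly zero. Under the null these p-values are
  uniform (verified by KS across 200 simulated replicates).
- **Classical tests** (Welch/pooled t, Pearson/Spearman, Wilcoxon rank-sum
  with exact enumeration when n₁n₀ ≤ 10,000 and no ties) are delegated to
  scipy.stats behind stable result types; group-comparison t-tests default
  to Welch.
- **Cut-point sweep**: candidate cuts are midpoints between consecutive
  distinct scores plus ±∞; scores below the cut are called sensitive; the
  optimum and the contiguous interval beating a reference accuracy are
  reported.
- **Ordered-category medians**: per-category medians of the predictions and
  a strict monotonicity check along the declared clinical order
  (CR → PR → MR → NC → PD).

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed) and store their full
ground truth (coefficients, latent signal Xβ per sample, batch vectors), so
every benchmark can be scored against the truth with no downloads.

- **Expression**: per-gene baselines ~ N(7, 1.5²) on the log2 scale with
  per-gene total SDs ~ U(0.2, 1.5). Gene-gene covariance follows a
  latent-factor model: 15 shared factors carry 65% of each gene's variance
  (random loading directions), the scale of leading-component variance in
  real array cohorts. This co-expression structure is what makes dense
  ridge transfer informative; with fully independent genes no method can
  recover the sparse signal at these sample sizes.
- **Phenotype**: 30 causal genes with coefficients ±U(0.5, 1);
  log IC50 = Xβ + ε with ε scaled so the signal fraction hits the target
  R² (default 0.7; realized ratio within ±0.1 at n ≥ 100).
- **Clinical cohort**: patients drawn from the same expression model, then
  distorted per gene by a location shift ~ N(0, 1) and a scale factor
  ~ U(0.7, 1.4) about the gene's baseline mean — exactly the model class
  the EB adjustment removes — with a random 10% of genes dropped to emulate
  platform mismatch. Responses derive from the latent Xβ: binary by median
  split with 10% label flips, ordinal by quintiles, continuous as a
  log-normal months-to-progression analogue decreasing in Xβ. Note that
  per-gene location shifts are rank-neutral for any fixed linear model, so
  under this batch model the EB step's measurable benefit on rank metrics
  is small; its value on real data (nonlinear platform effects, global
  intensity differences) is larger than these simulations can show.
- **Targeted-agent screen**: the 15 truly most sensitive lines get
  accurately measured IC50s (noise SD 10% of signal SD); the rest get
  extrapolated values — offset two noise-SDs above the screening window and
  noise-dominated (noise SD 10× signal SD) — so that, as in real screens,
  non-responders' extrapolated values sit above essentially all in-window
  measurements while carrying almost no rank information.

Passing these benchmarks demonstrates internal correctness and
transfer under the stated batch model; it does not demonstrate clinical
accuracy on real trials, which depends on preprocessing choices, cohort
composition and response phenotype quality outside this package's scope.

## Numerical choices and defaults

| Parameter | Default | Notes |
|---|---|---|
| remove_fraction | 0.20 | merged-matrix variance filter |
| transform_family | yeo_johnson | handles negative log IC50 |
| lambda_method / grid | loo_gcv, 50 pts in [1e−3, 1e6] | ties → smaller λ |
| n_sensitive / n_resistant | 15 / 55 | targeted-agent split |
| k_features | 1000 | t-test feature selection |
| ttest_variant (selection) | pooled | Welch by flag |
| eval t-test | welch | group comparisons |
| permutations B | 100,000 | seeded |
| EB tolerance / cap | 1e−4 / 100 | posterior iteration |
| logistic tolerance / cap | 1e−8 / 100 | Newton with step-halving |

Tie-breaking is lexicographic by identifier everywhere (variance filter,
binarization, gene ranking), making every run bit-reproducible given the
configuration and seed; the acceptance script and `run` command verify
byte-identical artifacts across reruns.

Problem sizes in the shipped benchmarks (1,000–2,000 genes, 40–200
samples, B = 2,000–100,000 permutations) are chosen so the full suite runs
in minutes on one CPU while keeping every statistical property testable;
they are smaller than real panels (~700 lines, ~10,000 shared symbols) but
preserve the n ≪ G regime the method operates in.

## Known limitations

- No covariate-preserving batch correction, reference-batch mode, or
  non-parametric EB priors.
- Missing expression values are a hard error; arrays are assumed complete
  after upstream summarization.
- Probe-to-symbol mapping is assumed done upstream; gene identifiers are
  case-sensitive and not normalized.
- The cut-point analysis dichotomizes a continuous prediction and inherits
  the usual instability of optimal cut-points on small cohorts.
- Survival endpoints and multi-drug joint models are out of scope.
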