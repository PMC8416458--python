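# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions a maintainer would want recorded. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The problem

A chemical is *DNA-damage-inducing* (DDI) if it creates lesions that the
cell's damage-response machinery reacts to. Two complementary measurements
are analyzed: physical strand breaks (median % tail DNA from a
microwell-arrayed alkaline comet assay, n = 4 wells per concentration) and
the transcriptional damage response (a 64-gene biomarker measured by
targeted RNA-seq, ~3,000-probe panel, n = 4 per concentration, five
concentrations plus a matched vehicle control). A chemical is called
genotoxic if either endpoint is positive; potency is quantified for both
endpoints by the benchmark concentration (BMC) at which the modeled
response departs control by one standard deviation.

## Synthetic data (`cometddi.synthetic`)

The generator defines the study conditions under which everything is
tested.

* **Counts.** Negative binomial around a 1,000,000-read target depth with
  log-normal probe baselines (σ = 1), per-sample log-normal size-factor
  jitter (σ = 0.15) and dispersion 0.05. At the resulting per-probe depths
  the counting noise on the log2 scale is ≈ 0.3, consistent with the
  default log2 residual SD (`noise_sd = 0.3`). The default panel is 500
  probes (64 biomarker genes, every fourth with two probes to exercise
  probe averaging, plus 436 background probes) — a scaled-down stand-in for
  a ~3,000-probe panel that keeps tests fast without changing any per-gene
  statistics.
* **Dose response.** Responsive biomarker genes follow a three-parameter
  Hill curve in log2 fold change, amplitude `effect_size_log2 = 2.0`
  (signed: half the panel up-, half down-regulated), Hill coefficient 2.
  The half-max constant is solved in closed form so the curve crosses the
  noise SD exactly at the chemical's true BMC; this makes "the generator's
  truth" and "the BMC definition" the same quantity by construction.
  Comet % tail DNA uses the same machinery (baseline 3%, maximum increase
  25 points, replicate SD 1.2, Gaussian noise on the per-well median scale
  — the distribution of per-well medians is not published, so Gaussian is
  an assumption of this package, not a claim about the source assay).
  Viability declines logistically (slope 3) around the chemical's EC50.
* **Seeding.** One top-level seed; children are spawned per purpose and
  chemical through `SeedSequence` with CRC32-folded labels, so outputs are
  bit-identical across runs and platforms and partial reruns reproduce.
* **Not emulated.** Plate/batch effects, probe cross-hybridization,
  between-chemical shared controls on one plate, read-level artifacts.
  Passing tests therefore demonstrate the statistics under a clean,
  well-specified data-generating process — not robustness to the lab
  artifacts real studies contain.

## QC and normalization (`cometddi.qc`)

Median-of-ratios size factors (geometric-mean reference over probes with no
zeros). Note the estimator's actual invariances: a global rescale of all
counts leaves factors unchanged, and rescaling one sample by c multiplies
its factor *relative to the others* by c while normalized values change
only by a common constant. Expression values downstream are
log2(normalized + 0.5).

Exclusion rules: total reads < 100,000 (10% of target depth); any of
{probes capturing the top 80% of signal, Gini coefficient, active probes
(≥ 5 reads)} strictly outside Tukey's outer fence (3×IQR, linearly
interpolated quartiles — values exactly on a fence are kept); samples that
cluster alone at complete-linkage height 0.1 on 1 − Spearman ρ (computed on
log2-normalized values restricted to probes active in ≥ 50% of samples,
since ranks of near-zero counts are noise); whole concentration groups with
< 40% viability. Cytotoxic concentrations are excluded from classification,
hazard calls and BMC modeling, but comet summary statistics can still be
computed at them (the flag is carried separately). Because QC here runs per
24-sample experiment, strong treatment effects can themselves push top-dose
samples over a fence; downstream stages tolerate conditions thinned below
n = 2 by dropping them with a warning.

## TGx-DDI classification (`cometddi.classify`)

Nearest shrunken centroids with pooled within-class SD s_i, fudge
s0 = median(s_i), m_k = √(1/n_k − 1/n), soft-thresholding of the
standardized centroid differences by Δ, and class priors proportional to
training class sizes. Δ is chosen once by stratified 7-fold
cross-validation on the training set (largest Δ among the error minimizers)
and then frozen. The probability-analysis call requires a class posterior
> 0.90, else unclassified.

The PCA and clustering analyses are formalizations of what is usually read
off plots, and the exact decision rules are this package's design choices:
PCA projects the profile on the training set's first principal component
(gene-centered training data only) and calls by side of the midpoint
between class-mean scores, with a dead band of 10% of the class separation;
hierarchical clustering (average linkage, Euclidean) of training compounds
plus the profile is cut into two clusters and the call is the majority
class of the profile's cluster-mates (alone or tied → unclassified).
A concentration is DDI if any of the three analyses says DDI; non-DDI only
if all three do; a chemical is DDI if any non-cytotoxic concentration is,
and an unclassified concentration without any DDI call leaves the chemical
unclassified rather than negative.

## Comet statistics (`cometddi.comet`)

One-way ANOVA across concentration groups. Anderson–Darling is applied to
pooled residuals (n = 4 per group is too small to test normality per
group); Fligner–Killeen to the raw groups; either rejecting at 0.05 swaps
all observations for their joint ranks and repeats the analysis. Pairwise
comparisons use two-sided t statistics with the residual variance pooled
across all groups (pooled rather than Welch — configurable), adjusted by
the Dunnett many-to-one multivariate-t distribution (scipy implementation,
fixed integration stream; adjusted p floored at the raw p so adjustment is
monotone). The hazard call is positive only for a significant *increase* at
a non-cytotoxic concentration — two-sided p-values with a one-sided
direction requirement at the call stage.

## BMC modeling (`cometddi.bmc`)

* **Prefilter (genes only).** Williams-type trend statistic: group means
  isotonized by pool-adjacent-violators in the direction of the overall
  (dose-weighted) trend; t of the isotonic top-dose mean vs the control
  mean with pooled within-group SD. Permutation p with 250 label
  permutations and the +1 correction (p floor 1/251, below the 0.05 gate),
  |statistic| compared two-sided because biomarker genes respond in both
  directions. Retention also requires a maximum linear fold change > 1.5.
  The comet endpoint is not prefiltered; chemicals enter by their positive
  ANOVA/Dunnett call.
* **Model suite.** Linear, 2° polynomial, Power a + b·c^p with p ≥ 1, and
  exponentials in the conventional BMD parameterizations Exp2 = a·e^{±bc},
  Exp4 = a(d − (d−1)e^{−bc}), Exp5 = a(d − (d−1)e^{−(bc)^g}), all under a
  constant-variance normal likelihood. The likelihood depends on the data
  only through group means and the pure-error SSE, so fitting happens at
  the group level; every model is linear in (intercept, amplitude) given
  its shape parameters, leaving 1-D or 2-D profile optimizations with
  closed-form inner solves (grid + bounded polish; Nelder–Mead for Exp5).
  AIC selects the model (k = parameters + 1 for σ); SSE differences below
  the data's floating-point resolution are floored so numerically
  indistinguishable fits tie and parsimony (fewer parameters, then a fixed
  model order) decides.
* **Goodness of fit.** Dose-group lack-of-fit F test (model SSE above pure
  error over df_lof, against pure error over df_pe). The F form is used
  rather than the chi-square LR because at n = 24 the LR over-rejects
  (measured 16% at nominal 10% under a true suite member, vs 9.3% for F —
  computed in the test suite).
* **BMC.** |f(BMC) − f(0)| = BMR·σ̂ with BMR = 1 and σ̂ the modeled residual
  SD of the selected fit (residual rather than control-group SD, matching
  constant-variance practice; configurable). Closed forms for
  Linear/Power/Exp2/Exp4/Exp5, bracketed root-finding for Poly2, searched
  on (0, 10×c_max]; no crossing ⇒ +∞ (fails the top-concentration filter).
  Because BMC ∝ σ̂, its *relative* CI width has a floor set by σ̂'s own
  sampling error (≈ 1/√(2(n−k)) on the log scale, ~15% at n = 24): the
  interval collapses in absolute terms as noise vanishes but never below
  that relative floor.
* **Confidence limits.** Primary: profile likelihood — the deviance is
  minimized subject to the constraint that the response change at a trial
  BMC equals ±BMR·σ (σ profiled as a parameter), and the 95% limits are
  where the profiled deviance rises by χ²₁(0.95); a parametric-bootstrap
  percentile interval (500 draws) is the fallback when profiling fails.
  Gene-level estimates default to a log-scale delta-method interval
  (parameter covariance from the weighted Jacobian plus the σ̂ variance
  term): the two-level bootstrap refits each gene 100 times and profiling
  inside that loop is computationally impractical; profile and delta agree
  within 10% on a Linear fit at n = 24 (asserted in the tests). The comet
  endpoint, fit once per chemical, uses the profile path.
* **Filters.** Fail on fit p ≤ 0.1, BMC/BMCL ≥ 20, BMCU/BMCL ≥ 40, BMC at
  or above the top concentration, or BMC more than two decades below the
  lowest nonzero concentration. Note the p > 0.1 gate removes ~10% of
  genes even when the model is exactly right — a designed false-negative
  rate, visible throughout the recovery simulations.
* **Gene-set summary.** Median BMC over genes passing the trend prefilter
  and all estimate filters. Two-level bootstrap: per gene, 100 group-wise
  normal (sample mean/SD) datasets are refit and filtered end to end
  including the prefilter; the pass count / 100 is the gene's inclusion
  probability and its passing BMCs form a pool. Then 2,000 set-level
  resamples include each gene independently with its inclusion probability
  and draw one passing BMC uniformly (a single draw rather than the gene
  median — config-switchable); the median over included genes is recorded,
  and the 2.5/97.5 percentiles of those 2,000 medians form the 95% CI.
  Bootstrap datasets are centered on sample group means rather than on the
  fitted curve, so pass counts well below 100 are expected even for clean
  genes.

## Integration and ranking (`cometddi.integrate`)

Combined call = positive iff either endpoint is positive; an unclassified
transcriptomic chemical counts as not-positive but is surfaced in the
report. Potency ratio = transcriptomic bootstrap-median BMC / comet BMC,
reported with the fold deviation max(ratio, 1/ratio); ranks are by
ascending BMC within each endpoint over its modeled chemicals, ties broken
by chemical label for determinism; "n.m." (not modeled) propagates as
missing rather than zero.

## Validation studies (`cometddi.validation`)

Problem sizes are the package's own choices, set so the full run completes
in minutes on one core: classifier-oracle agreement on 50 random toy
training sets × 5 profiles; bootstrap-CI coverage over 50 replications of a
6-gene set whose genes are all calibrated to a 10 µM truth with per-gene
SDs drawn from 0.1–0.3; Williams null retention over 10,000 pure-noise
genes with the fold-change gate disabled; pipeline familywise error over
2,000 null chemicals (5 treatments + control, n = 4); Dunnett adjusted
p-values vs a 10⁶-draw max-|t| Monte-Carlo oracle on a fixed 3-group
design; integrated-call accuracy over 40 chemicals (20 DDI with BMCs
log-spaced 3–300 µM, 20 inert) under generator defaults; and potency-rank
agreement over 30 seeds × 4 DDI chemicals spanning 100× in true potency,
where gene-set BMCs use the prefiltered median path (the bootstrap CI is
exercised separately in the coverage study) and comet BMCs the profile
path.

## Known limitations

* The published 64-gene centroid values cannot be reproduced (the original
  training data are not part of this package); the classifier is rebuilt on
  synthetic reference compounds.
* The PCA/HC call rules are formalizations of visual judgments; other
  reasonable formalizations exist and are exposed via configuration.
* The constant-variance likelihood is assumed throughout BMC modeling;
  heteroscedastic responses will push genes into the rank/bootstrap paths'
  filters rather than being modeled with a variance power.
* The generator's clean noise model means the measured false-negative
  rates of the BMC filters (~10% from the fit gate alone) are lower bounds
  for real data.
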