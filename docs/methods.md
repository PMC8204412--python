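# Methods

## Overview

`splicestem` implements a stemness-from-splicing analysis for bulk tumor
cohorts: a one-class logistic regression (OCLR) stemness signature trained on
stem-cell expression profiles, an mRNA stemness index (mRNAsi) for tumor
samples, decile stratification into stem-like (TSC) and non-stem-like (USC)
groups, differential splicing between paired tumor/normal tissue (KASE) and
between stemness extremes (SASE), a splicing-factor correlation network, and
survival models linking events and stemness to outcome. A seeded synthetic
cohort generator with ground-truth labels makes every stage testable without
any external download.

## PSI representation and filtering

Percent spliced in is stored as a fraction: PSI = inclusion / (inclusion +
exclusion) read counts, in [0, 1]. A 0/0 count pair carries no evidence for
either splice form and yields a missing value, not 0. All thresholds
(0.05 mean filter, 0.1/0.2 differential deltas) are interpreted on the
fraction scale. Tables whose maximum value exceeds 1.5 are treated as
percent-scale and rescaled; a table whose maximum says "percent" while most
values are <= 1 is rejected as mixed-scale rather than guessed at.

Event-quality filtering keeps events observed in >= 80% of samples (read as
an inclusive bound) whose mean PSI over observed samples is >= 0.05; the mean
uses non-missing values only. The operation is idempotent and order-
preserving, and reports kept/dropped counts per reason.

Event ids use the `GENE_TYPE_ASID` dialect (e.g. `SLC2A11_ES_61347`) over the
seven splice modes AA, AD, AP, AT, ES, ME, RI. Gene symbols containing
underscores are rejected because they make the dialect ambiguous.

## The OCLR stemness signature

The signature is the minimiser of the one-class logistic loss

    L(w) = (1/n) Σ_i −log σ(wᵀx_i) + (λ/2)‖w‖²

over stem-cell profiles x_i (log2(x+1) expression, feature-centered), with
ridge penalty λ defaulting to 1/p. The problem is convex, so zero
initialisation plus a deterministic L-BFGS solve (gradient ∞-norm tolerance
1e−6, iteration cap 10 000) gives a reproducible optimum. An optional
elastic-net L1 term (default 0) is solved by proximal gradient (FISTA).

**Centering.** If features are centered by the stem-sample means themselves,
the gradient vanishes at w = 0 and the ridge term makes w = 0 the global
minimum — the signature degenerates. The package therefore computes the
per-feature centering means over the full reference cohort (stem and
non-stem samples) while the one-class fit itself sees only the stem-labeled
columns. This preserves the one-class character of the fit and anchors the
signature at the stem-vs-rest contrast.

**Feature space.** By default the signature is restricted to "spliced
genes": genes harboring events that survive filtering in the target cohort.
This couples the index to the splicing landscape under study while remaining
computable from expression alone.

**Scoring and orientation.** A sample's raw score is the Spearman
correlation between w and the sample's profile over shared features; rank
correlation makes scores invariant to any monotone platform or normalisation
effect, so no cross-cohort scale harmonisation is needed. The mRNAsi is the
raw score min-max scaled over the scored cohort. Under the default
`stem_low` orientation the scale is flipped (1 − x) so that more stem-like
samples receive a lower mRNAsi; TSC is then the lowest-mRNAsi decile
(floor(0.10·n) samples) and USC the highest, with deterministic (score,
sample id) tie-breaks. A `stem_high` flag gives the opposite convention.
Scaling anchors are frozen into the model at first scoring so later cohorts
stay comparable; out-of-range raw scores clip to [0, 1] with a warning.

Separation quality is quantified by the rank-based (Mann–Whitney) AUC with
ties counting 1/2.

## Differential calling

Three presets share the machinery: per-feature group means on non-missing
values, |ΔPSI| = |mean_a − mean_b|, log2FC = log2((mean_a+ε)/(mean_b+ε))
with ε = 1e−3 guarding zero means (ratio of means, not mean of ratios), a
two-sided t-test, and Benjamini–Hochberg adjustment.

* **KASE** (tumor vs matched normal): paired t-test on complete pairs;
  |log2FC| ≥ 1, FDR < 0.05, |ΔPSI| > 0.1.
* **SASE** (TSC vs USC tumors): Welch t-test; |ΔPSI| > 0.2, same other
  thresholds.
* **DEG** (expression): Welch t-test on log2(x+1); |log2FC| ≥ 1, FDR < 0.05.

The BH family of each call is the set of events passing the missingness
precondition (≥ 2 values per group, or ≥ 2 complete pairs); events below it
are reported `tested = False` and never enter the adjustment. Moderated
(limma-style) statistics are deliberately not used; the plain Welch test is
the documented choice and will be slightly conservative at very small n.

## Correlation network

Associations between the mRNAsi (or splicing-factor expression) and event
PSI use Spearman rho with mid-ranks for ties and the t-approximation with
n−2 df for p-values, after pairwise missing removal (≥ 4 complete pairs
required). Edges are retained at FDR < 0.05 and |rho| > 0.6; the BH family of
the factor network is the full factor × event pair set of the call (global
rather than per-factor adjustment — the stricter choice). The network is
bipartite by construction; node degrees summarise factors hitting multiple
events and events hit by multiple factors.

Clinical composition tables cross-tabulate TSC vs USC (MID excluded) over a
clinical variable with a chi-square test, switching to Fisher's exact test
for 2×2 tables with any expected count ≤ 5.

## Survival analysis

Cox models maximise the partial likelihood with the Efron tie correction
(via lifelines, Newton precision 1e−9); hazard ratios carry Wald 95% CIs.
Suspected monotone-likelihood fits are flagged, not silently returned.
Median dichotomization labels values > median "high" and ≤ median "low";
Kaplan–Meier curves and the two-sided log-rank test compare the groups.

The multivariate model is built from univariate-significant (BH FDR < 0.05)
events by backward elimination on the partial-likelihood AIC, after greedy
pruning of near-collinear covariate pairs (|r| > 0.75 — stemness-driven
events are mutually correlated by construction, and an explicit covariate
list can override the selection). One joint fit is evaluated at all horizons
rather than one model per horizon.

Discrimination: Harrell's C over usable pairs (the shorter time must be an
observed event; risk ties count 1/2), and cumulative/dynamic AUC(t) with
inverse-probability-of-censoring weights from the Kaplan–Meier estimate of
the censoring distribution (cases: events with time ≤ t weighted by
1/G(T−); controls: subjects with time > t). With no censoring the estimator
reduces exactly to the binary AUC of the indicator (time ≤ t).

## Synthetic cohorts: what they emulate and what they do not

The generator plants the exact statistical structure the analysis assumes,
with one global seed fanned out to per-stage substreams so cohorts re-run
independently.

* **Training panel** (default 93 stem + 160 non-stem samples, 2000 genes):
  log-normal expression (gene baselines Uniform(2, 8) on the log2 scale,
  unit log2 noise); 200 signature genes shifted +2.0 log2 (4-fold) in stem
  samples — a realistic effect for pluripotency markers. Non-signature genes
  are exchangeable between groups.
* **Tumor cohort** (default 200 tumors, 39 matched normals, 5000 events):
  each tumor draws latent stemness U ~ Uniform(0, 1). True
  stemness-associated events (60) have Beta-distributed PSI (precision 30)
  with mean μ0 ± 0.3·(U − 0.5) clipped to (0.01, 0.99), sign per event;
  base means μ0 ~ Uniform(0.20, 0.35) so both the ΔPSI and the |log2FC| ≥ 1
  criteria are attainable at the planted effect; null events draw μ0 ~
  Uniform(0.05, 0.95) independent of U. Cancer-specific events (300, half
  overlapping the stemness set) shift their mean by ±0.3 in matched normals,
  with μ0 ~ Uniform(0.15, 0.28). Entries go missing completely at random at
  the configured rate (default 5%).
* **Signature genes in tumors** increase with latent stemness (slope 2.0
  log2 per unit), so stem-like tumors resemble the stem-cell reference and
  the flipped (stem-low) mRNAsi decreases with stemness — TSC, the lowest
  mRNAsi decile, is the most stem-like group.
* **Splicing factors** (30): log2 expression affine in the signed PSI of one
  target event plus Gaussian noise (sd 0.12 on the PSI scale). One target
  per factor keeps the factor's event-specific signal well above the
  latent-driven background correlation that all stemness events share
  (population own-target Spearman ≈ 0.8 versus ≈ 0.45 cross-talk), so edge
  recovery is a meaningful test rather than a foregone conclusion in either
  direction. Several factors may share a target, giving multi-factor events.
* **Survival**: exponential proportional hazards with linear predictor
  log-HR·U (default 1.0), baseline median ~5 years, uniform censoring on
  (0.5, 8) years; clinical covariates (stage, T/N/M, gender, smoking) are
  noisy ordinal functions of U so composition tables show a stemness
  gradient.

Not emulated: read-level simulation, library-size/batch effects, gene-gene
co-expression structure, non-proportional hazards, informative censoring,
isoform-level coupling between expression and PSI of the same gene. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to violations real cohorts may show.

## Numerical and design choices

* Percent-vs-fraction dialect decided per table (max > 1.5 ⇒ percent);
  mixed scales are an error rather than a silent guess.
* t-test rather than rank-sum for differential PSI: group sizes of 20–39
  with Beta noise are well within t robustness; the paired design is used
  whenever a pairing map is supplied.
* BH is computed per call over tested features, not over the pre-filter
  universe.
* Backward-AIC covariate selection is a documented default, overridable by
  an explicit covariate list; LASSO-penalised Cox is out of scope.
* Pipeline outputs are plain TSVs with the seed in a header comment;
  reruns with the same configuration are byte-identical (timings live only
  in the JSON report).

## Problem sizes used in the checks

The automated checks run the generator at its default sizes (253 training
samples, 200 tumors, 5000 events) for recovery measurements — stemness
separation AUC, SASE sensitivity/FDR, network precision/recall, hazard
recovery — averaging over 5–10 seeds; unit tests use smaller cohorts
(hundreds of events, ~100 samples) where the property under test is
size-free, such as null false-call rates and estimator cross-checks against
brute-force oracles. Confidence-interval coverage uses 200 replicates of a
60-subject null cohort.

## Known limitations

* The one-class signature depends on the reference cohort used for
  centering; a stem-only reference degenerates (see above), and centering on
  a non-representative cohort tilts the signature.
* Welch-on-log2 differential expression lacks the variance moderation of
  limma and loses power at very small group sizes.
* The time-dependent AUC assumes censoring independent of the risk score
  (KM censoring weights).
* Harrell's C is computed by exhaustive pair enumeration (O(n²)); fine for
  cohort-scale n, slow beyond ~10⁴ samples.
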