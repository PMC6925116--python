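# Methods

This note documents the statistical model behind `platesig`, the defaults
and why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical decisions that matter when reading its output.

## Study design being modeled

The pipeline targets a 1:1 matched case-control transcriptomic screen:
each case (acute coronary thrombosis, STEMI) is matched to one control on
sex and age, expression is measured on a log2 scale for tens of thousands
of genes, and the discovery cohort has on the order of 19 pairs (38
arrays). A second cohort — cases versus patients with documented coronary
atherosclerosis but no thrombosis (SCAD) — serves as the external test of
whether the signature detects the *event* rather than the background
disease. The defining statistical features are: very small n, very large
G, aggressive univariate selection, and within-pair correlation.

## Synthetic cohorts

The generator implements the simplest model consistent with that design:

    x[s, g] = mu_g + delta_g * 1(s is case) + u_pair(s) + e[s, g]

with gene baselines `mu_g ~ U(4, 12)` log2 units, gene noise
`e ~ N(0, sigma_g^2)` with `sigma_g ~ U(0.3, 1.0)`, an additive pair
random effect `u_pair ~ N(0, 0.25^2)` shared by the two members of a pair,
and case-minus-control shifts `delta_g` at a handful of signal genes
(zero elsewhere). Defaults: 19 pairs; 1,000 genes in test-scale runs
(the full-scale array has ~67,000 probe sets and ~6,700 survive the 10%
variance filter — the same pipeline runs at that scale, it is simply not
the default problem size for the test suite).

Parameter rationale:

* **Baselines 4–12 log2 units** span the usual dynamic range of processed
  microarray intensities.
* **Gene SDs 0.3–1.0** cover quiet to noisy genes on the log2 scale.
* **Pair effect SD 0.25** induces moderate within-pair correlation
  (intra-pair r between ~0.06 and ~0.4 depending on `sigma_g`). A nonzero
  pair effect is what makes the matched structure real, and is the reason
  the bootstrap resamples whole pairs rather than rows.
* **Seeding** is substreamed per purpose and per gene from one master
  seed, so enlarging `n_genes` appends columns without changing the draws
  of existing genes, and the external cohort shares gene-level parameters
  (but not noise) with the discovery cohort of the same spec.

What the generator does **not** model: probe-level effects, batch or array
artifacts, heavy-tailed or intensity-dependent noise, correlated gene
modules, missing values, or subject exclusions. Passing tests therefore
demonstrate correctness of the *procedure* under its own assumptions, not
robustness of the biology to real-data pathologies.

## Per-gene screen

Each gene is tested with a simple (unpaired) logistic regression of case
status on expression, deliberately mirroring the gene-by-gene design of
the original analysis rather than moderated differential-expression
practice. Reported per gene: `beta` (log-OR per unit log2 expression),
Wald SE, OR, 95% **profile-likelihood** CI on the OR scale, Wald p,
likelihood-ratio p (`p_lr`), convergence and separation flags. Reporting
uses `p < 0.05`; selection uses strict `p < 0.01`, unadjusted (a BH q
column is attached for information only, never used for selection).

Profile CIs were chosen because printed intervals of this kind of analysis
are asymmetric around the OR on the log scale (e.g. an OR of 204 with CI
12–15,706), which Wald intervals cannot produce; Wald p-values were kept
as the selection statistic because they are what standard GLM summaries
print and the magnitude of published p-values of such panels is consistent
with z-statistics, not with LR statistics.

Two small-sample properties of this screen are measured, documented, and
deliberately not "fixed", because they are properties of the mirrored
design itself:

* **Conservatism.** At n = 38 the Wald test rejects well below nominal
  level: on all-null synthetic cohorts the fraction of genes with Wald
  p < 0.05 is ≈ 0.02–0.03 (the LR p is near-nominal at ≈ 0.035–0.05).
  The pair random effect adds to this, because the unpaired test ignores
  a positive within-pair correlation. Verified against an independent
  implementation (statsmodels) to 1e-8: this is the test's behavior, not
  a fitting defect.
* **Separation / Hauck–Donner.** For effects beyond roughly 3–4 sigma at
  this n, fits separate: |beta| diverges, the Wald SE diverges faster, and
  the Wald p collapses toward 1 — the screen can *fail to select its
  strongest genes*. Fits flag separation (`separation_flag`), stop at the
  bound |beta| > 20, and the LR p (which remains small) is reported
  alongside precisely so such genes are visible.

## IRLS and profile likelihood

Fits use Newton/IRLS with step-halving, convergence at relative
log-likelihood change < 1e-8 (max 100 iterations), separation declared at
|beta| > 20 with a still-improving likelihood. Collinear designs fall back
to a pseudo-inverse and are flagged. Profile CIs invert the LR test at the
chi-square(1) 0.95 cutoff by bracketed root-finding on the profile
log-likelihood (intercept re-maximized at each fixed slope, initialized at
`logit(ybar) - b*mean(x)` to avoid weight underflow at large offsets);
bounds beyond ±500 on the log-odds scale are reported as infinite.

## Combined score and AUC

The signature is the ML multivariable logistic fit on the selected genes;
its score is the linear predictor. With ~5 strong predictors and 38
samples, quasi-separation of the joint fit is the norm: the fit stops,
flags itself, and the score is still a valid *ranking*, which is all AUC
uses. No probability threshold is applied anywhere.

AUC is computed from midranks (Mann–Whitney form), which handles ties
exactly and equals the trapezoidal area of the emitted ROC curve to
machine precision; the O(n^2) pair-counting definition is kept in the test
suite as an oracle. External validation applies the frozen model — exact
gene order, coefficients fixed — with no refitting by construction.

## Selection-aware bootstrap

One estimator object implements filter → screen → select → fit, and the
bootstrap re-runs that same object on every resample, so "the same
procedure as the main analysis" holds by construction rather than by
discipline. The resampling unit is the matched pair: P pair ids drawn with
replacement, each contributing its case and its control, duplicates
relabeled so design invariants keep holding.

Two summaries:

* **percentile** (default): mean and 2.5/97.5 percentiles of per-iteration
  apparent AUCs (each refit model on its own resample).
* **optimism**: Harrell's correction — per iteration, optimism =
  (apparent AUC on the resample) − (same model's AUC on the original
  data); corrected AUC = (full-data apparent AUC) − mean optimism.

Iterations in which no gene passes selection are *degenerate*: they record
the no-information AUC 0.5 and are counted (`n_degenerate`); dropping them
would bias the interval upward. When the full-data fit itself is
degenerate the full-data apparent AUC is likewise 0.5, and the corrected
value can fall somewhat below 0.5 — on all-null 19-pair cohorts it lands
near 0.38, versus apparent bootstrap means of 0.7–0.85. The gap between
those two numbers is the selection optimism this machinery exists to
expose. The standard correction formula is kept without special-casing
degenerate full fits. Default B = 30,000 matches the full-scale protocol;
tests and the acceptance script use B = 200 as the package's scaled-down
default problem size.

Per-iteration seeds derive from the master seed by a counter scheme, so
results are independent of execution order.

## qPCR normalization

Triplicate Cq values are averaged (replicate SD > 0.5 cycles raises a
flag; nothing is auto-dropped). Relative quantities use
`q[s] = E^(minCq − Cq[s])` with the gene's lowest mean Cq (its
highest-expressing sample) as calibrator — so `q ∈ (0, 1]`, max exactly 1,
invariant to any constant Cq shift. Default efficiency E = 2 (perfect
doubling) unless an efficiency table is supplied. The per-sample
normalization factor is the geometric mean of the housekeeping-gene
quantities (default reference set ACTB + ITGA2B jointly, as fixed
references); normalized values are exactly invariant to per-sample loading
effects. GeNorm stability `M_j = mean_{k≠j} SD_samples(log2 q_j/q_k)`
(ddof = 1) is reported for the reference set; iterative least-stable-gene
elimination is available (`rank_reference_genes`) but off by default.

## Known limitations

* The screen inherits the small-sample pathologies of unpaired Wald
  logistic tests (conservatism, Hauck–Donner) by design; `p_lr` is the
  built-in diagnostic for both.
* Percentile intervals of apparent bootstrap AUCs describe the optimism
  phenomenon, not out-of-sample performance; use optimism mode for a
  de-biased point estimate.
* No multiplicity control in the selection path (faithful to the mirrored
  protocol); the BH column is there for anyone who wants it.
* The generators produce Gaussian log2 data with independent genes; none
  of the pipeline's guarantees have been exercised against correlated
  gene-gene structure.
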