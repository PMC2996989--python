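# Methods

## Model

All three score families measure departure from a multiplicative
neutrality model of independent gene effects on exponential growth.
Fitness is identified with the logarithmic growth rate *m* (1/min), so
relative fitness and rate ratios are interchangeable.

* **F-score** (per environment): `eps_fit = m(X,Y)·m(wt)/(m(X)·m(Y)) − 1`.
  Negative = aggravating (double worse than expected), positive =
  alleviating.
* **Sensitivity**: `S = m(E1)/m(E2)` with E1 the reference and E2 the
  perturbed environment.  A perturbation that slows growth gives S > 1,
  and more-affected strains have larger S.
* **ES-score**: `eps_env(X) = S(ref)/S(X) − 1`, the relative change in
  sensitivity caused by deleting X (reference = wildtype, or a single
  mutant when scoring a deletion in that background).  With this
  orientation, perturbation-hypersensitive mutants score negative.
* **S-score**: `eps_sen = S(X,Y)·S(wt)/(S(X)·S(Y)) − 1`, epistasis in
  sensitivity space.

The identity `eps_sen = (1+eps_fit(E1))/(1+eps_fit(E2)) − 1` holds exactly
whenever all scores are computed from the same mean rates; the test suite
verifies it symbolically on random rate sets to 1e-12.  Consequently the
S-score responds only to environment-modulated interactions; interactions
of equal strength in both environments have eps_sen = 0 exactly.

All scores are computed from mean rates; replicate CVs travel alongside
and enter only the significance machinery.  When both a measured and a
pooled-estimate single-mutant rate exist, the measured one is used unless
the gene is on an explicit override list.  The pooled estimate for gene X
is the median over partners Yi of `m(X,Yi)·m(wt)/m(Yi)`; estimates
deviating more than 5% from the measured rate are flagged.

## Growth-rate estimation

Rates are ordinary-least-squares slopes of ln(OD) against time, using
only readings with OD in [0.1, 0.4] *and* time in [60, 360] minutes
(both bounds conjunctive; per-strain window overrides are a config
choice, not automatic).  Non-positive OD readings inside the window are
excluded before the log.  A replicate is rejected — recorded, not raised
— when fewer than `min_points` usable readings remain (default 10; set
12 for noisier perturbed-environment data).  Fits with R² < 0.95 are
flagged but kept, a stand-in for manual curve inspection.  No
blank/baseline subtraction is applied by default.  Lag and stationary
phases are out of scope; the OD window is what excludes them.

## Significance

P values are parametric-bootstrap with the null imposed on the double
mutant: per trial its rate is drawn from a normal with mean `m0` at the
neutral expectation and variance `m0²·(cv1² + cv2²)`, where cv1 is the
CV of the measured double-mutant rate and cv2 the library-median CV of
all double-mutant rates (computed per environment, since perturbed
cultures are noisier).  P values are two-sided by absolute value with
the add-one rule `(1 + #{|eps_trial| ≥ |eps_obs|})/(n_trials + 1)`, so no
P value is ever 0; the default is 300,000 trials.  Draws that would give
non-positive rates are redrawn (cap 100, then the trial is discarded and
counted).

Two interpretive choices deserve emphasis:

* **CV scale.**  All CVs entering the bootstrap are uncertainties of the
  *measured mean rate* — replicate-level cv divided by √n.  Using
  replicate-level CVs directly would widen the null by roughly √n of the
  double-mutant replicate count and drive type-I error to zero.
* **Null-mean mode.**  By default (`per-trial`) the wildtype and single
  rates are redrawn each trial and m0 recomputed from the draws.  The
  drawn references then cancel algebraically from the trial statistic,
  so the trial F-score is exactly a relative deviation
  `N(0, cv1²+cv2²)` truncated to positive rates; the S-score trial is a
  ratio of two such deviations, one per environment, with fitness
  neutrality imposed per trial in each environment (which jointly imposes
  sensitivity neutrality).  A `fixed` mode (m0 from observed means, full
  recomputation of the trial score from drawn references) is available
  for sensitivity analysis and is somewhat more conservative.

The ES-score null (S(X) = S(wt)) uses the classic full-redraw
construction: the three reference means are drawn around their observed
values, the perturbed-environment mutant rate around the
gene-environment-neutral expectation with its own measured CV, and the
trial ES-score is recomputed.  There is no cv2 analogue for single
mutants; under the cancellation construction the ES null would collapse
to a single CV term and reject vastly too often, while the full-redraw
null is exact under the synthetic no-interaction model.

### Calibration

Type-I error was measured on independent synthetic pair experiments at
the default study conditions (19 wildtype/single and 4 double replicates,
replicate cv 0.03, CVs estimated from the replicates as in a real
screen).  Long-run rejection rates at nominal alpha = 0.01/0.05:
F 0.018/0.062, S 0.013/0.056, ES 0.011/0.051.  The S and ES families are
within ±0.01 of nominal at both levels.  The F family is slightly
anti-conservative at alpha = 0.05 (≈ +0.012): the 3-degree-of-freedom
double-mutant CV estimates fatten the observed score's tails somewhat
more than the cv2 term widens the null.  Replacing the standard SD
estimator with the small-sample unbiased (c4-corrected) one centres the
F family (0.011/0.044) but over-widens the four-CV S-score null
(0.007/0.035); since no uniform estimator policy centres every family and
mixing policies per family would be result-driven, the package keeps the
standard estimator and documents the residual +0.01-scale F-family
anti-conservatism as a property of the method.  Raw P thresholds are the
default throughout (as in the original analyses); Benjamini–Hochberg
adjustment is available but never applied implicitly.

Single-mutant growth defects are tested against the wildtype with a
two-sided Welch t-test (replicate or summary-statistic form).  F-family
interactions are assigned to environments by the four-way rule at
alpha = 0.01: significant only in E1, only in E2, in both, or neither.

## Downstream analyses

* **Calling**: threshold (strict P < alpha) or top-k by P with
  deterministic tie-breaking (larger |eps|, then pair name).  F-family
  pairs are called once across environments with the assignment label.
* **Enrichment**: upper-tail hypergeometric tests (including the observed
  count) of evidence categories among called pairs; the fold enrichment R
  is the ratio of hit frequencies.  Co-binding of two factors to common
  differentially expressed targets uses the same test over the
  differential-expression universe.  The "any evidence" category counts a
  pair once regardless of how many categories support it.  Exactness is
  verified against exhaustive subset enumeration on small universes.
* **Masking**: masking of Y by upstream X is an alleviating, significant
  interaction whose score equals the masked gene's single-mutant
  signature: `|eps_sen − eps_env(Y)| < delta_thr` (sensitivity family) or
  `|eps_fit − (W_wt/W_Y − 1)| < delta_thr` (fitness family, evaluated in
  a chosen environment, by default the perturbed one where the phenotypes
  are expressed).  Alleviating means negative eps_sen (sensitivity) or
  positive eps_fit (fitness); both conventions are overridable.  Both
  directions of every pair are always evaluated; unassayed directions are
  excluded from both TPR numerator and denominator, and the FPR universe
  is every other assayed direction.
* **Clustering**: genes are leaves; dissimilarity is 1 − Pearson
  correlation of S-score profile rows over shared unmasked partners,
  excluding the mutual cell so d(i,j) is driven by third-party profiles;
  agglomeration is average linkage.  Signed scores are clustered (the
  aggravating/alleviating distinction carries the structure).  Pairs with
  fewer than 3 shared partners are flagged unstable; undefined
  correlations raise with the offending pair named.  Optional support is
  a plain column-resampling bootstrap (fraction of resampled trees
  reproducing each node's leaf set, over non-degenerate resamples) — not
  a multiscale-corrected support, and intended qualitatively.

## Synthetic libraries

The generator plants truth at the level the scores measure it:
`m(X,Y,E) = (1+eps_fit(E))·m(X,E)·m(Y,E)/m(wt,E)`, with per-gene relative
fitness per environment and replicate rates drawn as
`mean·(1+Normal(0, cv))` truncated positive (lognormal optional).
Defaults mirror a realistic microplate screen: wildtype rate 0.0077/min
untreated and 0.0062/min perturbed, 19 wildtype/single and 4 double
replicates, replicate cv 0.03, and an optional unassayed-pair fraction
(2.8% in the 26-gene presets, ≈316 of 325 pairs assayed).  What it does
not emulate: plate spatial effects, evaporation, lag/stationary phases,
batch structure, or strain-construction artefacts — so green tests
certify the statistical machinery under the stated noise model, not
robustness to those real-data pathologies.

Presets: `null` (no pairwise epistasis and environment-equal single
effects, so all three score families are truly zero), `static` (every
pair at eps_fit = 0.3 in both environments), `modulated` (eps_fit 0
untreated vs −0.4 perturbed, hence eps_sen = 2/3), `complex` (three
complexes of 3/4/3 genes with equal within-complex phenotypes; the
middle one purely co-equivalent so masking holds in both score spaces,
the other two with an extra environment-independent double-mutant defect
g = 0.8 that preserves sensitivity masking — the factor cancels from the
rate ratio — but breaks fitness masking), and `two_module` (two 5-gene
modules, eps_sen −0.4 within and +0.3 between, cv 0.02, for clustering).

One measurement subtlety: every score in a library shares the wildtype
means, so a single library's median score is offset by the wildtype
measurement error (sd ≈ 0.01 at 19 replicates and cv 0.03).  Tests of
distribution centring therefore pool several independently generated
null libraries.

## Problem sizes and determinism

The shipped tests and the acceptance script use 26-gene libraries
(≈316 assayed pairs), 2000 independent pairs for calibration, and 10⁴
bootstrap trials (the 300,000-trial default is for production runs);
the bootstrap cores are vectorised over pairs with draws chunked at
2×10⁶ values.  Every stochastic step takes an explicit seed
(`numpy.random.default_rng`); identical seeds give bit-identical P
values, tables and CLI outputs, and each CLI run writes a manifest
recording inputs, parameters, seed and version.

## Known limitations

* The F-family bootstrap is ≈0.01 anti-conservative at alpha = 0.05
  under the default replicate design (see Calibration).
* CVs estimated from 4 replicates are individually unreliable; the
  library-median cv2 term is the method's own stabiliser, not a
  variance-component model.
* The masking FPR denominator counts all non-expected assayed
  directions, including within-complex ones when a complex definition
  excludes some members.
* Bootstrap clustering support resamples profile columns jointly for all
  genes and is a qualitative guide only.
* File formats are deliberately minimal (tab-delimited text); no
  plate-reader vendor formats or external-database retrieval.
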