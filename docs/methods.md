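# Methods

## Niche decomposition and the specialization index

The core quantity is the within/between variance decomposition of a
population's isotopic niche (in the Roughgarden tradition). For
individual *i* with *m* delta values along its whisker, the individual
niche width INW<sub>i</sub> is the sample variance of the series, and
the between-individual niche width BINW is the variance of the
per-individual means across the sampled population. The total niche
width TNW = mean(INW) + BINW, and

SI<sub>i</sub> = INW<sub>i</sub> / (INW<sub>i</sub> + BINW).

Small SI means the individual occupies a narrow slice of the population
niche. Classification uses strict thresholds — specialist below 0.2,
generalist above 0.5 — with boundary values assigned to the
intermediate class. NSI (from δ15N) and CSI (from δ13C) are computed
independently, never pooled across elements. BINW is computed once for
the whole multi-site population, not per site.

Two deliberate choices here:

* **BINW dialect.** "Between-individual niche width" is sometimes
  described as the total variance of all pooled values, which breaks
  the additive decomposition TNW = mean(INW) + BINW. The default
  dialect is `between-means` (variance of individual means), which
  keeps the decomposition exact; `total-variance` is available behind a
  flag for sensitivity analysis.
* **Variance divisor.** Sample variances use divisor n − 1 by default.
  With only three segments per whisker this choice is material
  (divisor n would shrink every INW by a third); it is configurable
  (`ddof`).

### Finite-segment bias — what SI estimates from 3-segment whiskers mean

With *m* segments, INW is a scaled chi-square variable
(σ²<sub>W</sub>·χ²<sub>m−1</sub>/(m−1)) and BINW concentrates on
σ²<sub>B</sub> + mean(σ²<sub>W</sub>)/m. Because x ↦ x/(x+c) is
concave, E[SI] is *below* the asymptotic variance ratio
σ²<sub>W</sub>/(σ²<sub>W</sub>+σ²<sub>B</sub>) for moderate true SI
(Jensen), while near SI = 0 the analytical-noise floor pushes estimates
*up*. At the default study conditions (m = 3) the net downward bias of
the population mean is about 0.07; it shrinks monotonically with m in
the noise-free case and vanishes asymptotically.
`simulate.expected_si_estimate` computes the exact finite-m
expectation by quadrature under this law (neglecting the
O(1/n_individuals) sampling noise of BINW itself), and the test suite
verifies the Monte-Carlo mean of pipeline estimates against it.
Practical consequence: SI values from few-segment whiskers are
informative about *ordering* and class membership, but their absolute
scale is compressed toward the specialist end at high SI and inflated
near zero; comparisons should be within-design, not across designs with
different segment counts.

## Whisker chronology

Growth follows L(t) = L∞(1 − e<sup>−k(t−t0)</sup>). The daily-discrete
variant steps L<sub>d+1</sub> = L<sub>d</sub> + (L∞ − L<sub>d</sub>)(1 −
e<sup>−k</sup>), whose closed form coincides with the continuous curve
at integer days, so the two modes differ only in how lengths between
integer days are treated; they agree within one day for k ≤ 0.05/day on
whiskers up to 0.9·L∞ (asserted in tests). Material at distance d below
the base lay at the growing tip when the whisker was (total − d) long,
so its deposition date is the collection date minus the age difference;
dates are whole days with sub-day remainders truncated toward the
collection date. The whisker is assumed actively growing (base =
"now"); tip wear is ignored.

Segment planning works greedily from the base: cut an isotope segment
whose estimated mass hits the target (default: midpoint of the
0.2–0.5 mg analytical window), then a buffer spanning a fixed duration
of growth (default 11.3 days), repeat. Mass converts to cut length
through a linear-density profile (uniform by default; a linear-taper
profile with a base:tip ratio is available). Fixed-duration buffers
were chosen over fixed-length ones because their purpose is temporal
independence between samples.

**Growth parameters are calibration defaults, not biology.** The
source study's von Bertalanffy parameters are unpublished. The package
defaults — L∞ = 70 mm, k = 0.022/day, t0 = 0, linear density
0.30 mg/mm, whiskers ≈ 45 mm observed + 5 mm intradermal — were chosen
so that the default three-segment plan reproduces the reported sampling
design: segments of ≈ 2.7 days of growth each, 11.3-day buffers, and a
total span of roughly one month. Intradermal length is a config lookup
keyed by whisker position label (scalar default).

## Run normalization

Raw instrument readings are corrected per run and per element by the
unique affine map sending each of two standards' raw readings to its
assigned value (USGS40: δ15N −4.52‰, δ13C −26.39‰; USGS41a: +47.55‰,
+36.55‰, both δ13C on the VPDB-LSVEC realization, no scale conversion
attempted). Replicate standard readings are averaged before fitting.
Equal raw readings for the two standards are a hard error. No
within-run drift ramp is modelled — the per-run affine map is the
minimal standard treatment; interspersed-standard designs would need a
time-indexed extension. Rejected sample rows are always reported with
row index and reason, never silently dropped.

## Isoscape

Food-item samples are pooled across the member species of each group
(groups are a fixed config table — ten groups by default — because the
grouping in the motivating study was judgment-based, not rule-based),
then summarized as mean ± SE per element. Trophic discrimination
factors (+3.5‰ δ15N, +2.2‰ δ13C) are added exactly once — a `corrected`
flag guards against double application — and consumers enter the biplot
as per-individual means over their whisker segments. SEs of n = 1
groups are reported as 0 and flagged.

## Driver selection

Gaussian linear models of the index on sex, age class (binary:
adult/yearling), mass (kg), competition level (normal/lowered) and site
are fitted for every subset of the main effects (2⁵ = 32 candidates),
plus a mass × competition interaction in models containing both parents
(marginality rule; 8 more candidates). Conventions, chosen to match the
standard information-theoretic workflow:

* treatment coding with the alphabetically first level as reference;
  intercept always included;
* logLik is the maximized Gaussian likelihood with ML variance RSS/n,
  and k counts mean parameters plus one for the variance — so an
  intercept + competition + mass model has df = 4;
* AICc = −2logLik + 2k + 2k(k+1)/(n−k−1); ΔAICc < 2 flags substantial
  support; Akaike weights are reported normalized over the full
  candidate set *and* renormalized over the supported subset;
* each supported model is compared with the intercept-only null by a
  nested F test (no multiple-testing correction);
* rows with missing values are dropped listwise with a logged count;
* candidate models whose design matrix is rank-deficient (e.g. site
  together with competition when competition level is a function of
  site, as in the motivating design) are excluded from the candidate
  set with a warning.

Site enters as a fixed effect only; no mixed models, no model-averaged
coefficients.

### Residual-normality screen

The screen simulates n_sim (default 500) normal samples of the
residual size, scaled to the residual SD, sorts each, and widens the
per-order-statistic envelope rank by rank until 95% of the simulated
curves lie entirely inside — a *global* (simultaneous) envelope, so a
correctly specified model passes in ≈ 95% of datasets (calibration
verified at 1,000 replicates in the tests). Raw pointwise 2.5%/97.5%
bands (`calibrate=False`) are retained for comparison but are
anti-conservative as a joint check. If the top model for a raw index
fails the screen, the workflow refits the entire candidate set on the
log index (`auto_log=True`); a zero index (an individual with constant
series) makes the log transform a hard error naming the individual.

## Synthetic-population generator

The generator emulates the study conditions: 71 individuals × 3
segments, population means 7.4‰ (δ15N) and −22.5‰ (δ13C),
between-individual SDs σ_B = 1.3‰ (N) and 2.8‰ (C) chosen from the
reported population ranges, analytical noise 0.1‰ per capsule, mass ~
Normal(8, 1.8²) kg truncated positive, seven sites with two
lowered-competition sites, 70% adults, 50% females, and one individual
with a blank mass record (so listwise deletion reproduces n = 70).
True SI is linked to covariates on the logit scale — intercept, mass
slope and lowered-competition offset, plus individual logit noise so
covariates explain only part of the variation (the motivating study's
top model had R² ≈ 0.17) — and within-individual variance is set to
σ²_B·SI/(1−SI) so the asymptotic variance ratio equals the configured
truth. Segment values are i.i.d. normal by default; an AR(1) option
(`ar1_rho`) probes the consequences of serial correlation that buffer
cuts are meant to remove.

Link defaults were calibrated once against the reported class
composition: the NSI link (1.2, −0.25, −0.5; logit SD 0.8) reproduces
≈ 55% specialists / 13% generalists among *estimated* indices. The two
reported CSI proportions (76% specialists *and* 18% generalists)
cannot both be reached by any logit spread once the pooled δ13C SD is
held near the reported population range — the 3-segment estimator's
tails tie the two proportions together — so the CSI link (−2.0, 0, 0;
logit SD 2.0) matches the specialist share (≈ 73%) at the cost of a low
generalist share (≈ 11%).

What the generator does *not* emulate: temporal diet trends within the
month, site-level isotopic baselines (site affects SI only through
competition), covariance between NSI and CSI beyond shared covariates,
digestibility or tissue-turnover dynamics, and measurement error in
covariates. Passing recovery tests therefore demonstrate correctness of
the estimators under the variance-components model, not robustness to
these field realities.

## Problem sizes and numerical choices

Replicate studies in the tests and the acceptance script use 150–500
replicate populations at the study scale (71 × 3) and 500-sample
envelopes at 1,000 replicates — sizes at which Monte-Carlo error is
well below the effects being checked. Quadrature expectations use the
gamma law of the sample variance. Ties in AICc ranking break
deterministically by parameter count, then model label. Degenerate
inputs (constant series, equal standard readings, whiskers too short
for a plan, SI of exactly 0 under log) raise typed errors rather than
propagating NaNs; perfect fits (RSS = 0) carry infinite logLik and
dominate any ranking.

## Known limitations

* SI estimates from few segments are biased (see above); the package
  reports the conventional estimator and quantifies the bias rather
  than attempting bias correction, which would change the index's
  published meaning.
* BINW includes a mean(σ²_W)/m contribution by construction of the
  between-means dialect; with m = 3 this inflates BINW by up to ~20%
  under the default conditions.
* The focal individual's own segments are not excluded from BINW.
* No bootstrap or Bayesian uncertainty on SI; no mixing-model source
  apportionment; no spatial interpolation of isoscapes.
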