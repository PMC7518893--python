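# Methods

## Decay model and fitting scale

Each genotype × site × year *FLC* time course is summarised by a starting
level and one or two shutdown rates.  The default model is piecewise
*linear* in time, `E(t) = S − r₁t` before the VIN3-induction day and a
continuation with slope `−r₂` after it, with abundances truncated below
at a floor (default 0.01 a.u., keeping values positive and log-safe).
Cold-driven transcript decline is often described as exponential, and a
log-linear mode (`scale="log"`) is provided for that reading; the linear
default was chosen because shutdown rates are conventionally reported in
a.u. per day — the slope of a straight line fitted to the abundance
itself — and only the linear-scale regression is dimensionally consistent
with that unit.  Rates are fitted by ordinary least squares on
replicate-level points (not day means), so the same long table feeds both
the rate estimates and the mixed-model contrasts.  The starting level is
the replicate mean ± s.e. at the first *field* timepoint; by that day
some VIN3-independent shutdown has already occurred, so it is not a
non-vernalized baseline and recovery tests compare it to the trajectory
value at that day, not to the day-0 intercept.

A configurable trailing-day exclusion (`exclusion_after_day`) supports
single-rate ("combined") fitting for seasons in which the two phases are
not separable, dropping late-winter measurements where warming-driven
*FLC* reactivation would otherwise bend the fit.  A phase window with
fewer than two distinct days yields an explicit "unavailable" note,
never a silent NaN.

## Breakpoint detection and the boundary convention

The VIN3 induction day is estimated from the reference genotype's VIN3
series: baseline = median of the first `baseline_points` (default 3)
genotype-mean values; threshold = max(baseline × `fold` (default 3), an
absolute floor of 0.05 a.u.); the induction day is the first sampled day
exceeding the threshold for `min_consecutive` (default 2) consecutive
timepoints.  The sustained-crossing requirement and the absolute floor
make the rule robust to the short-term VIN3 fluctuations that track the
temperature profile; disabling the floor makes the rule scale-invariant.
A series that never crosses returns an explicit no-induction result
(delayed-induction mutants are expected inputs).  The breakpoint is
estimated once per site and shared across genotypes, since induction
timing is set by the site's temperature profile; a fixed day can be
supplied instead.

Which window owns the breakpoint day itself depends on how it was
obtained.  A *fixed* day is read as the last slow-phase day and belongs
to the VIN3-independent window; a *detected* day is by construction the
first sampled day with VIN3 already high — the first day of the
VIN3-dependent phase — and belongs to the VIN3-dependent window.
`extract_features` resolves the default accordingly (still overridable
via `boundary=`); assigning a detected day to the slow-phase window
measurably biases the slow rate, because with weekly sampling that day
already lies one interval into the fast phase.

## Group statistics

**Dunnett many-to-one.**  One-way fixed-effects model with pooled
residual variance; each genotype-vs-control contrast is adjusted by the
equicoordinate distribution of the maximum absolute t over the correlated
contrasts, evaluated by seeded Monte-Carlo over the corresponding
multivariate t (default 200 000 draws, reported MC standard error
≤ 5·10⁻⁴).  Monte-Carlo was preferred over numeric integration for
transparency and exact reproducibility under a seed; `scipy.stats.dunnett`
serves as an independent cross-check in the test suite.

**Mixed-model slope contrasts.**  Rate differences are tested as
genotype × timepoint interactions in
`value ~ genotype * day + (1 | block)`, fitted by REML with timepoints
centered to mean 0, in a purpose-built dense implementation (designs here
are a few hundred rows at most).  Denominator degrees of freedom use the
Satterthwaite approximation: `df = 2f²/(g'Ag)` with `f` the contrast
variance, `g` its finite-difference gradient with respect to the variance
components and `A` the inverse observed REML information (numerical
Hessian).  When the information matrix is ill-conditioned — typically
when the block variance estimate sits on the zero boundary — the residual
df are used and a warning is recorded.  A single-block design falls back
to fixed-effects OLS with a logged warning.  statsmodels `MixedLM` and an
OLS-ANCOVA oracle cross-check the estimates in the tests.

**CV equality.**  The asymptotic (Feltz–Miller) statistic
`D = Σ(nᵢ−1)(cvᵢ−c̄v)² / (c̄v²(0.5+c̄v²))` with the (nᵢ−1)-weighted pooled
c̄v, referred to χ²(k−1).  Rates enter as magnitudes (variability, not
sign, is compared); that choice is recorded in the report metadata.  The
variability report runs starting-vs-rate comparisons within each
site-year and site-vs-site comparisons per feature, BH-corrected together
at q = 0.05, over genotype-level point estimates by default (a grouping
scheme argument reproduces accession-only / NIL-only / combined panels).
All groups constant gives D = 0, p = 1 rather than 0/0.

**Benjamini–Hochberg.**  Standard step-up rule with stable-sort tie
handling; adjusted p are running minima of `m·p₍k₎/k` capped at 1.
Verified elementwise against a literal brute-force implementation and
statsmodels.

## FLC-post-vern

`days to bolting = m·[FLC at transfer] + c` is fitted per genotype and
site on genotype-level means per transfer date (the plant-level option is
provided), with censored (DNF) and dead plants excluded from the means
and the exclusion counted.  Exactly two transfer points give the exact
slope with standard error and p marked unavailable; a fit with p > 0.1
(or unavailable) is flagged unreliable; a genotype with no FLC spread
across transfers (the effectively-*FLC*-free case) returns an explicit
"inestimable" result.  Cross-site averages are taken over unrounded
per-site slopes; half-up rounding to one decimal is display-only —
averaging rounded values would disagree with the unrounded mean in the
second decimal (e.g. 51.0 and 67.3 average to 59.15).

## Fitness models

Precocious bolting is summarised two ways, both reported: a plant-level
binomial-logit GLM of the bolting indicator on genotype autumn FLC, and
the genotype-level linear regression R² of bolting percentage on FLC.
Perfect separation is flagged on the result rather than raised.  The
"binomial proportions test" of survival is the two-proportion chi-square
(score) test, with a continuity-correction flag and a Fisher-exact
option.  Silique models are genotype-level OLS fits (siliques among
survivors ~ branches; branches ~ post-vern m; total siliques ~ post-vern
m + % survival with adjusted R²), plus a plant-level Poisson GLM of
counts on branches.  The minimal adequate model is found by backward
elimination on coefficient p-values, accepting a drop only when the
overall model p improves, with every step logged; exactly collinear
predictors trigger a condition-number warning and refusal to auto-reduce.
The Mann–Whitney U test enumerates the exact null distribution of U over
all assignments of the pooled mid-ranks for combined n ≤ 20 (valid under
ties; the null remains symmetric), and uses the tie-corrected normal
approximation above that.

## Synthetic data: what it does and does not emulate

The generator mirrors the field design: 6 replicates in 3 randomised
blocks per genotype × timepoint, weekly-ish sampling over days 21–97
with VIN3 induction at day 48, 12 plants per warm-transfer date with a
205-day follow-up horizon, and a 36-plant overwinter census.  Replicate
noise is multiplicative log-normal (expression data are positive and
heteroscedastic) with log-sd 0.2 — a typical qPCR replicate spread,
chosen for test power since replicate-level noise magnitudes are not
something the field data report — plus a log-normal block effect
(log-sd 0.1) shared by all genotypes within a block.  Bolting is linear
in FLC at transfer with Gaussian noise floored at 1 day; transfers
exceeding the horizon become censored DNF records.  The census draws
bolting-before-winter as Bernoulli in autumn FLC (logit link), survival
with a logit penalty for bolted plants, branching declining in the
genotype post-vern slope, and siliques Poisson in branches for survivors.

Deliberately not emulated: temperature-driven VIN3 dynamics (the
induction day is a config input, not a mechanistic output), within-season
reactivation bumps, plate/batch structure below the block level, and
between-year correlation.  Passing recovery tests therefore demonstrate
estimator correctness under the stated noise model, not robustness to
every artefact of real field qPCR data.

Default genotype presets span the observed haplotype behaviours (RV-like:
lower starting level, faster shutdown; SV-like: higher starting level,
slower early shutdown) with true parameters chosen so trajectories stay
positive across the sampled window.  In the default season the slowest
genotypes never bolt within the horizon and their post-vern value is
honestly inestimable, and one genotype yields a two-point fit without a
standard error — both situations the analysis stages must handle.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeds; identical
(config, seed) gives byte-identical tables and hash-identical pipeline
output directories.  Monte-Carlo studies use 500 seeds for coverage
checks and 2000 simulations for error-rate calibration (Dunnett
calibration runs at 10 000 draws per simulation, the single-call default
remains 200 000); these sizes give binomial standard errors of ~1% and
~0.5% respectively and complete in about a minute in total.  The
two-phase recovery study fixes truth S = 20, r₁ = 0.2, r₂ = 0.15 with
breakpoint 45 over days 10–80, the smallest round values that keep the
noiseless trajectory strictly positive across the window under the
study's noise level.  Cq values convert to concentrations as
`efficiency^(−cq)` with efficiency 2.0 by default (per-amplicon
efficiencies are accepted as configuration; window-of-linearity
estimation from fluorescence curves is upstream of this pipeline).

## Known limitations

* The linear decay default can cross the floor inside a fitting window
  for fast-shutdown genotypes; floored points then flatten the fitted
  rate.  The exponential mode avoids this at the cost of the a.u./day
  unit convention.
* The Satterthwaite implementation covers the single random-intercept
  structure used here; nested or crossed random effects are out of scope.
* The CV-equality test is asymptotic; with very small panels (< ~8
  genotype values per group) its type-I error drifts and the modified
  signed-likelihood-ratio variant (not implemented) would be preferable.
* GLM inference is Wald-based; separation is flagged but penalized
  (Firth-type) fits are not provided.
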