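# Methods

## Data model

The unit of observation is one embryo; the response is a non-negative
integer count of rosette-shaped apoptotic clusters in its optic tectum
(clusters/OT). A dose group holds either the raw counts or the summary
triple (mean m, sample SD s with the n−1 denominator, group size n); a
dataset is an ordered, strictly increasing dose series for one radiation
quality. Raw CSV rows sharing a dose are pooled into one group, because
each dose level is one experimental group of embryos. All statistics
downstream are computable from the summaries alone, and wherever raw
counts exist the summary path is algebraically identical to the raw-data
computation (proven by property tests against `scipy.stats.f_oneway`).

## Curve families and fitting

Dose x (Gy) maps to expected clusters/OT through one of four families:
linear y = cx, linear-quadratic y = αx + βx², quadratic y = βx², and the
shifted power y = (x + a)ᵖ + b with p an odd integer from {3, 5, 7, 9}.
The linear-type coefficients are constrained non-negative (the effect
cannot decrease with dose); odd p makes every shifted-power member
monotone non-decreasing on all of ℝ, including shifts that put x + a
negative on part of the dose range — that is what lets the family bend
through an inflection at x = −a, as the X-ray curve (x − 0.9)³ + 0.729
does. By default the shifted-power offset is bound to b = −aᵖ so the
curve passes exactly through (0, 0); a free-offset mode exists to
represent curves with rounded published coefficients verbatim.

The objective is least squares on the group means weighted by group size,
Σᵢ nᵢ(mᵢ − ŷᵢ)², which equals per-embryo least squares whenever the means
came from raw counts. Linear and quadratic have closed-form weighted
solutions (clipped at zero); linear-quadratic uses non-negative least
squares on the √nᵢ-weighted design. The shifted-power shift a is found by
a deterministic coarse grid (step 0.01 on [−3, 3], auto-expanding in ±3
blocks whenever the argmin lands on the grid edge, up to |a| ≤ 30)
followed by bounded scalar refinement to ~1e−8; the exponent p is
exhaustively enumerated. No random starts are used, so fits are exactly
reproducible. The auto-expansion matters in practice: on the bundled
reference data the best p = 3 shift is a ≈ 3.11, outside the initial
grid.

## Lack of fit and model selection

Whether a family "can be fitted" is operationalized as the classical
pure-error lack-of-fit F test for replicated designs:

    MS_lack = Σ nᵢ(mᵢ − ŷᵢ)² / (k − n_params)
    MS_pure = Σ (nᵢ − 1)sᵢ² / (N − k)
    F = MS_lack / MS_pure  on (k − n_params, N − k) df,

with rejection at α = 0.05 by default. n_params counts the fitted
quantities: 1 (linear, quadratic), 2 (linear-quadratic), 2 for the
constrained shifted power (a and the enumerated p) plus 1 when b is free.
Zero pooled variance makes the test undefined and raises a
degenerate-variance error rather than silently reporting p = 0; callers
that only need the curve (bootstrap refits of resampled replicates, whose
pure error can collapse to zero) can skip the test explicitly.

`select_model` fits every candidate and picks the lowest-SSE fit among
those the test accepts, with one parsimony refinement: a richer accepted
family only displaces a simpler accepted one when its SSE advantage
exceeds one pure-error mean square per extra parameter (the
extra-sum-of-squares F < 1 heuristic). Without this, the
linear-quadratic family — which nests the linear — wins on SSE by a
noise-level margin on data generated from a purely linear curve. Exact
ties break by fewer parameters, then candidate order. When nothing is
accepted, the lowest-SSE fit is returned flagged `accepted=False` with a
warning.

### A known negative result on the reference data

On the bundled published group summaries no candidate family survives the
test: linear (F = 14.93 on (4, 38) df), linear-quadratic (F = 15.10),
quadratic (F = 21.71) and the best shifted-power member (p = 3,
a ≈ 3.11, F = 15.64) are all rejected with p < 1e−5. The shifted-power
family has no amplitude parameter — its shape is fully determined by
(a, p) — and the observed response flattens between 1.0 Gy (mean 49) and
1.5 Gy (mean 64), which no convex-on-this-range member can track within
the pure error (MS_pure = 28.95; group-mean standard errors ≈ 1.6–2.2
clusters/OT). The published iron-ion curve itself predicts 87.5
clusters/OT at 1.5 Gy. The published curves are therefore treated as
given descriptive equations: all RBE reproduction uses their printed
coefficients directly, and refitting is never required to reproduce the
published RBE values.

## RBE

RBE(y) = D_reference(y) / D_test(y), reference dose over test dose at
equal effect — the standard convention, under which the steeper test
curve yields RBE > 1. Shifted-power curves invert in closed form through
the real odd root x = sign(z)|z|^{1/p} with z = y − b, minus a; the
polynomial families invert by Brent root-finding on a bracket doubled
until it contains the effect level. RBE is reported at full precision;
one-decimal display rounding matches the published 4.2 (y = 15) and 3.7
(y = 45). The bootstrap interval is percentile-based (2.5/97.5) over
embryo-level resampling within each dose group, refitting the chosen
family per replicate; summary-only groups are resampled parametrically
from a moment-matched negative binomial (Poisson when the variance does
not exceed the mean; a point mass at zero for zero-mean controls). The
reference side may be a dataset (refit per replicate) or a fixed curve —
the bundled X-ray curve is held fixed because only its 3.5 Gy group is
bundled; the curve derives from a fuller earlier dose series. Replicates
that fail to fit or invert are skipped; more than 20% skipped aborts the
interval.

## Threshold statistics

One-way ANOVA from summaries (SS_between = Σ nᵢ(mᵢ − m̄)² with the
n-weighted grand mean; SS_within = Σ (nᵢ − 1)sᵢ²), then pooled-MSE t
tests of each dose against the control on N − k df, two-sided p-values
multiplied by the number of non-control comparisons (Bonferroni, capped
at 1) — the classical post-hoc procedure; pooling also handles the
zero-variance control groups naturally, where Welch-type tests would be
undefined. Flags are set at 0.05 (significant) and 0.01 (highly
significant). The threshold interval is (highest non-significant dose
below the first significant one, lowest significant dose); all-significant
patterns report (0, lowest dose), none-significant patterns an empty
interval, and a non-monotone significance pattern is flagged rather than
raised.

## Synthetic data generator

Counts are drawn per embryo from a negative binomial with mean
μ(x) = max(0, curve(x)) and size (dispersion) parameter k, so the
variance is μ + μ²/k; k = ∞ selects Poisson, and μ = 0 gives a point mass
at zero, matching the observed 0 ± 0 control groups. The default k = 10
reproduces roughly the SD-to-mean ratios of the bundled groups at
intermediate means (e.g. SD 8.1 at mean 11.7 implies k ≈ 2.5, SD 9.2 at
mean 49 is slightly under-dispersed vs Poisson; k = 10 sits between these
regimes as a single compromise). The generator emulates between-embryo
count dispersion only: it does not model counting error, embryo mortality,
batch effects between irradiation runs, or any LET dependence beyond the
driving curve, so recovery results on synthetic data demonstrate the
pipeline's statistical correctness, not the biological fidelity of the
negative-binomial choice — the true between-embryo distribution is not
identifiable from the bundled summaries.

The recovery study run by the test suite simulates 100 seeded replicates
(5 doses 0–1.5 Gy, 50 embryos per dose, dispersion 10) from the published
iron-ion curve and bootstraps (300 resamples per replicate) the RBE at
y = 15 against the fixed X-ray curve; the 95% interval covers the
generating value 4.2302 in ≥ 90 of 100 replicates. These sizes keep the
full study under a minute while giving the coverage estimate a Monte
Carlo SE of ~2–3 percentage points.

## Numerical choices and degenerate inputs

* Tolerances: summaries must match raw counts to 1e−9; inversion solves
  to 1e−9 in dose; odd roots are exact inverses to 1e−12 relative.
* Through-origin shifted-power curves evaluate to exactly 0 at dose 0
  (b is stored as −aᵖ computed with the same sign convention).
* Empty datasets, non-increasing doses, negative doses/counts, n = 1
  groups with nonzero SD, and stated summaries that contradict raw counts
  are all rejected at construction with named errors.
* All-zero means refuse to fit (degenerate data); zero pooled variance
  refuses lack-of-fit and ANOVA (degenerate variance).
* All randomness flows through `numpy.random.default_rng(seed)`; every
  stochastic operation takes an explicit seed and is bit-reproducible.

## Limitations

* The package fits mean dose-response by weighted least squares; it is
  not a count GLM, and no dose-rate, fractionation or LET-response terms
  are modelled.
* The Bonferroni family is the dose-vs-control contrasts only, not all
  pairwise comparisons.
* RBE uncertainty reflects resampling of the test-radiation dataset (and
  the reference dataset when one is supplied); a fixed reference curve is
  treated as known without error.
* The bundled X-ray dataset holds a single dose group, enough to anchor
  the iso-effect comparison but not to refit the X-ray curve.
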