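# Methods

## Scope and model

`stressdoe` analyzes two-level full factorial forced-degradation
experiments. The k stress factors are coded to −1/+1 via
`x = (actual − midpoint)/half-range`; the 2^k runs are kept in standard
(Yates) order, first listed factor alternating fastest, because the Yates
algorithm requires that ordering (user-supplied run tables are re-aligned
to it by their coded sign pattern before analysis). The response is
% degradation of the drug peak against a single unstressed comparator at
the same nominal concentration.

The response model is the saturated multilinear polynomial in the coded
factors. On an orthogonal 2^k design its least-squares coefficients reduce
to contrast averages (`β0 = ΣY/2^k`, `β_term = column·Y/2^k`), the fit
interpolates all observations exactly, and each Yates effect equals twice
the corresponding coefficient. These identities are enforced by property
tests (contrast/dot-product equivalence against a brute-force oracle up to
k = 5; zero residuals; the ANOVA identity ΣMS = ΣY² − (ΣY)²/2^k).

Canonical term order is the Yates binary order (X1, X2, X1X2, X3, X1X3,
X2X3, X1X2X3, …), so contrast *i* of the transform maps positionally to
term *i*. Equation rendering displays main effects before interactions for
readability.

## Effect screening

An unreplicated factorial has no residual degrees of freedom, so the error
mean square is estimated by pooling the `pool_size` (default 2) smallest
effect mean squares; ties are broken by term order. Every effect — pooled
ones included, flagged as such — receives `F = MS/error_MS`, tested against
`F(1, pool_size)` at `alpha` (default 0.01; `F(1,2;0.99) ≈ 98.5`), or an
explicit `f_critical`. The screen is configurable to consider main effects
only, a convention often used when interactions are judged physically
implausible; note that on the built-in acid data the full-table screen also
flags the temperature×time interaction (F = 200), while the main-effects
screen retains temperature and time alone.

Two response-handling conventions are supported. `yates_rounding =
"nearest-integer"` (half away from zero) reproduces hand-computed Yates
worksheets, which traditionally carry integer responses; `"none"` (the
default for new analyses) keeps full precision. One caveat in the built-in
alkali worksheet: its run-7 integer response is 32 although the raw value
is 32.51, so `datasets.ALKALI_YATES_INPUT` stores the worksheet column
verbatim; analyzing the raw responses under nearest-integer rounding gives
slightly different F values and a reduced R² of 0.979 rather than 0.977.

Pareto ranking reports `100·E²/ΣE²` per effect, sorted by decreasing signed
effect (worksheet convention) or by magnitude (`pareto_sort="abs"`). The
reduced-model R² is `ΣMS(significant)/ΣMS(all effects)`; the significant
set is always an explicit argument and is never inferred silently, because
which mean squares a reported R² includes is an analysis decision.

## Surface inversion and condition choice

With all factors but one fixed, the multilinear model is linear in the
remaining factor, so solving for a target response is closed-form; every
solution is substitution-checked to 1e−6 and solutions outside [−1, +1]
are reported and marked out-of-domain, never clipped, since two-level
designs support no extrapolation. `choose_condition` holds inactive
factors at 0, tries all active factors at 0 first, then for each active
factor enumerates ±1 bound assignments of the others and solves the last
one exactly; among feasible points the smallest max-norm wins, ties broken
lexicographically. Attainability is pre-checked by corner enumeration
(multilinear functions attain box extrema at vertices) and an unattainable
target raises an error reporting the attainable range.

A `rounded(2)` model variant reproduces worksheet arithmetic carried out on
2-dp equations; full precision is the default. The two can differ visibly:
for the built-in alkali system the 10%-target temperature solves to coded
−0.886 (56.4 °C) on either variant, while the original worksheet reports
−0.86 (56.75 °C) — an arithmetic discrepancy in the source worksheet that
is documented rather than replicated.

Confirmation runs are compared to the prediction by a one-sample t-test;
zero-spread agreement is reported as exact rather than as a 0/0 statistic.

## Method validation statistics

Calibration lines are fitted by ordinary least squares
(`scipy.stats.linregress`), by default on per-concentration mean responses,
so the linearity ANOVA `F = MS_regression/MS_residual` has (1, m−2) df
(≈ F crit 7.71 for six levels at 5%); raw-replicate mode is available.
Coefficient t-tests take explicit null values — `(estimate − null)/SE` on
n−2 df — and an exactly collinear data set is flagged rather than producing
infinite statistics. Detection and quantitation limits follow ICH Q2:
`DL = 3.3σ/S`, `QL = 10σ/S` (so QL/DL = 10/3.3 identically); the σ source
defaults to the residual SD. Intermediate precision uses one-way ANOVA with
day as the group: `BMS` on d−1 df, `WMS` on d(r−1) df, `F = BMS/WMS`,
computed from explicit sums of squares (cross-checked against
`scipy.stats.f_oneway` in the tests) because the mean squares themselves
are reported, not just F. Only balanced tables are accepted; %RSD uses the
sample (n−1) standard deviation. Recovery regresses amount found on amount
added (per-level means by default) and reports per-level
`100·mean(found)/added`.

## Synthetic data

The generators emulate the three input structures the pipeline consumes:
factorial responses as a known multilinear polynomial plus i.i.d. Gaussian
noise (optionally expressed as stressed/unstressed peak areas); calibration
points as a noisy straight line; precision tables as
`nominal + day_effect + replicate_noise` with independent between-day and
within-day components. Each generator draws from one explicitly seeded
`numpy.random.default_rng` stream — no global state — and is
bit-reproducible per seed. The default factorial scenario uses the acid
system's magnitudes (intercept 18.32%, dominant temperature effect 10.26%,
time effect 4.56%) with 0.5% response noise, a realistic chromatographic
repeatability for peak-area ratios.

What the synthetic data do **not** emulate: chromatographic drift,
integration error correlated across runs, heteroscedastic detector noise,
day effects in the factorial experiments, or degradation kinetics. Passing
parameter-recovery and calibration tests therefore demonstrates
correctness of the statistical machinery under its own assumptions, not
robustness of conclusions from real chromatograms.

Monte-Carlo checks and their sizes: coefficient unbiasedness over 500
draws (tolerance 3 pooled standard errors); one-way ANOVA type-I error
0.05 ± 0.02 over 2000 tables; screening power over 200–500 simulations per
scenario; confirmation-run t-test null behaviour over 1000 draws. These
sizes give comfortable Monte-Carlo margins while keeping the full suite in
a few seconds.

## Numerical choices and degenerate inputs

* Rounding half away from zero for worksheet mode (7.5 → 8, −7.5 → −8).
* Pooling ties broken by term order (stable argsort); error df = pool size.
* Zero error MS: F is reported as +∞ for nonzero effects, 0 for zero ones.
* All-zero effects make Pareto normalization undefined → explicit error.
* Inversion slope below 1e−12 → no-solution error; substitution tolerance
  1e−6 (relative above |target| = 1).
* Coded values beyond ±1 are accepted by decode/predict but emit an
  extrapolation warning.
* Factor specs with high ≤ low, duplicate factor names, k outside 1–12,
  non-power-of-two response vectors, unbalanced precision tables, and
  records carrying inconsistent areas+response are all rejected with typed
  errors.

## Known limitations

Only full 2^k designs (no fractions, centre points, blocking, or
second-order designs); single-response optimization; the calibration block
reports the statistics of the fitted data set and cannot reconstruct
quantities whose raw inputs are unavailable (e.g. a detection limit quoted
without its underlying response SD). The pooled-error F test is exact only
under the assumption that pooled effects are truly null; pooling the
smallest observed mean squares biases the error estimate downward, so
screening p-values are approximate — the Pareto chart is the recommended
corroboration, as in standard DOE practice.
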