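# Methods

## The measurement model

The package analyses the classical dual-isotope terminal-sample design for
BBB transport. Each animal is an independent observation: at its terminal
time t it contributes one serum sample (counts of test tracer and albumin
marker in a 50 µL aliquot) and one dissected brain (weights and counts per
region for both isotopes). Counts are assumed spillover-corrected per
channel by the counter; dual-isotope crosstalk is out of scope.

Uptake is modelled as irreversible unidirectional influx plus a rapidly
equilibrating vascular compartment:

    Am(t) = Ki ∫₀ᵗ Cp dτ + (Vi + Vv) · Cp(t)          [tracer, cpm/g]
    Am_alb(t) = Vv · Cp_alb(t)                         [marker, cpm/g]

Dividing by serum concentration and subtracting the marker ratio gives the
Patlak line ΔB/S = Ki·Expt + Vi with Expt = ∫₀ᵗCp dτ / Cp(t). Because each
animal yields a single timepoint, the serum curve Cp(τ) needed for Expt is
estimated at the group level (genotype × sex by default; per sex or pooled
as options — with one sample per animal a per-animal curve does not exist).
Each animal then contributes one (Expt, ΔB/S) point, and Ki ± SE, Vi ± SE,
r and the two-sided slope p come from ordinary least squares over the
group's animals.

Assumptions worth stating: serum decay is log-linear over the sampled
window (mono-exponential); the marker does not cross the BBB on this time
scale; tracer degradation products do not re-enter either compartment; and
regional counts scale with dissected weight.

## Decision rules

* **Transport flag.** A region shows transport only when the Patlak slope
  is *positive* with p < α (default 0.05). A significantly negative slope
  is an anomaly, not transport. Where transport is non-significant the
  intercept has no meaning, so Vi is reported non-measurable: by
  construction the "ns" set and the "nm" set always coincide.
* **Negative values.** Negative ΔB/S points and negative fitted Vi are
  legitimate (early times, low-binding regions) and are never clamped.
* **"Linear portion".** Both the serum fit and the Patlak fit accept an
  explicit window. An automatic rule (drop earliest points while r²
  improves by > 0.01, keeping ≥ 4 points) exists but is off by default and
  always logged — silent automatic windowing would make results
  irreproducible. Default: all points.
* **Whole brain** is the weight-and-count sum of all dissected regions
  except the olfactory bulb, making its B/S the region-weight-weighted
  mean of the included regional ratios.
* **Vascular space** is the marker B/S collapsed across time per group ×
  region (mean ± SE). Collapsing is justified per cell by regressing
  marker B/S on terminal time; the summary flags cells where that trend is
  significant (p < 0.05), in which case a time-collapsed mean is invalid.

## Serum clearance and exposure time

The clearance fit is OLS of log₁₀ concentration on time; half-life is
0.301/|slope|. The constant 0.301 is the rounded log₁₀2 and is used as
printed on the default path for compatibility with the field's convention;
`half_life_constant=math.log10(2)` gives the full-precision path. The
identity half_life · k = ln 2 therefore holds only to ~1e−3 relative on
the default path.

Expt uses the closed form (e^(kt) − 1)/k of the fitted mono-exponential
(computed with `expm1`, so the k → 0 limit Expt → t is exact). An
empirical path integrates the fitted curve by trapezoid on a 4097-point
grid (worst-case ~5e−7 relative against the closed form at k = 1/min,
t = 10 min; a coarse grid of a few hundred points is *not* sufficient for
1e−6 agreement, which is why the default grid is dense). The closed form
is verified against adaptive quadrature in the acceptance checks.

## Dose correction

Injected dose varies per animal. Because both isotopes share the syringe,
a per-animal dose factor multiplies serum and brain counts of both
channels alike and cancels algebraically in every B/S ratio. It does not
cancel in the group serum fit, where it acts as extra scatter on the
fitted k. The `dose_correction="marker"` analysis option divides each
animal's tracer serum level by its marker serum level before the clearance
fit — the marker is near-constant over 10 min, so this removes dose
variation exactly at the cost of shifting the fitted rate by the marker's
own clearance (0.005/min by default, a ~2–5% effect on k). The default
path fits raw tracer serum.

## The synthetic generator

`default_config()` encodes the reference study: 4 genotype × sex groups
(apoE3/apoE4 targeted-replacement mice) × 10 animals, terminal times
assigned round-robin over 10 values evenly spread across 0.5–10 min, 50 µL
aliquots, and 11 dissected regions. Ground-truth Ki/Vi/Vv per group ×
region are seeded from reported group-level estimates of insulin BBB
kinetics in these mice (regions without measurable transport get Ki = 0,
Vi = 0; one configured Vi is negative, −2.91 µL/g, as estimated for the
E3-female hypothalamus — allowed because Vi + Vv stays positive). Whole
brain is *derived* downstream, so the recoverable whole-brain truth is the
weight-weighted mean of the dissected truths
(`SimulationConfig.whole_brain_truth()`); the configured whole-brain
reference entries are kept for reporting but cannot be recovered exactly
alongside the regional values, since the published regional and
whole-brain estimates are not mutually consistent under aggregation.

Declared assumptions (not observable from B/S ratios, which are
scale-free): blood volume 1.5 mL → C₀ ≈ 667 (tracer) and 333 (marker)
cpm/µL from 1×10⁶ / 5×10⁵ cpm injected; serum elimination k = 0.23/min
(females) and 0.10/min (males), matching the reported >2-fold faster
female clearance; marker clearance 0.005/min (effectively flat over
10 min); mean region weights totalling ~0.45 g with ~10% SD.

Noise models: `none` (deterministic expectations, mean weights — inverts
exactly), `poisson_counts` (integer Poisson draws on every expected count,
gamma-counter statistics; configs whose expected serum counts would give
> 1% zero draws are rejected as unusable designs), and `lognormal_cv`
(mean-one multiplicative lognormal). Per-animal dose variability is a
separate mean-one lognormal factor (`dose_cv`, 0.05 under the noisy
default, 0 under `noise=False`) so the noiseless-with-dose configuration
needed to demonstrate cancellation is expressible. Identical
(config, seed) gives bit-identical datasets.

What the generator does **not** emulate: biological between-animal
variability in Ki/Vi/Vv (every animal in a group shares the truth),
bi-exponential distribution phases (available via `tracer_fast_phase`, off
by default), tracer degradation, capillary depletion, or cerebral blood
flow. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated measurement model, not robustness to
model misspecification in real data.

## Statistics

Line comparisons use the extra-sum-of-squares F test: separate lines vs
common-slope (slope homogeneity, q = k−1, denominator df = N−2k), then
common-slope vs single line (elevation). The elevation result carries a
flag for whether its common-slope premise survived; both are always
computed since k-group comparisons are routinely read both ways. For two
groups the slope test equals the textbook two-slope t test squared.
Per-region comparisons are reported unadjusted; family-wise adjustment is
available via `sidak_adjust`.

Two-way ANOVA requires a balanced design with non-empty cells (unbalanced
designs are rejected rather than silently reinterpreted) and delegates the
fit to statsmodels OLS/anova_lm, which equals the classical
sums-of-squares decomposition in the balanced case; an all-constant
response is returned as a degenerate table with NaN F ratios. Post-hoc
pairwise comparisons use the residual mean square and Šidák adjustment
1 − (1 − p)^m.

## Numerical choices and edge cases

* OLS via `scipy.stats.linregress` (slope/intercept SEs, r, p) and
  `numpy.linalg.lstsq` for the multi-group designs.
* Fits require ≥ 3 points and non-constant x; violations raise
  `FitError`. Inside the pipeline an unfittable group × region cell is
  recorded as `None` and logged, while an unfittable serum fit aborts the
  run (nothing downstream is defined without it).
* Animals with a non-positive serum count are excluded up front, each
  exclusion logged with its reason; non-positive serum concentrations
  inside a clearance window are dropped with a warning.
* Exactly time-flat marker ratios (noiseless data) get a time-trend p of
  1 rather than an undefined regression p.
* Dose-factor cancellation is exact algebraically but only
  float-exact (~1e−15) numerically, since multiplicative factors are
  rounded per operation; tests assert it at float precision.
* Study CSVs round-trip at full float precision; results tables are
  written at 6 significant digits with a full-precision JSON sidecar.

## Known limitations

* **Interval coverage at n = 10.** A ±2·SE interval around an OLS slope
  from 10 points has ideal-case coverage P(|t₈| ≤ 2) ≈ 92%, not 95%.
  Under Poisson counting noise the ΔB/S scatter grows with exposure time —
  exactly the high-leverage points — so the homoscedastic OLS standard
  error underestimates the slope's sampling variance and measured coverage
  at the reference design is ~79% (computed by the acceptance script over
  500 replicate studies). This is a property of the design and estimator
  (single count per sample, plain OLS, strong clearance in females), not
  of the implementation; weighted fits or longer counting times would
  restore nominal coverage but are outside the standard method.
* Monte-Carlo problem sizes used by the test-suite and acceptance script —
  500 replicate studies for coverage, 2000 replicates for the type-I error
  of the slope test, 100 random ANOVA fixtures — were chosen to give
  Monte-Carlo standard errors well below the decision margins.
* The regression comparison assumes independent Gaussian residuals within
  groups; Patlak points within a group share one fitted serum curve, so
  their exposure times are weakly dependent. The effect is negligible at
  realistic serum counting precision.
* Unbalanced ANOVA, mixed models, efflux estimation and compartmental
  modelling beyond the Patlak linearisation are out of scope.
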