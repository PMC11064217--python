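# Methods

## The problem

Long lake-water total phosphorus (TP) records are needed to understand
eutrophication history, but monitoring rarely extends past a few
decades.  Two independent paleolimnological inferences exist: a
diatom transfer-function reconstruction (DI-TP, taken here as an input)
and a sediment-geochemistry inference (SI-TP), which this package
implements together with the statistics used to compare the two.

## SI-TP: steady-state mass-balance inversion

The lake is a steady-state phosphorus box.  Inflow load `L_in`
(mg P m⁻² yr⁻¹, per unit lake area) splits into permanent burial
`L_sed = R_P · L_in` and outflow export `L_out = (1 − R_P) · L_in`, and
outflow export is `q_s · TP` where `q_s` is the areal water loading
(annual outflow volume / lake area, m yr⁻¹).  Eliminating `L_in`:

    TP(t) = L_sed(t) · (1 − R_P) / (R_P · q_s)        [µg L⁻¹]

`L_sed(t)` comes from dated cores as `p_conc × MAR` (mg g⁻¹ ×
g cm⁻² yr⁻¹ × 10⁴), divided by a per-core focusing factor `F` to
convert a core-local to a lake-wide flux.  The steady-state form was
verified against an independent discrete-time box model
`dTP/dt = (L_in − L_sed − q_s·TP)/z̄` iterated to convergence; the two
agree to better than 0.1% over a 9×9×9 grid of (L_sed, R_P, q_s)
(`tests/test_acceptance.py`).

**Anchoring.**  `R_P` is not taken from regional regressions but
calibrated: with `L_out = q_s × mean monitored TP` over the monitoring
window and `L_sed_cal` the mean burial flux over the same window,
`R_P = L_sed_cal / (L_sed_cal + L_out)`.  Algebraically this forces the
mean inferred TP over the window to equal the mean monitored TP
(identity to rounding; property-tested at 1e-9 relative).  The
consequence, worth stating plainly: the modern end of an SI-TP record
agrees with monitoring *by construction*; only its shape and its
pre-monitoring levels are informative.

**Focusing.**  Strategies: `none` (F = 1), `fixed_factor` (user-supplied
per-core F, the default), and `hakanson`, a documented heuristic from
the lake's dynamic ratio (√area/mean depth) that estimates the
erosion/transport area share and returns F = 1/(accumulation fraction)
≥ 1.  The heuristic is deliberately pluggable: published focusing
corrections are site-calibrated, and because anchoring rescales the
whole record, a core-wide constant F cancels out of the final TP record
— focusing choices matter only through the *relative* weighting of
cores in the multi-core mean.

**q_s estimation.**  Where no long outflow record exists, `estimate_qs`
regresses a short monitored outflow series on a long reference gauge
(OLS), predicts annual outflow volumes over the calibration years, and
divides their mean by lake area.  Negative predictions are floored at
zero with a warning.

**Aggregation.**  Cores are linearly interpolated onto an annual grid
(no extrapolation beyond a core's dated range); the aggregate is the
per-year mean of covering cores with min/max envelope and a coverage
count.  Because the inversion is linear in flux at fixed (R_P, q_s),
averaging fluxes then inverting equals inverting per core then
averaging; the package inverts the aggregate and also reports per-core
records on the same grid.

## Diagenesis correction (two-fraction model)

Freshly deposited sediment P contains a stable fraction and a labile
fraction that decays first-order after burial (rate `k`, yr⁻¹),
returning to the water column.  The decaying pool creates a transient
surface-ward enrichment (the "stationary peak") that is not part of the
depositional signal; left in place it inflates the calibration-window
flux, inflates `R_P`, and therefore depresses the whole pre-modern
record.  Measured concentration against burial age τ follows

    p(τ) = a + b · exp(−k·τ)

`penn_fit` fits (a, b, k) per core by bounded multi-start nonlinear
least squares (k started at {0.01, 0.03, 0.1, 0.3} yr⁻¹, bounds
a, b ≥ 0, 0 < k ≤ 10); `penn_correct` subtracts the fitted transient
`b·exp(−k·τ)`, i.e. corrects each sample to the concentration it will
hold after full labile decay — the permanently buried P that SI-TP
interprets.  Both branches (raw and corrected) are re-anchored
independently, which is what lifts the corrected record's older section
relative to the raw one.

**Fit window and pooling (important).**  Two failure modes were
measured during development and drive the pipeline defaults:

1. Fitted over a whole core that records a secular eutrophication rise,
   the exponential latches onto the *trend* (k → ~1/century,
   b → the full surface concentration), which can zero out the recent
   record entirely.  The pipeline therefore fits only samples buried
   ≤ 30 yr (`penn_max_burial_age_yr`), the home of the stationary peak.
   `penn_fit` itself defaults to the whole core so the bare model
   remains available.
2. Per-core fits on sparsely sliced cores (4–6 points in the window)
   chase noise spikes.  The pipeline default (`penn_mode="shared_k"`)
   fits one decay constant across all cores — same lake, same
   diagenetic regime — with per-core (a, b) profiled out by linear
   least squares, reducing the nonlinear search to a 1-D bounded
   minimization over log k.  On the default synthetic world this cuts
   the retention-coefficient recovery error from 3–14% (per-core) to
   well under 1% at seed 42.  `penn_mode="per_core"` restores
   independent fits.

The fitted stable level `a` is an asymptote estimated from the data;
the absolute magnitude of the assumed stable fraction directly scales
corrected TP, so `a`, `b`, `k`, SSE and identifiability flags are
always written to the provenance sidecar.

## Smoothing and comparison statistics

Irregularly spaced records are smoothed with a penalized cubic B-spline
(P-spline: equally spaced basis, default 10 functions, second-order
difference penalty), the Gaussian equivalent of the GAM smooths
standard in this literature.  The smoothing parameter is selected by
GCV (default) or REML on a 55-point log-spaced grid; β is solved via
the augmented least-squares form for numerical stability at extreme
penalties.  The penalty null space contains all linear functions, so
exactly linear data are reproduced exactly; the fitted grid never
extends beyond the data range.  Peak timing is the argmax on the annual
grid, with ties broken to the earliest year and boundary peaks flagged.

Proxy pairing: for each DI-TP sample date, the mean of all SI-TP points
(all cores pooled) within ±5 yr (`half_window_yr`, configurable; 5 yr
matches the decadal smoothing scale of both proxies).  DI-TP is then
regressed on SI-TP by OLS with intercept (statsmodels), reporting
slope/intercept with 95% CIs, r² (identically the squared Pearson
correlation), the two-sided slope p-value, per-point 95% confidence and
prediction intervals, and residual normality by both Shapiro–Wilk and
the normal Q-Q correlation coefficient.  Record-level summaries use the
interval-weighted mean (mean of calendar-aligned decadal bin means),
which is invariant to oversampling within a bin, unlike the plain mean.

## The synthetic world

The generator states a full world so every stage is testable without
external data.  Defaults, chosen once:

| quantity | default | why |
|---|---|---|
| lake | 0.154 km², z̄ 6.3 m, q_s 2.79 m yr⁻¹ | small temperate lowland lake; realistic magnitudes |
| TP trajectory | baseline 30 → peak 150 µg L⁻¹ at 1930 → 90 µg L⁻¹ | logistic rise from ~1850, partial recovery ending by ~1980 |
| true R_P | 0.75 | typical for small lakes with long residence times |
| cores | 4; F = {1, 1.3, 1.6, 2}; slices 0.5–2 cm; MAR 0.045–0.07 g cm⁻² yr⁻¹ | differing focusing and sampling density; eutrophic-lake accumulation rates so 0.5–2 cm slices span 2–7 yr and can resolve a decadal transient |
| bulk density | 0.25 g cm⁻³ | organic-rich lake mud |
| diagenesis | b = 1.6 mg g⁻¹, k = 0.1 yr⁻¹ | 7-yr half-life (decadal-scale return of labile P); amplitude sized so the labile pool is ~35% of calibration-window flux, consistent with published corrected/uncorrected record ratios |
| noise | flux CV 10%, monitoring CV 10%, DI-TP CV 15%, DI-TP bias ×2 | multiplicative lognormal everywhere: concentrations are positive and right-skewed |
| monitoring | monthly, 2003–2018 | short window typical of routine monitoring |

Randomness is a single seed split into named substreams (cores,
monitoring, ditp, dates), so toggling one component never perturbs
another's draws; identical scenarios are bit-identical.

What the generator does *not* emulate — so a green test does not
establish robustness to: age–depth model error (ages are exact),
non-steady-state P dynamics, labile deposition varying with load
(b is constant through time), core-to-core differences in k, compaction
(constant bulk density), or a diatom community response (DI-TP is a
statistical transform of the truth, not an ecological model).

## Numerical choices and degenerate inputs

- Fluxes internally in mg P m⁻² yr⁻¹ (10⁴ × mg cm⁻² yr⁻¹); TP in
  µg L⁻¹ ≡ mg m⁻³; ages in calendar years CE at slice midpoints.
- Retention consistency (`r_p == l_sed/(l_sed+l_out)`) enforced to
  1e-12; anchoring tested to 1e-9 relative.
- `penn_fit` on a constant profile returns b = 0 flagged degenerate
  with a = mean; windows spanning < 3 fitted half-lives are flagged
  weakly identified; negative corrected concentrations floor at 0 with
  a warning.
- Zero/negative MAR or negative concentrations are rejected at ingest,
  not patched: they indicate upstream dating or measurement errors.
- P-spline λ grid 1e-8…1e10; peak ties break to the earliest year.
- `interval_weighted_mean` bins are calendar-aligned (1900–1909, …) for
  reproducibility.

## Known limitations

- The steady-state inversion has no memory: short-lived loading spikes
  are smeared by the lake's residence time in reality but mapped 1:1
  here.
- Focusing beyond a fixed per-core factor (the `hakanson` strategy) is
  a heuristic, not a calibrated morphometric model.
- The diagenesis correction assumes a single exponential labile pool;
  multi-pool or diffusion-controlled profiles will leave residual bias,
  and the fitted-asymptote stable fraction directly scales corrected TP.
- No uncertainty propagation from chronologies or from the (R_P, q_s)
  calibration; reported intervals cover regression uncertainty only.
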