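"""Synthetic lake-sediment systems with known ground truth.

A scenario states a smooth multi-century "true" lake-water TP
trajectory (baseline, logistic rise from the mid-19th century to a
~1930 peak, partial relaxation), a lake with a true retention
coefficient, and a set of cores that record the implied burial flux
under differing focusing factors and sampling densities.  A two-fraction
diagenetic overprint (labile P decaying first-order after burial) and
multiplicative lognormal noise turn the truth into realistic measured
profiles; a short monitoring window and a biased, noisy diatom-style
proxy complete the dataset.  Every stage of the inference pipeline is
thereby testable against known truth without any external data.

Lake constants default to a small temperate lowland lake (area
0.154 km^2, mean depth 6.3 m, q_s 2.79 m/yr, monitoring 2003-2018) so
magnitudes land in realistic ranges; the truth itself is synthetic.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .datamodel import CoreProfile, LakeCatchment, TimeSeries, TPSeries, ValidationError
from .diagenesis import penn_forward

__all__ = [
    "Scenario",
    "SyntheticTruth",
    "make_tp_history",
    "make_cores",
    "make_monitoring",
    "make_ditp",
    "default_ditp_dates",
    "tp_trajectory",
]

# substream codes: one generator per named component so toggling one
# component never perturbs another's draws
_SUBSTREAMS = {"cores": 1, "monitoring": 2, "ditp": 3, "dates": 4, "gauge": 5}


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _SUBSTREAMS[name]])


def _default_lake() -> LakeCatchment:
    return LakeCatchment(
        lake_area_m2=0.154e6,
        mean_depth_m=6.3,
        max_depth_m=9.3,
        catchment_area_m2=4.6e6,
        q_s=2.79,
    )


@dataclass
class Scenario:
    """A fully stated synthetic world; the seed is mandatory."""

    seed: int
    span: tuple[float, float] = (1700.0, 2018.0)
    # true TP trajectory, ug/L
    baseline_ugL: float = 30.0
    peak_ugL: float = 150.0
    rise_start_ce: float = 1850.0
    peak_ce: float = 1930.0
    post_peak_ugL: float = 90.0
    # decline timing: logistic relaxation centered decline_mid_offset_yr
    # after the peak; most of the fall is complete within ~3*decline_tau_yr
    decline_mid_offset_yr: float = 25.0
    decline_tau_yr: float = 12.0
    shape: str = "logistic"
    lake: LakeCatchment = field(default_factory=_default_lake)
    true_r_p: float = 0.75
    # cores
    n_cores: int = 4
    focusing_factors: tuple[float, ...] = (1.0, 1.3, 1.6, 2.0)
    slice_thickness_cm: tuple[float, ...] = (0.5, 1.0, 1.0, 2.0)
    mar_g_cm2_yr: tuple[float, ...] = (0.05, 0.06, 0.045, 0.07)
    bulk_density_g_cm3: float = 0.25
    collection_year: float = 2018.0
    # diagenetic overprint (labile pool at deposition, first-order decay)
    diagenesis_on: bool = True
    penn_labile0_mg_g: float = 1.6
    penn_k_yr: float = 0.1
    # noise (coefficients of variation, multiplicative lognormal)
    flux_cv: float = 0.10
    monitoring_cv: float = 0.10
    ditp_cv: float = 0.15
    ditp_bias: float = 2.0
    monitoring_window: tuple[float, float] = (2003.0, 2018.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("scenario seed is mandatory")
        if not 0 < self.true_r_p < 1:
            raise ValidationError("true_r_p must be in (0, 1)")
        if not (len(self.focusing_factors) == len(self.slice_thickness_cm)
                == len(self.mar_g_cm2_yr) == self.n_cores):
            raise ValidationError("per-core parameter tuples must have length n_cores")
        if any(f <= 0 for f in self.focusing_factors):
            raise ValidationError("focusing factors must be > 0")
        for cv in (self.flux_cv, self.monitoring_cv, self.ditp_cv):
            if cv < 0:
                raise ValidationError("noise CVs must be >= 0")
        if not self.span[0] < self.span[1]:
            raise ValidationError("span start must precede span end")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lake"] = asdict(self.lake)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        if isinstance(d.get("lake"), dict):
            d["lake"] = LakeCatchment(**d["lake"])
        for key in ("span", "focusing_factors", "slice_thickness_cm",
                    "mar_g_cm2_yr", "monitoring_window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def tp_trajectory(scenario: Scenario):
    """Closed-form true TP(t), ug/L, as a vectorized callable.

    Baseline until the rise starts, logistic rise peaking at ``peak_ce``,
    then smooth logistic relaxation toward the post-peak level.  The
    product of two logistics is time-shifted (numerically, on a 0.05-yr
    grid) so its argmax lands exactly on ``peak_ce``; the construction is
    infinitely differentiable and strictly positive.
    """
    s = scenario
    amp = s.peak_ugL - s.baseline_ugL
    if abs(amp) < 1e-12:
        return lambda t: np.full_like(np.asarray(t, dtype=float), s.baseline_ugL)
    tau_r = max((s.peak_ce - s.rise_start_ce) / 10.0, 1e-6)
    m_r = 0.5 * (s.rise_start_ce + s.peak_ce)
    post_frac = (s.post_peak_ugL - s.baseline_ugL) / amp
    m_d = s.peak_ce + s.decline_mid_offset_yr
    tau_d = s.decline_tau_yr

    def raw(t):
        t = np.asarray(t, dtype=float)
        rise = 1.0 / (1.0 + np.exp(-(t - m_r) / tau_r))
        decline = post_frac + (1.0 - post_frac) / (1.0 + np.exp((t - m_d) / tau_d))
        return s.baseline_ugL + amp * rise * decline

    fine = np.arange(s.span[0], s.span[1] + 0.05, 0.05)
    shift = float(fine[int(np.argmax(raw(fine)))]) - s.peak_ce

    def tp(t):
        return raw(np.asarray(t, dtype=float) + shift)

    return tp


def make_tp_history(scenario: Scenario) -> TimeSeries:
    """True TP trajectory evaluated on an annual grid over the span."""
    grid = np.arange(scenario.span[0], scenario.span[1] + 0.5)
    return TimeSeries("true TP (ug/L)", grid, tp_trajectory(scenario)(grid))


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the stated CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


@dataclass
class SyntheticTruth:
    """Everything the generator knows: the answer key for the pipeline."""

    scenario: Scenario
    tp: TimeSeries                      # true TP, annual grid
    l_sed: TimeSeries                   # true lake-wide burial flux, annual grid
    deposited: dict[str, CoreProfile]   # stable (permanently buried) profiles, noiseless
    overprinted: dict[str, CoreProfile]  # after diagenetic overprint, noiseless


def make_cores(truth_tp: TimeSeries, scenario: Scenario) -> tuple[list[CoreProfile], SyntheticTruth]:
    """Forward-model measured core profiles from the true TP trajectory.

    Lake-wide flux from the steady-state mass balance
    L_sed(t) = TP(t) * q_s * r_p / (1 - r_p); per-core flux multiplies by
    that core's focusing factor; concentration divides by MAR.  Slice
    midpoint ages follow from slice thickness, MAR and a constant dry
    bulk density.  The diagenetic overprint (when enabled) adds a labile
    pool decaying first-order with burial age, and multiplicative
    lognormal noise with the stated CV is applied last.
    """
    s = scenario
    q_s = s.lake.q_s
    if q_s is None:
        raise ValidationError("scenario lake must carry q_s")
    tp_fn = tp_trajectory(s)
    ratio = q_s * s.true_r_p / (1.0 - s.true_r_p)
    l_sed_true = TimeSeries("true L_sed (mg/m2/yr)", truth_tp.when, truth_tp.value * ratio)

    rng = _rng(s.seed, "cores")
    cores: list[CoreProfile] = []
    deposited: dict[str, CoreProfile] = {}
    overprinted: dict[str, CoreProfile] = {}
    for i in range(s.n_cores):
        cid = f"C{i + 1}"
        F, thick, mar = s.focusing_factors[i], s.slice_thickness_cm[i], s.mar_g_cm2_yr[i]
        accretion = mar / s.bulk_density_g_cm3          # cm/yr
        dt = thick / accretion                          # yr per slice
        n_slices = int(np.floor((s.collection_year - s.span[0]) / dt))
        j = np.arange(n_slices)
        depth_mid = (j + 0.5) * thick
        age_mid = s.collection_year - (j + 0.5) * dt
        keep = age_mid >= s.span[0]
        depth_mid, age_mid = depth_mid[keep], age_mid[keep]

        stable = tp_fn(age_mid) * ratio * F / (mar * 1.0e4)   # mg/g
        if s.diagenesis_on:
            measured = penn_forward(
                age_mid, stable, s.penn_labile0_mg_g, s.penn_k_yr, s.collection_year
            )
        else:
            measured = stable.copy()
        noisy = measured * _lognormal_factor(rng, s.flux_cv, len(measured))

        def _mk(p):
            return CoreProfile(
                core_id=cid, collection_year=s.collection_year,
                depth_cm=depth_mid.copy(), age_ce=age_mid.copy(),
                p_conc=p, mar=np.full(len(age_mid), mar),
            )

        deposited[cid] = _mk(stable)
        overprinted[cid] = _mk(measured)
        cores.append(_mk(noisy))
    truth = SyntheticTruth(
        scenario=s, tp=truth_tp, l_sed=l_sed_true,
        deposited=deposited, overprinted=overprinted,
    )
    return cores, truth


def make_monitoring(truth_tp: TimeSeries, scenario: Scenario) -> TimeSeries:
    """Monthly monitored TP over the monitoring window, noisy."""
    s = scenario
    w0, w1 = s.monitoring_window
    if w0 < s.span[0] or w1 > s.span[1]:
        raise ValidationError("monitoring window must lie inside the scenario span")
    months = np.arange(w0, w1, 1.0 / 12.0) + 1.0 / 24.0
    if len(months) == 0:
        raise ValidationError("monitoring window is empty")
    tp = tp_trajectory(s)(months)
    noisy = tp * _lognormal_factor(_rng(s.seed, "monitoring"), s.monitoring_cv, len(months))
    return TimeSeries("monitored TP (ug/L)", months, noisy)


def default_ditp_dates(scenario: Scenario, n: int = 60) -> np.ndarray:
    """Irregular proxy sample dates: sorted uniform draws over the span."""
    s = scenario
    lo, hi = s.span[0], min(s.span[1], 2010.0)
    dates = np.sort(_rng(s.seed, "dates").uniform(lo, hi, size=n))
    # enforce strict increase for TimeSeries validity
    dates += np.arange(n) * 1e-9
    return dates


def make_ditp(truth_tp: TimeSeries, sample_dates: np.ndarray, scenario: Scenario) -> TimeSeries:
    """Diatom-style proxy: bias * TP(t) * lognormal noise at irregular dates."""
    s = scenario
    dates = np.asarray(sample_dates, dtype=float)
    if np.any(dates < s.span[0]) or np.any(dates > s.span[1]):
        raise ValidationError("DI-TP sample dates outside the scenario span")
    tp = tp_trajectory(s)(dates)
    vals = s.ditp_bias * tp * _lognormal_factor(_rng(s.seed, "ditp"), s.ditp_cv, len(dates))
    return TimeSeries("DI-TP (ug/L)", dates, vals)
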