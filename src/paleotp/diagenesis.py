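"""Two-fraction sediment-P diagenesis model (stable + decaying labile pool).

Freshly deposited sediment carries a stable P fraction that is buried
permanently and an unstable (labile) fraction that decays first-order
after deposition, diffusing back to the water column on decadal time
scales.  The decaying pool produces a transient surface-ward enrichment
("stationary peak") in recent sediment that is not part of the
depositional signal.  Fitting

    p_conc(burial_age) = a + b * exp(-k * burial_age)

per core and subtracting the fitted transient term removes that peak,
leaving the ultimately-retained concentration used by the SI-TP
inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .datamodel import CoreProfile, ValidationError

__all__ = [
    "PennParams",
    "penn_forward",
    "penn_fit",
    "penn_fit_shared_k",
    "penn_correct",
    "FitError",
]


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge from every start."""


@dataclass
class PennParams:
    """Fitted two-fraction parameters for one core.

    p_stable   -- non-decaying concentration asymptote a, mg/g
    p_unstable0 -- labile concentration at deposition b, mg/g
    k          -- first-order decay constant, 1/yr
    """

    p_stable: float
    p_unstable0: float
    k: float
    sse: float = np.nan
    identifiable: bool = True
    degenerate: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.p_stable < 0 or self.p_unstable0 < 0:
            raise ValidationError("stable and unstable fractions must be >= 0")
        if not self.k > 0:
            raise ValidationError("decay constant k must be > 0")


def penn_forward(
    age_ce: np.ndarray,
    p_stable: np.ndarray | float,
    p_unstable0: np.ndarray | float,
    k: float,
    collection_year: float,
) -> np.ndarray:
    """Concentration measured at core collection, per sample.

    measured = stable + unstable_at_deposition * exp(-k * burial_age).
    Strictly decreasing in burial age wherever the labile input is > 0.
    """
    age_ce = np.asarray(age_ce, dtype=float)
    tau = collection_year - age_ce
    if np.any(tau < 0):
        raise ValidationError("negative burial age: sample younger than collection year")
    if not k > 0:
        raise ValidationError("k must be > 0")
    return np.asarray(p_stable, float) + np.asarray(p_unstable0, float) * np.exp(-k * tau)


#: multistart grid for the decay constant (1/yr); constant+exponential
#: fits are multimodal, so every fit tries each start.
K_STARTS = (0.01, 0.03, 0.1, 0.3)


def _window_mask(profile: CoreProfile, fit_window_depths, max_burial_age_yr) -> np.ndarray:
    m = np.ones(profile.n_samples, dtype=bool)
    if fit_window_depths is not None:
        lo, hi = fit_window_depths
        m &= (profile.depth_cm >= lo) & (profile.depth_cm <= hi)
    if max_burial_age_yr is not None:
        m &= profile.burial_age() <= max_burial_age_yr
    return m


def penn_fit(
    profile: CoreProfile,
    fit_window_depths: tuple[float, float] | None = None,
    max_burial_age_yr: float | None = None,
) -> PennParams:
    """Fit a + b*exp(-k*burial_age) to a core by bounded least squares.

    Multi-start over ``K_STARTS``; bounds a >= 0, b >= 0, k > 0.  The fit
    window (depth range) defaults to the whole core.  Identifiability is
    flagged when fewer than 4 samples, or the window spans less than
    ~3 fitted half-lives of burial age; a near-zero labile amplitude is
    flagged degenerate (no detectable labile pool).
    """
    m = _window_mask(profile, fit_window_depths, max_burial_age_yr)
    tau = profile.burial_age()[m]
    y = profile.p_conc[m]
    flags: list[str] = []
    if len(y) < 4:
        raise FitError(f"core {profile.core_id}: need >=4 samples in fit window, have {len(y)}")

    # degenerate constant profile: no labile pool detectable
    if np.ptp(y) < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        return PennParams(
            p_stable=float(np.mean(y)), p_unstable0=0.0, k=K_STARTS[1],
            sse=float(np.sum((y - np.mean(y)) ** 2)),
            identifiable=False, degenerate=True,
            flags=["constant profile: b=0, k not identified"],
        )

    def model(t, a, b, k):
        return a + b * np.exp(-k * t)

    best = None
    y0, ybar = float(y[np.argmin(tau)]), float(np.mean(y))
    b0 = max(y0 - ybar, 0.1 * max(ybar, 1e-6))
    for k0 in K_STARTS:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, tau, y,
                    p0=[max(ybar, 1e-6), b0, k0],
                    bounds=([0.0, 0.0, 1e-8], [np.inf, np.inf, 10.0]),
                    maxfev=20000,
                )
            sse = float(np.sum((model(tau, *popt) - y) ** 2))
            if best is None or sse < best[1] - 1e-10 * (1 + best[1]):
                best = (popt, sse)
        except RuntimeError:
            continue
    if best is None:
        raise FitError(f"core {profile.core_id}: exponential fit failed from all starts")
    (a, b, k), sse = best

    identifiable = True
    rel_b = b / max(abs(a), 1e-12)
    degenerate = rel_b < 1e-6
    if degenerate:
        flags.append("b ~ 0: no detectable labile pool")
        identifiable = False
    span = float(np.ptp(tau))
    if k > 0 and span < 3 * np.log(2) / k:
        flags.append(
            f"fit window spans {span:.1f} yr < 3 half-lives ({3 * np.log(2) / k:.1f} yr); "
            "k weakly identified"
        )
        identifiable = False
    return PennParams(
        p_stable=float(a), p_unstable0=float(b), k=float(max(k, 1e-8)),
        sse=sse, identifiable=identifiable, degenerate=degenerate, flags=flags,
    )


def penn_fit_shared_k(
    profiles: list[CoreProfile],
    fit_window_depths: tuple[float, float] | None = None,
    max_burial_age_yr: float | None = 30.0,
) -> dict[str, PennParams]:
    """Fit the two-fraction model across cores with one shared decay constant.

    All cores from one lake experience the same diagenetic regime, so k is
    common while the stable level a_i and labile amplitude b_i vary per
    core (different focusing and accumulation).  Given k the per-core
    (a_i, b_i) are linear least squares, so k is found by bounded 1-D
    minimization of the pooled SSE over log k.  Pooling pins k with the
    finely sliced cores and stops sparse cores from fitting noise spikes.

    The default window keeps only samples buried <= 30 yr: the stationary
    peak is a recent-sediment feature, and widening the window admixes the
    depositional (eutrophication) trend into the exponential, biasing the
    labile amplitude.
    """
    from scipy.optimize import minimize_scalar

    data = []
    for p in profiles:
        m = _window_mask(p, fit_window_depths, max_burial_age_yr)
        if np.sum(m) < 3:
            raise FitError(
                f"core {p.core_id}: only {int(np.sum(m))} samples in fit window; need >=3"
            )
        data.append((p.burial_age()[m], p.p_conc[m]))

    def coefs(tau, y, k):
        X = np.column_stack([np.ones_like(tau), np.exp(-k * tau)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        if beta[1] < 0:  # labile amplitude is physically non-negative
            beta = np.array([float(np.mean(y)), 0.0])
        r = y - X @ beta
        return beta, float(r @ r)

    def pooled_sse(logk):
        k = float(np.exp(logk))
        return sum(coefs(tau, y, k)[1] for tau, y in data)

    res = minimize_scalar(
        pooled_sse, bounds=(np.log(1e-3), np.log(0.7)), method="bounded",
        options={"xatol": 1e-10},
    )
    k = float(np.exp(res.x))
    out: dict[str, PennParams] = {}
    for p, (tau, y) in zip(profiles, data):
        (a, b), sse = coefs(tau, y, k)
        flags = []
        degenerate = bool(b < 1e-6 * max(abs(a), 1e-12))
        if degenerate:
            flags.append("b ~ 0: no detectable labile pool")
        span = float(np.ptp(tau))
        identifiable = bool(not degenerate and span >= 3 * np.log(2) / k)
        if not degenerate and span < 3 * np.log(2) / k:
            flags.append("fit window spans < 3 half-lives; k weakly identified")
        out[p.core_id] = PennParams(
            p_stable=float(max(a, 0.0)), p_unstable0=float(b), k=k,
            sse=sse, identifiable=identifiable, degenerate=degenerate, flags=flags,
        )
    return out


def penn_correct(profile: CoreProfile, params: PennParams) -> CoreProfile:
    """Strip the transient labile component from a measured profile.

    corrected = measured - b * exp(-k * burial_age): the concentration the
    sample will hold once the labile pool has fully decayed, i.e. the
    permanently buried P the SI-TP inversion interprets.  Negative results
    are floored at 0 with a warning.
    """
    transient = params.p_unstable0 * np.exp(-params.k * profile.burial_age())
    corrected = profile.p_conc - transient
    if np.any(corrected < 0):
        n = int(np.sum(corrected < 0))
        warnings.warn(
            f"core {profile.core_id}: {n} corrected concentrations were negative; floored at 0"
        )
        corrected = np.maximum(corrected, 0.0)
    return profile.replace_p_conc(corrected)
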