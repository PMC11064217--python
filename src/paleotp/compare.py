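"""Smoothing and validation statistics for proxy-proxy TP comparison.

Irregularly spaced paleolimnological records are smoothed with a
penalized cubic B-spline (P-spline: equally spaced B-spline basis,
second-order difference penalty), the Gaussian-response equivalent of
the GAM smooths standard in this literature.  The smoothing parameter
is chosen by GCV or REML.  The smoothed records supply peak timing; the
raw records supply window-centered means that are paired with the
independent proxy and compared by ordinary least squares with
confidence/prediction intervals and residual-normality diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.interpolate import BSpline

from .datamodel import TimeSeries, TPSeries, ValidationError

__all__ = [
    "SmoothFit",
    "ComparisonResult",
    "fit_gam",
    "find_peak",
    "centered_means",
    "regress_proxies",
    "interval_weighted_mean",
    "five_year_means",
]


@dataclass
class SmoothFit:
    """A fitted penalized-spline smooth of one record."""

    basis: str
    fitted: TimeSeries  # dense annual grid, endpoints = data endpoints
    edf: float
    lam: float
    knots: np.ndarray
    coef: np.ndarray
    degree: int = 3

    def __call__(self, x) -> np.ndarray:
        spl = BSpline(self.knots, self.coef, self.degree, extrapolate=False)
        return spl(np.asarray(x, dtype=float))


def _pspline_design(x: np.ndarray, basis_size: int, degree: int = 3):
    """Equally spaced B-spline basis over the data range (padded knots)."""
    a, b = float(x.min()), float(x.max())
    nseg = basis_size - degree
    h = (b - a) / nseg
    knots = a + h * np.arange(-degree, nseg + degree + 1)
    # guard against x == b falling off the last interval by rounding
    xx = np.clip(x, a, b - 1e-12 * max(1.0, abs(b)))
    B = BSpline.design_matrix(xx, knots, degree).toarray()
    return B, knots


def fit_gam(
    series: TimeSeries,
    basis_size: int = 10,
    selection: str = "GCV",
) -> SmoothFit:
    """Penalized cubic regression spline with automatic smoothing selection.

    The smoothing parameter is chosen by minimizing GCV or the (negative)
    restricted likelihood over a log-spaced grid.  The penalty null space
    contains all linear functions, so exactly linear data are reproduced
    exactly at any smoothing level.  Fitted values are returned on an
    annual grid whose endpoints equal the data endpoints (no
    extrapolation).
    """
    if selection not in ("GCV", "REML"):
        raise ValidationError(f"selection must be GCV or REML, got {selection!r}")
    x, y = series.when, series.value
    n = len(x)
    if n < 4:
        raise ValidationError(f"{series.label}: need >=4 points to fit a smooth, have {n}")
    basis_size = int(min(basis_size, n))
    if basis_size < 4:
        basis_size = 4
    if n < basis_size + 2:
        warnings.warn(
            f"{series.label}: only {n} points for a {basis_size}-function basis; "
            "smooth may be under-determined"
        )
    B, knots = _pspline_design(x, basis_size)
    K = B.shape[1]
    D = np.diff(np.eye(K), n=2, axis=0)
    BtB, Bty = B.T @ B, B.T @ y
    DtD = D.T @ D
    null_dim = 2  # second-difference penalty leaves linear functions unpenalized
    # positive eigenvalues of D'D for the REML log|S|+ term
    ev = np.linalg.eigvalsh(DtD)
    log_det_S_pos = float(np.sum(np.log(ev[ev > 1e-10 * ev.max()])))

    def solve(lam: float):
        # augmented least squares ||y - B beta||^2 + lam ||D beta||^2:
        # numerically stable even for very large lam (exact-fit null space)
        aug_X = np.vstack([B, np.sqrt(lam) * D])
        aug_y = np.concatenate([y, np.zeros(D.shape[0])])
        beta, *_ = np.linalg.lstsq(aug_X, aug_y, rcond=None)
        resid = y - B @ beta
        rss = float(resid @ resid)
        A = BtB + lam * DtD
        edf = float(np.trace(np.linalg.solve(A, BtB)))
        return beta, rss, edf, A

    def criterion(lam: float) -> float:
        beta, rss, edf, A = solve(lam)
        if selection == "GCV":
            denom = max(n - edf, 1e-8)
            return n * rss / denom**2
        pen = float(lam * beta @ DtD @ beta)
        sign, logdet_A = np.linalg.slogdet(A)
        log_det_S = (K - null_dim) * np.log(lam) + log_det_S_pos
        return (n - null_dim) * np.log(max(rss + pen, 1e-300)) + logdet_A - log_det_S

    lams = np.logspace(-8, 10, 55)
    scores = [criterion(l) for l in lams]
    lam = float(lams[int(np.argmin(scores))])
    beta, rss, edf, _ = solve(lam)

    x0, x1 = float(x.min()), float(x.max())
    years = np.arange(np.ceil(x0), np.floor(x1) + 1.0)
    grid = np.unique(np.concatenate([[x0], years, [x1]]))
    fit = SmoothFit(
        basis=f"cubic P-spline, {K} basis functions, 2nd-order difference penalty, {selection}",
        fitted=TimeSeries(f"smooth({series.label})", grid, np.empty(len(grid))),
        edf=max(edf, 1.0),
        lam=lam,
        knots=knots,
        coef=beta,
    )
    vals = fit(np.clip(grid, x0, x1 - 1e-12 * max(1.0, abs(x1))))
    fit.fitted = TimeSeries(f"smooth({series.label})", grid, vals)
    return fit


def find_peak(fit: SmoothFit) -> dict:
    """Argmax of the fitted smooth on its annual grid.

    Ties break to the earliest year (and are reported); a peak at either
    grid endpoint is flagged as a boundary peak.
    """
    g, v = fit.fitted.when, fit.fitted.value
    vmax = np.max(v)
    at_max = np.flatnonzero(np.isclose(v, vmax, rtol=0, atol=1e-12 * max(1.0, abs(vmax))))
    i = int(at_max[0])
    return {
        "peak_year": float(g[i]),
        "peak_value": float(v[i]),
        "tie": len(at_max) > 1,
        "boundary": i == 0 or int(at_max[-1]) == len(g) - 1,
    }


def centered_means(
    sitp: TPSeries, ditp: TimeSeries, half_window_yr: float = 5.0
) -> pd.DataFrame:
    """Pair each DI-TP sample with the mean SI-TP in a centered window.

    All SI-TP points (every core pooled when per-core records exist) within
    +/- half_window_yr of a DI-TP date are averaged; DI-TP dates with no
    SI-TP neighbours are dropped and counted in ``attrs['n_dropped']``.
    """
    if not half_window_yr > 0:
        raise ValidationError("half_window_yr must be > 0")
    if sitp.per_core:
        t = np.concatenate([ts.when for ts in sitp.per_core.values()])
        v = np.concatenate([ts.value for ts in sitp.per_core.values()])
    else:
        t, v = sitp.aggregate.when, sitp.aggregate.value
    ok = np.isfinite(v)
    t, v = t[ok], v[ok]
    rows = []
    dropped = 0
    for when, val in zip(ditp.when, ditp.value):
        m = np.abs(t - when) <= half_window_yr
        if not np.any(m):
            dropped += 1
            continue
        rows.append((when, val, float(np.mean(v[m])), int(np.sum(m))))
    if not rows:
        raise ValidationError("no DI-TP dates could be paired with SI-TP points")
    out = pd.DataFrame(rows, columns=["ditp_date", "ditp_value", "sitp_mean", "n_sitp"])
    out.attrs["n_dropped"] = dropped
    return out


@dataclass
class ComparisonResult:
    """OLS comparison of two TP proxies (y = DI-TP regressed on x = SI-TP)."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    prediction_band: pd.DataFrame  # x, fit, pi_lo, pi_hi, ci_lo, ci_hi
    residuals: np.ndarray
    qq_stats: dict = field(default_factory=dict)
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "p_value": self.p_value,
            "ci95_slope": list(self.ci95_slope),
            "ci95_intercept": list(self.ci95_intercept),
            "qq_stats": self.qq_stats,
            "n": self.n,
        }


def regress_proxies(pairs: pd.DataFrame) -> ComparisonResult:
    """OLS of DI-TP on SI-TP with intervals and residual diagnostics.

    Expects the table from :func:`centered_means` (or any frame with
    ``sitp_mean``/``ditp_value`` columns).  Reports slope/intercept with
    95% CIs, r^2, the two-sided slope p-value, per-point 95% confidence
    and prediction intervals, and residual normality (Shapiro-Wilk plus
    the normal Q-Q correlation coefficient).
    """
    x = pairs["sitp_mean"].to_numpy(float)
    y = pairs["ditp_value"].to_numpy(float)
    if len(x) < 3:
        raise ValidationError(f"need >=3 pairs for regression, have {len(x)}")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in SI-TP means; regression undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    pred = fit.get_prediction(X).summary_frame(alpha=0.05)
    band = pd.DataFrame(
        {
            "x": x,
            "fit": pred["mean"].to_numpy(),
            "ci_lo": pred["mean_ci_lower"].to_numpy(),
            "ci_hi": pred["mean_ci_upper"].to_numpy(),
            "pi_lo": pred["obs_ci_lower"].to_numpy(),
            "pi_hi": pred["obs_ci_upper"].to_numpy(),
        }
    )
    resid = np.asarray(fit.resid)
    if len(resid) >= 3:
        sw_stat, sw_p = scipy.stats.shapiro(resid)
        (osm, osr), (_, _, qq_r) = scipy.stats.probplot(resid, dist="norm")
        qq = {"shapiro_stat": float(sw_stat), "shapiro_p": float(sw_p),
              "qq_corr": float(qq_r)}
    else:  # pragma: no cover
        qq = {}
    return ComparisonResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        ci95_slope=(float(ci[1, 0]), float(ci[1, 1])),
        ci95_intercept=(float(ci[0, 0]), float(ci[0, 1])),
        prediction_band=band,
        residuals=resid,
        qq_stats=qq,
        n=len(x),
    )


def interval_weighted_mean(series: TimeSeries, interval_yr: float = 10.0) -> float:
    """Mean of calendar-aligned bin means (default decadal).

    Corrects for variable sampling density: oversampling within a bin
    cannot move the result, unlike a plain mean.
    """
    if len(series) == 0:
        raise ValidationError("interval_weighted_mean of an empty series")
    bins = np.floor(series.when / interval_yr)
    df = pd.DataFrame({"bin": bins, "v": series.value})
    return float(df.groupby("bin")["v"].mean().mean())


def five_year_means(monitored: TimeSeries) -> TimeSeries:
    """Non-overlapping calendar-aligned 5-year bin means at bin centers."""
    if len(monitored) == 0:
        raise ValidationError("five_year_means of an empty series")
    start = np.floor(monitored.when / 5.0) * 5.0
    df = pd.DataFrame({"start": start, "v": monitored.value})
    g = df.groupby("start")["v"].mean()
    return TimeSeries(
        f"5yr-mean({monitored.label})",
        g.index.to_numpy(float) + 2.5,
        g.to_numpy(float),
    )
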