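"""Domain types and unit conventions for the sediment-P / lake-TP pipeline.

Units are fixed at the package boundary and never vary internally:

* sediment P concentration ``p_conc`` — mg P per g dry sediment
* dry-mass accumulation rate ``mar`` — g dry sediment cm^-2 yr^-1
* areal P fluxes (L_sed, L_out) — mg P m^-2 yr^-1
  (1 mg cm^-2 yr^-1 = 1e4 mg m^-2 yr^-1)
* lake-water TP — ug L^-1, numerically identical to mg m^-3
* areal water loading q_s — m yr^-1
* ages and timestamps — calendar years CE, fractional allowed;
  a sample's age refers to the slice midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoreProfile",
    "LakeCatchment",
    "TimeSeries",
    "TPSeries",
    "ValidationError",
    "MG_CM2_TO_MG_M2",
]

#: areal flux conversion: mg cm^-2 yr^-1 -> mg m^-2 yr^-1
MG_CM2_TO_MG_M2 = 1.0e4


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        bad = np.flatnonzero(~np.isfinite(arr)).tolist()
        raise ValidationError(f"{name} contains non-finite values at rows {bad}")
    return arr


@dataclass
class CoreProfile:
    """One dated sediment core.

    Parallel per-sample arrays ordered by increasing depth below the
    sediment surface.  Age decreases strictly with depth (younger mud on
    top) and never exceeds the collection year.
    """

    core_id: str
    collection_year: float
    depth_cm: np.ndarray
    age_ce: np.ndarray
    p_conc: np.ndarray
    mar: np.ndarray

    def __post_init__(self) -> None:
        self.depth_cm = _as_1d(self.depth_cm, "depth_cm")
        self.age_ce = _as_1d(self.age_ce, "age_ce")
        self.p_conc = _as_1d(self.p_conc, "p_conc")
        self.mar = _as_1d(self.mar, "mar")
        n = len(self.depth_cm)
        if not (len(self.age_ce) == len(self.p_conc) == len(self.mar) == n):
            raise ValidationError("sample arrays have unequal lengths")
        if n == 0:
            raise ValidationError("core profile has no samples")
        d = np.diff(self.depth_cm)
        if np.any(d <= 0):
            rows = (np.flatnonzero(d <= 0) + 1).tolist()
            raise ValidationError(
                f"core {self.core_id}: depth not strictly increasing at rows {rows}"
            )
        a = np.diff(self.age_ce)
        if np.any(a >= 0):
            rows = (np.flatnonzero(a >= 0) + 1).tolist()
            raise ValidationError(
                f"core {self.core_id}: age must strictly decrease with depth; "
                f"violated at rows {rows}"
            )
        if np.any(self.age_ce > self.collection_year):
            rows = np.flatnonzero(self.age_ce > self.collection_year).tolist()
            raise ValidationError(
                f"core {self.core_id}: ages exceed collection year at rows {rows}"
            )
        if np.any(self.p_conc < 0):
            rows = np.flatnonzero(self.p_conc < 0).tolist()
            raise ValidationError(f"core {self.core_id}: negative p_conc at rows {rows}")
        if np.any(self.mar <= 0):
            rows = np.flatnonzero(self.mar <= 0).tolist()
            raise ValidationError(f"core {self.core_id}: non-positive mar at rows {rows}")

    @property
    def n_samples(self) -> int:
        return len(self.depth_cm)

    def burial_age(self) -> np.ndarray:
        """Years since deposition at core collection, per sample."""
        return self.collection_year - self.age_ce

    def replace_p_conc(self, p_conc: np.ndarray) -> "CoreProfile":
        return CoreProfile(
            core_id=self.core_id,
            collection_year=self.collection_year,
            depth_cm=self.depth_cm.copy(),
            age_ce=self.age_ce.copy(),
            p_conc=np.asarray(p_conc, dtype=float),
            mar=self.mar.copy(),
        )


@dataclass
class LakeCatchment:
    """Lake and catchment constants.

    ``q_s`` (areal water loading, annual outflow volume / lake area,
    m yr^-1) may be supplied directly or estimated from discharge records.
    """

    lake_area_m2: float
    mean_depth_m: float
    max_depth_m: float
    catchment_area_m2: float
    q_s: float | None = None

    def __post_init__(self) -> None:
        for name in ("lake_area_m2", "mean_depth_m", "max_depth_m", "catchment_area_m2"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.mean_depth_m > self.max_depth_m:
            raise ValidationError("mean_depth_m exceeds max_depth_m")
        if self.q_s is not None and not self.q_s > 0:
            raise ValidationError("q_s must be strictly positive when given")


@dataclass
class TimeSeries:
    """A dated record: strictly increasing timestamps, finite values.

    Units are declared by the label (TP in ug/L = mg/m3; discharge in
    m3/yr).
    """

    label: str
    when: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.when = _as_1d(self.when, "when")
        self.value = _as_1d(self.value, "value")
        if len(self.when) != len(self.value):
            raise ValidationError("when and value have unequal lengths")
        if np.any(np.diff(self.when) <= 0):
            raise ValidationError(f"{self.label}: timestamps not strictly increasing")

    def __len__(self) -> int:
        return len(self.when)

    def window(self, start: float, end: float) -> "TimeSeries":
        """Sub-series with start <= when <= end (may be empty)."""
        m = (self.when >= start) & (self.when <= end)
        ts = TimeSeries.__new__(TimeSeries)
        ts.label, ts.when, ts.value = self.label, self.when[m], self.value[m]
        return ts


VALID_TP_METHODS = ("SI-TP-raw", "SI-TP-penn", "DI-TP", "monitored", "true")


@dataclass
class TPSeries:
    """A lake-water TP record (ug/L) tagged with its inference method.

    ``aggregate`` is the headline record; ``per_core`` optionally carries
    the individual-core records behind a multi-core mean.
    """

    method: str
    aggregate: TimeSeries
    per_core: dict[str, TimeSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in VALID_TP_METHODS:
            raise ValidationError(
                f"method {self.method!r} not in {VALID_TP_METHODS}"
            )
        for ts in (self.aggregate, *self.per_core.values()):
            vals = ts.value[np.isfinite(ts.value)]
            if np.any(vals < 0):
                raise ValidationError(f"{ts.label}: negative TP values")
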