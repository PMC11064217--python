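"""Orchestration: simulate -> infer -> compare.

``infer_tp_records`` is the library-level composition of the SI-TP
stages (flux, focusing, optional diagenesis correction, aggregation,
anchoring, inversion) on in-memory objects; ``run_infer``/``run_compare``
/``run_simulate`` wrap it with config files, CSV/JSON outputs and
provenance sidecars.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import (
    centered_means,
    find_peak,
    fit_gam,
    five_year_means,
    interval_weighted_mean,
    regress_proxies,
)
from .datamodel import CoreProfile, LakeCatchment, TimeSeries, TPSeries, ValidationError
from .diagenesis import penn_correct, penn_fit, penn_fit_shared_k
from .engine import (
    SITPConfig,
    aggregate_cores,
    calibrate_rp,
    compute_lsed,
    compute_lout,
    focusing_correct,
    infer_tp,
)
from .io import read_core_csv, read_series_csv, write_core_csv, write_series_csv
from .synthetic import (
    Scenario,
    default_ditp_dates,
    make_cores,
    make_ditp,
    make_monitoring,
    make_tp_history,
)

__all__ = [
    "PipelineConfig",
    "infer_tp_records",
    "run_infer",
    "run_compare",
    "run_simulate",
]

log = logging.getLogger("paleotp")


@dataclass
class PipelineConfig:
    """File-level configuration for ``run_infer``/``run_compare``."""

    cores: list[dict]                  # {path, core_id, collection_year, [focusing_factor]}
    monitoring_path: str
    lake: LakeCatchment
    sitp: SITPConfig = field(default_factory=SITPConfig)
    ditp_path: str | None = None
    diagenesis: bool = True
    penn_mode: str = "shared_k"          # shared_k | per_core
    penn_max_burial_age_yr: float | None = 30.0
    penn_fit_window_depths: tuple[float, float] | None = None
    half_window_yr: float = 5.0
    gam_basis_size: int = 10
    gam_selection: str = "GCV"
    interval_yr: float = 10.0
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        lake = LakeCatchment(**d.pop("lake"))
        sitp = SITPConfig(**d.pop("sitp", {}))
        if "penn_fit_window_depths" in d and d["penn_fit_window_depths"] is not None:
            d["penn_fit_window_depths"] = tuple(d["penn_fit_window_depths"])
        return cls(lake=lake, sitp=sitp, **d)


def _branch(
    fluxes: list, monitored_tp: TimeSeries, config: SITPConfig, q_s: float, method: str
) -> tuple[TPSeries, dict]:
    """Aggregate fluxes, anchor R_P to the monitoring window, invert."""
    window = (config.calib_start_ce, config.calib_end_ce)
    agg, meta = aggregate_cores(fluxes, config.aggregation_grid_step_yr)
    l_out = compute_lout(monitored_tp, q_s, window)
    retention = calibrate_rp(agg, l_out, window)
    tp = infer_tp(agg, retention, q_s, method=method)
    scale = (1.0 - retention.r_p) / (retention.r_p * q_s)
    per_core = {}
    for f in fluxes:
        # per-core TP on the aggregate grid (no extrapolation past the core)
        m = (agg.age_ce >= f.age_ce[0]) & (agg.age_ce <= f.age_ce[-1])
        per_core[f.core_id] = TimeSeries(
            f"{method} ({f.core_id})",
            agg.age_ce[m],
            np.interp(agg.age_ce[m], f.age_ce, f.l_sed) * scale,
        )
    tp = TPSeries(method=method, aggregate=tp.aggregate, per_core=per_core)
    prov = {
        "method": method,
        "r_p": retention.r_p,
        "l_sed_cal": retention.l_sed_cal,
        "l_out": l_out,
        "q_s": q_s,
        "window": list(window),
        "focusing": config.focusing,
        "full_overlap": meta["full_overlap"],
        "version": __version__,
    }
    log.info("%s: r_p=%.6f q_s=%.4f l_out=%.3f l_sed_cal=%.3f",
             method, retention.r_p, q_s, l_out, retention.l_sed_cal)
    return tp, prov


def infer_tp_records(
    cores: list[CoreProfile],
    monitored_tp: TimeSeries,
    lake: LakeCatchment,
    config: SITPConfig,
    diagenesis: bool = True,
    penn_mode: str = "shared_k",
    penn_max_burial_age_yr: float | None = 30.0,
    penn_fit_window_depths: tuple[float, float] | None = None,
) -> dict:
    """Run both SI-TP branches (raw and Penn-corrected) on loaded cores.

    Returns a dict with ``raw``/``penn`` TPSeries, per-branch provenance
    (anchored r_p, q_s, l_out), and per-core fitted diagenesis parameters.
    Each branch is anchored independently: stripping the labile overprint
    lowers the calibration-window flux, hence the corrected branch's r_p.

    ``penn_mode='shared_k'`` (default) fits one decay constant across all
    cores with per-core amplitudes, restricted to recently buried samples;
    ``'per_core'`` fits each core independently over the stated window.
    """
    q_s = config.q_s if config.q_s is not None else lake.q_s
    if q_s is None:
        raise ValidationError("q_s must be supplied in SITPConfig or LakeCatchment")
    factors = config.focusing_factors or {}
    fluxes = [
        focusing_correct(compute_lsed(c), lake, config.focusing, factors.get(c.core_id))
        for c in cores
    ]
    raw_tp, raw_prov = _branch(fluxes, monitored_tp, config, q_s, "SI-TP-raw")
    out = {"raw": raw_tp, "raw_provenance": raw_prov}
    if diagenesis:
        if penn_mode == "shared_k":
            penn_params = penn_fit_shared_k(
                cores, penn_fit_window_depths, penn_max_burial_age_yr
            )
        elif penn_mode == "per_core":
            penn_params = {
                c.core_id: penn_fit(c, penn_fit_window_depths, penn_max_burial_age_yr)
                for c in cores
            }
        else:
            raise ValidationError(f"unknown penn_mode {penn_mode!r}")
        corrected = []
        for c in cores:
            params = penn_params[c.core_id]
            corrected.append(penn_correct(c, params))
            log.info("penn %s: a=%.4f b=%.4f k=%.5f sse=%.4g flags=%s",
                     c.core_id, params.p_stable, params.p_unstable0, params.k,
                     params.sse, params.flags)
        fluxes_c = [
            focusing_correct(compute_lsed(c), lake, config.focusing, factors.get(c.core_id))
            for c in corrected
        ]
        penn_tp, penn_prov = _branch(fluxes_c, monitored_tp, config, q_s, "SI-TP-penn")
        penn_prov["penn_params"] = {
            cid: {"a": p.p_stable, "b": p.p_unstable0, "k": p.k, "sse": p.sse,
                  "identifiable": p.identifiable, "degenerate": p.degenerate,
                  "flags": p.flags}
            for cid, p in penn_params.items()
        }
        out.update(penn=penn_tp, penn_provenance=penn_prov, penn_params=penn_params,
                   corrected_cores=corrected)
    return out


def run_infer(config: PipelineConfig) -> dict:
    """File-level inference: read inputs, run both branches, write outputs."""
    cores = []
    factors = dict(config.sitp.focusing_factors or {})
    for spec in config.cores:
        p = Path(spec["path"])
        if not p.exists():
            raise FileNotFoundError(f"core file not found: {p}")
        cores.append(read_core_csv(p, spec["core_id"], spec["collection_year"]))
        if "focusing_factor" in spec:
            factors[spec["core_id"]] = float(spec["focusing_factor"])
    config.sitp.focusing_factors = factors or None
    mon_path = Path(config.monitoring_path)
    if not mon_path.exists():
        raise FileNotFoundError(f"monitoring file not found: {mon_path}")
    monitored = read_series_csv(mon_path, "monitored TP")
    result = infer_tp_records(
        cores, monitored, config.lake, config.sitp,
        diagenesis=config.diagenesis,
        penn_mode=config.penn_mode,
        penn_max_burial_age_yr=config.penn_max_burial_age_yr,
        penn_fit_window_depths=config.penn_fit_window_depths,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_series_csv(result["raw"], out / "sitp_raw.csv")
    (out / "sitp_raw.json").write_text(json.dumps(result["raw_provenance"], indent=2))
    if config.diagenesis:
        write_series_csv(result["penn"], out / "sitp_penn.csv")
        (out / "sitp_penn.json").write_text(json.dumps(result["penn_provenance"], indent=2))
        for c in result["corrected_cores"]:
            write_core_csv(c, out / f"core_{c.core_id}_penn_corrected.csv")
    return result


def compare_records(
    sitp: TPSeries,
    ditp: TimeSeries,
    half_window_yr: float = 5.0,
    basis_size: int = 10,
    selection: str = "GCV",
    interval_yr: float = 10.0,
    monitored: TimeSeries | None = None,
) -> dict:
    """Smooth both records, pair them, and compute the validation statistics."""
    agg = sitp.aggregate
    ok = np.isfinite(agg.value)
    sitp_ts = TimeSeries(agg.label, agg.when[ok], agg.value[ok])
    gam_sitp = fit_gam(sitp_ts, basis_size, selection)
    gam_ditp = fit_gam(ditp, basis_size, selection)
    pairs = centered_means(sitp, ditp, half_window_yr)
    comparison = regress_proxies(pairs)
    report = {
        "n_pairs": int(len(pairs)),
        "n_ditp_dropped": int(pairs.attrs["n_dropped"]),
        "regression": comparison.to_dict(),
        "peaks": {
            "sitp": find_peak(gam_sitp),
            "ditp": find_peak(gam_ditp),
        },
        "interval_weighted_mean": {
            "sitp": interval_weighted_mean(sitp_ts, interval_yr),
            "ditp": interval_weighted_mean(ditp, interval_yr),
            "interval_yr": interval_yr,
        },
        "gam": {
            "sitp": {"edf": gam_sitp.edf, "lam": gam_sitp.lam, "basis": gam_sitp.basis},
            "ditp": {"edf": gam_ditp.edf, "lam": gam_ditp.lam, "basis": gam_ditp.basis},
        },
    }
    if monitored is not None and len(monitored) > 0:
        fy = five_year_means(monitored)
        report["monitored_5yr_means"] = {
            "when": fy.when.tolist(), "value": fy.value.tolist()
        }
    return {
        "report": report, "pairs": pairs, "comparison": comparison,
        "gam_sitp": gam_sitp, "gam_ditp": gam_ditp,
    }


def run_compare(config: PipelineConfig, sitp_path, ditp_path) -> dict:
    """File-level comparison: read the two records, write report CSV + JSON."""
    for p in (sitp_path, ditp_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    sitp = read_series_csv(sitp_path, "SI-TP", method="SI-TP-raw")
    ditp = read_series_csv(ditp_path, "DI-TP")
    monitored = None
    if config.monitoring_path and Path(config.monitoring_path).exists():
        monitored = read_series_csv(config.monitoring_path, "monitored TP")
    res = compare_records(
        sitp, ditp,
        half_window_yr=config.half_window_yr,
        basis_size=config.gam_basis_size,
        selection=config.gam_selection,
        interval_yr=config.interval_yr,
        monitored=monitored,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res["pairs"].to_csv(out / "proxy_pairs.csv", index=False, float_format="%.12g")
    res["comparison"].prediction_band.to_csv(
        out / "prediction_band.csv", index=False, float_format="%.12g"
    )
    (out / "comparison_report.json").write_text(json.dumps(res["report"], indent=2))
    return res


def run_simulate(scenario: Scenario, out_dir) -> dict[str, Path]:
    """Write a full synthetic dataset (cores, monitoring, DI-TP, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_tp = make_tp_history(scenario)
    cores, truth = make_cores(truth_tp, scenario)
    monitoring = make_monitoring(truth_tp, scenario)
    ditp = make_ditp(truth_tp, default_ditp_dates(scenario), scenario)

    paths: dict[str, Path] = {}
    for c in cores:
        paths[f"core_{c.core_id}"] = p = out / f"core_{c.core_id}.csv"
        write_core_csv(c, p)
    paths["monitoring"] = out / "monitoring_tp.csv"
    write_series_csv(monitoring, paths["monitoring"])
    paths["ditp"] = out / "ditp.csv"
    write_series_csv(ditp, paths["ditp"])
    paths["truth_tp"] = out / "truth_tp.csv"
    write_series_csv(truth_tp, paths["truth_tp"])
    paths["truth_lsed"] = out / "truth_lsed.csv"
    write_series_csv(truth.l_sed, paths["truth_lsed"])
    paths["scenario"] = out / "scenario.yaml"
    with open(paths["scenario"], "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)
    # a ready-to-run inference config pointing at the files just written
    cfg = {
        "cores": [
            {"path": str(out / f"core_{c.core_id}.csv"), "core_id": c.core_id,
             "collection_year": c.collection_year,
             "focusing_factor": scenario.focusing_factors[i]}
            for i, c in enumerate(cores)
        ],
        "monitoring_path": str(paths["monitoring"]),
        "ditp_path": str(paths["ditp"]),
        "lake": {
            "lake_area_m2": scenario.lake.lake_area_m2,
            "mean_depth_m": scenario.lake.mean_depth_m,
            "max_depth_m": scenario.lake.max_depth_m,
            "catchment_area_m2": scenario.lake.catchment_area_m2,
            "q_s": scenario.lake.q_s,
        },
        "sitp": {
            "calib_start_ce": scenario.monitoring_window[0],
            "calib_end_ce": scenario.monitoring_window[1],
            "q_s": scenario.lake.q_s,
            "focusing": "fixed_factor",
        },
        "diagenesis": scenario.diagenesis_on,
        "out_dir": str(out),
    }
    paths["config"] = out / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return paths
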