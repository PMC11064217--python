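"""Mass-balance engine: flux, focusing, aggregation, q_s, anchoring, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleotp.datamodel import CoreProfile, LakeCatchment, TimeSeries, ValidationError
from paleotp.engine import (
    CalibrationError,
    FluxSeries,
    Retention,
    aggregate_cores,
    calibrate_rp,
    compute_lout,
    compute_lsed,
    estimate_qs,
    focusing_correct,
    hakanson_factor,
    infer_tp,
)


def box_model_tp(l_sed: float, r_p: float, q_s: float, z_mean: float = 6.3) -> float:
    """Independent oracle: converged discrete-time lake P box model.

    dTP/dt = (L_in - L_sed - q_s*TP) / z_mean with L_in = l_sed / r_p and
    burial fixed at l_sed; iterated to steady state.
    """
    l_in = l_sed / r_p
    tp = 0.0
    dt = 0.1 * z_mean / q_s  # stable explicit step
    for _ in range(200000):
        new = tp + dt * (l_in - l_sed - q_s * tp) / z_mean
        if abs(new - tp) < 1e-12 * max(1.0, abs(new)):
            return new
        tp = new
    raise AssertionError("box model failed to converge")


class TestComputeLsed:
    def test_unit_conversion(self, lake):
        """1 mg/g * 0.01 g/cm2/yr = 0.01 mg/cm2/yr = 100 mg/m2/yr."""
        core = CoreProfile(
            core_id="U", collection_year=2018.0,
            depth_cm=np.array([0.5, 1.5]), age_ce=np.array([2010.0, 2000.0]),
            p_conc=np.array([1.0, 0.0]), mar=np.array([0.01, 0.01]),
        )
        flux = compute_lsed(core)
        # output ordered by increasing age
        np.testing.assert_allclose(flux.age_ce, [2000.0, 2010.0])
        np.testing.assert_allclose(flux.l_sed, [0.0, 100.0])

    def test_linearity_in_mar(self, simple_core):
        doubled = CoreProfile(
            core_id=simple_core.core_id, collection_year=simple_core.collection_year,
            depth_cm=simple_core.depth_cm, age_ce=simple_core.age_ce,
            p_conc=simple_core.p_conc, mar=2 * simple_core.mar,
        )
        np.testing.assert_allclose(
            compute_lsed(doubled).l_sed, 2 * compute_lsed(simple_core).l_sed
        )


class TestFocusing:
    def test_none_is_identity(self, simple_core, lake):
        f = compute_lsed(simple_core)
        out = focusing_correct(f, lake, "none")
        np.testing.assert_array_equal(out.l_sed, f.l_sed)

    def test_fixed_factor_halves(self, simple_core, lake):
        f = compute_lsed(simple_core)
        out = focusing_correct(f, lake, "fixed_factor", factor=2.0)
        np.testing.assert_allclose(out.l_sed, f.l_sed / 2)

    def test_hakanson_factor_at_least_one(self, simple_core, lake):
        assert hakanson_factor(lake) >= 1.0
        f = compute_lsed(simple_core)
        out = focusing_correct(f, lake, "hakanson")
        assert np.all(out.l_sed <= f.l_sed + 1e-12)

    def test_bad_strategy_and_factor_rejected(self, simple_core, lake):
        f = compute_lsed(simple_core)
        with pytest.raises(ValidationError):
            focusing_correct(f, lake, "sideways")
        with pytest.raises(ValidationError):
            focusing_correct(f, lake, "fixed_factor", factor=-1.0)


class TestAggregation:
    def test_single_core_identity(self):
        f = FluxSeries("a", np.array([1900.0, 1910.0]), np.array([100.0, 200.0]))
        agg, meta = aggregate_cores([f])
        np.testing.assert_allclose(agg.l_sed, np.interp(agg.age_ce, f.age_ce, f.l_sed))
        assert meta["full_overlap"]

    def test_two_identical_cores_zero_spread(self):
        t = np.array([1900.0, 1905.0, 1910.0])
        v = np.array([100.0, 150.0, 120.0])
        agg, meta = aggregate_cores([FluxSeries("a", t, v), FluxSeries("b", t, v)])
        np.testing.assert_allclose(meta["hi"] - meta["lo"], 0.0, atol=1e-12)

    def test_constant_offset_halved_on_overlap(self):
        """Two cores offset by c: aggregate offset by c/2 where both cover."""
        t = np.array([1900.0, 1902.0, 1904.0, 1906.0, 1908.0])
        v = np.array([100.0, 110.0, 120.0, 130.0, 140.0])
        agg, _ = aggregate_cores([FluxSeries("a", t, v), FluxSeries("b", t, v + 10.0)])
        np.testing.assert_allclose(
            agg.l_sed, np.interp(agg.age_ce, t, v) + 5.0
        )

    def test_partial_overlap_flagged_and_bounded(self):
        a = FluxSeries("a", np.array([1900.0, 1950.0]), np.array([100.0, 100.0]))
        b = FluxSeries("b", np.array([1940.0, 1990.0]), np.array([200.0, 200.0]))
        agg, meta = aggregate_cores([a, b])
        assert not meta["full_overlap"]
        assert np.all(agg.l_sed >= meta["lo"] - 1e-12)
        assert np.all(agg.l_sed <= meta["hi"] + 1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_cores([])


class TestEstimateQs:
    def test_identity_regression(self, lake):
        t = np.arange(2016.0, 2019.0)
        gauge_t = np.arange(2003.0, 2019.0)
        vol = 4.0e5 + 1.0e4 * np.sin(gauge_t)
        gauge = TimeSeries("gauge", gauge_t, vol)
        outflow = TimeSeries("outflow", t, np.interp(t, gauge_t, vol))
        q_s, info = estimate_qs(outflow, gauge, lake, gauge_t)
        assert info["slope"] == pytest.approx(1.0, abs=1e-9)
        assert info["intercept"] == pytest.approx(0.0, abs=1e-3)
        assert q_s == pytest.approx(float(np.mean(vol)) / lake.lake_area_m2, rel=1e-9)

    def test_doubled_outflow_doubles_predictions(self, lake):
        gauge_t = np.arange(2000.0, 2019.0)
        vol = 4.0e5 + 1.0e4 * np.cos(gauge_t)
        gauge = TimeSeries("gauge", gauge_t, vol)
        t = np.arange(2016.0, 2019.0)
        outflow = TimeSeries("outflow", t, 2 * np.interp(t, gauge_t, vol))
        _, info = estimate_qs(outflow, gauge, lake, gauge_t)
        np.testing.assert_allclose(info["predicted_volume_m3_yr"], 2 * vol, rtol=1e-9)

    def test_insufficient_overlap_rejected(self, lake):
        a = TimeSeries("a", [2017.0, 2018.0], [1.0, 2.0])
        b = TimeSeries("b", [2017.0, 2018.0], [1.0, 2.0])
        with pytest.raises(ValidationError, match="overlap"):
            estimate_qs(a, b, lake, np.array([2018.0]))

    def test_slope_ci_coverage(self, lake):
        """OLS slope recovery: |slope_hat - slope| within 2 SE in most replicates."""
        rng = np.random.default_rng(7)
        gauge_t = np.arange(2000.0, 2019.0)
        base = 4.0e5 + 5.0e4 * rng.standard_normal(len(gauge_t))
        hits = 0
        n_rep = 600
        for _ in range(n_rep):
            noise = 2.0e4 * rng.standard_normal(len(gauge_t))
            out_v = 1.5 * base + 1.0e4 + noise
            gauge = TimeSeries("g", gauge_t, base)
            outflow = TimeSeries("o", gauge_t, out_v)
            _, info = estimate_qs(outflow, gauge, lake, gauge_t)
            x, y = base, out_v
            n = len(x)
            resid = y - (info["slope"] * x + info["intercept"])
            se = np.sqrt(np.sum(resid**2) / (n - 2) / np.sum((x - x.mean()) ** 2))
            from scipy.stats import t as tdist

            half = tdist.ppf(0.975, n - 2) * se
            hits += abs(info["slope"] - 1.5) <= half
        assert hits / n_rep >= 0.93


class TestRetentionAndInversion:
    def test_lout_hand_arithmetic(self, constant_tp):
        assert compute_lout(constant_tp, 2.79, (2003, 2018)) == pytest.approx(279.0)

    def test_lout_mean_symmetry(self):
        ts = TimeSeries("tp", [2004.0, 2010.0], [80.0, 120.0])
        assert compute_lout(ts, 2.79, (2003, 2018)) == pytest.approx(279.0)

    def test_lout_empty_window_names_window(self, constant_tp):
        with pytest.raises(ValidationError, match="1990"):
            compute_lout(constant_tp, 2.79, (1980, 1990))

    @pytest.mark.parametrize(
        "l_sed,l_out,expected",
        [(100.0, 100.0, 0.5), (100.0, 0.0, 1.0), (300.0, 100.0, 0.75)],
    )
    def test_calibrate_rp_values(self, l_sed, l_out, expected):
        f = FluxSeries("x", np.array([2005.0, 2010.0]), np.array([l_sed, l_sed]))
        r = calibrate_rp(f, l_out, (2003, 2018))
        assert r.r_p == pytest.approx(expected, rel=1e-12)

    def test_zero_flux_calibration_fails(self):
        f = FluxSeries("x", np.array([2005.0, 2010.0]), np.array([0.0, 0.0]))
        with pytest.raises(CalibrationError):
            calibrate_rp(f, 100.0, (2003, 2018))

    def test_retention_consistency_enforced(self):
        with pytest.raises(ValidationError):
            Retention(r_p=0.9, l_sed_cal=100.0, l_out_cal=100.0)

    def test_inversion_matches_box_model_example(self):
        """TP = 100*(1-0.5)/(0.5*2.79) = 35.842... checked against the box model."""
        f = FluxSeries("x", np.array([2000.0]), np.array([100.0]))
        r = Retention(0.5, 100.0, 100.0)
        tp = infer_tp(f, r, 2.79).aggregate.value[0]
        assert tp == pytest.approx(100.0 * 0.5 / (0.5 * 2.79), rel=1e-12)
        assert tp == pytest.approx(box_model_tp(100.0, 0.5, 2.79), rel=1e-6)

    def test_total_retention_gives_zero_tp(self):
        f = FluxSeries("x", np.array([2000.0, 2001.0]), np.array([50.0, 500.0]))
        r = Retention(1.0, 100.0, 0.0)
        np.testing.assert_allclose(infer_tp(f, r, 2.79).aggregate.value, 0.0)

    def test_linearity_in_flux(self):
        r = Retention(0.6, 300.0, 200.0)
        f1 = FluxSeries("x", np.array([2000.0, 2001.0]), np.array([100.0, 50.0]))
        f2 = FluxSeries("x", f1.age_ce, 2 * f1.l_sed)
        np.testing.assert_allclose(
            infer_tp(f2, r, 3.0).aggregate.value,
            2 * infer_tp(f1, r, 3.0).aggregate.value,
        )

    def test_box_model_agreement_small_grid(self):
        """Inversion equals the converged box-model steady state (<0.1%)."""
        for l_sed in (10.0, 100.0, 1000.0):
            for r_p in (0.1, 0.5, 0.9):
                for q_s in (0.5, 2.79, 20.0):
                    f = FluxSeries("x", np.array([2000.0]), np.array([l_sed]))
                    r = Retention(r_p, r_p, 1 - r_p)
                    got = infer_tp(f, r, q_s).aggregate.value[0]
                    want = box_model_tp(l_sed, r_p, q_s)
                    assert got == pytest.approx(want, rel=1e-3)

    def test_monotonicity_in_rp_and_qs(self):
        f = FluxSeries("x", np.array([2000.0]), np.array([100.0]))
        tps_rp = [
            infer_tp(f, Retention(rp, rp, 1 - rp), 2.79).aggregate.value[0]
            for rp in (0.2, 0.4, 0.6, 0.8)
        ]
        assert all(a > b for a, b in zip(tps_rp, tps_rp[1:]))
        tps_qs = [
            infer_tp(f, Retention(0.5, 1.0, 1.0), qs).aggregate.value[0]
            for qs in (1.0, 2.0, 4.0)
        ]
        assert all(a > b for a, b in zip(tps_qs, tps_qs[1:]))


class TestAnchoring:
    @settings(max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        q_s=st.floats(0.5, 20.0),
        tp_level=st.floats(5.0, 500.0),
    )
    def test_window_mean_tp_equals_monitored_mean(self, seed, q_s, tp_level):
        """Anchoring invariant: mean inferred TP over the calibration window
        equals mean monitored TP over the same window, for any valid input."""
        rng = np.random.default_rng(seed)
        ages = np.arange(2003.0, 2018.0)
        flux = FluxSeries("x", ages, rng.uniform(50.0, 1000.0, len(ages)))
        mon_t = np.arange(2003.0, 2018.0, 0.5)
        mon = TimeSeries("tp", mon_t, tp_level * rng.uniform(0.5, 1.5, len(mon_t)))
        window = (2003.0, 2018.0)
        l_out = compute_lout(mon, q_s, window)
        r = calibrate_rp(flux, l_out, window)
        tp = infer_tp(flux, r, q_s)
        m = (tp.aggregate.when >= window[0]) & (tp.aggregate.when <= window[1])
        assert np.mean(tp.aggregate.value[m]) == pytest.approx(
            np.mean(mon.window(*window).value), rel=1e-9
        )
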