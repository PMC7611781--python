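"""pV-loop analysis operations and physiological perturbation protocols."""

import numpy as np
import pandas as pd
import pytest

from cardioloop.protocols import (
    afterload_sweep,
    arterial_elastance,
    detect_end_systole,
    espvr_from_results,
    espvr_regression,
    mean_ventricular_pressure,
    pump_function_graph,
    run_protocol,
    starling_curve,
    stroke_volume,
)


def synthetic_beat(t_end=585.0, dt=1.0, q_on=100.0, q_off=300.0):
    """Half-sine aortic flow pulse on [q_on, q_off]; simple p/V traces."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    q = np.where((t > q_on) & (t < q_off),
                 0.08 * np.sin(np.pi * (t - q_on) / (q_off - q_on)), 0.0)
    p = 10.0 + 80.0 * np.exp(-0.5 * ((t - 200.0) / 80.0) ** 2)
    v = 50.0 - np.cumsum(q) * dt
    return pd.DataFrame({"t": t, "p_lv": p, "v_lv": v, "q_aortic": q})


class TestEndSystole:
    def test_half_sine_pulse_end_systole_at_flow_cessation(self):
        beat = synthetic_beat()
        es = detect_end_systole(beat, "lv")
        assert es["t_es"] == pytest.approx(300.0, abs=1.0)
        assert not es["no_ejection"]

    def test_no_ejection_falls_back_to_peak_pressure_flagged(self):
        beat = synthetic_beat()
        beat["q_aortic"] = 0.0
        es = detect_end_systole(beat, "lv")
        assert es["no_ejection"]
        assert es["t_es"] == pytest.approx(200.0, abs=1.0)

    def test_noise_robustness_against_clean_scan(self):
        """A small-amplitude noisy trace detects the same end-systole as the
        clean trace within one sample (threshold 1e-6 mL/ms)."""
        beat = synthetic_beat()
        clean = detect_end_systole(beat, "lv")
        rng = np.random.default_rng(0)
        noisy = beat.copy()
        noisy["q_aortic"] = noisy["q_aortic"] + np.where(
            noisy["q_aortic"] > 0, 1e-9 * rng.normal(size=len(beat)), 0.0)
        nz = detect_end_systole(noisy, "lv")
        assert abs(nz["t_es"] - clean["t_es"]) <= 1.0

    def test_missing_columns_reported(self):
        with pytest.raises(KeyError, match="missing columns"):
            detect_end_systole(pd.DataFrame({"t": [0.0]}), "lv")


class TestEspvr:
    def test_exact_collinear_points(self):
        fit = espvr_regression([(30.0, 20.0), (40.0, 40.0), (50.0, 60.0)])
        assert fit.e_es == pytest.approx(2.0, rel=1e-12)
        assert fit.v_d == pytest.approx(20.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_exact_interpolant(self):
        fit = espvr_regression([(30.0, 15.0), (50.0, 55.0)])
        assert fit.e_es == pytest.approx(2.0, rel=1e-12)
        assert fit.v_d == pytest.approx(22.5, rel=1e-12)

    def test_symmetric_noise_perturbs_slope_linearly(self):
        """Collinear points with +-delta noise recover the slope to O(delta)."""
        v = np.array([30.0, 40.0, 50.0, 60.0])
        delta = 0.5
        noise = np.array([delta, -delta, -delta, delta])
        # closed-form OLS slope on the noisy data (independent oracle)
        p = 2.0 * (v - 20.0) + noise
        vc = v - v.mean()
        slope_expected = (vc * p).sum() / (vc * vc).sum()
        fit = espvr_regression(list(zip(v, p)))
        assert fit.e_es == pytest.approx(slope_expected, rel=1e-12)
        assert abs(fit.e_es - 2.0) < 5 * delta / np.ptp(v)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            espvr_regression([(30.0, 20.0)])
        with pytest.raises(ValueError, match="vertical"):
            espvr_regression([(30.0, 20.0), (30.0, 40.0)])


class TestScalarMeasures:
    def test_arterial_elastance_division(self):
        beat = synthetic_beat()
        es = detect_end_systole(beat, "lv")
        sv = stroke_volume(beat, "lv")
        assert arterial_elastance(beat, "lv") == pytest.approx(es["p_es"] / sv)

    def test_arterial_elastance_scale_invariance(self):
        beat = synthetic_beat()
        double = beat.copy()
        double["p_lv"] *= 2.0
        double["v_lv"] = 2.0 * beat["v_lv"]
        double["q_aortic"] *= 2.0
        assert arterial_elastance(double, "lv") == pytest.approx(
            arterial_elastance(beat, "lv"), rel=1e-4)

    def test_mvp_of_constant_pressure(self):
        t = np.arange(0, 586.0)
        beat = pd.DataFrame({"t": t, "p_lv": np.full_like(t, 50.0)})
        assert mean_ventricular_pressure(beat, "lv") == pytest.approx(50.0)

    def test_mvp_of_square_wave(self):
        t = np.arange(0, 1001.0)
        p = np.where(t < 500, 80.0, 0.0)
        beat = pd.DataFrame({"t": t, "p_lv": p})
        assert mean_ventricular_pressure(beat, "lv") == pytest.approx(40.0, rel=2e-3)

    def test_mvp_of_sine_matches_integral(self):
        t = np.linspace(0.0, 585.0, 2000)
        p = 40.0 + 30.0 * np.sin(2 * np.pi * t / 585.0)
        beat = pd.DataFrame({"t": t, "p_lv": p})
        # closed form: mean of offset sine over one period is the offset
        assert mean_ventricular_pressure(beat, "lv") == pytest.approx(40.0, abs=0.01)

    def test_incomplete_cycle_rejected(self):
        t = np.arange(0, 100.0)
        beat = pd.DataFrame({"t": t, "p_lv": t})
        with pytest.raises(ValueError, match="full cycle"):
            mean_ventricular_pressure(beat, "lv", t_cycle=585.0)


class TestSyntheticFits:
    def test_pfg_recovers_exact_quadratic(self):
        """Data generated from MVP(q) = P_iso (1 - (q/q_mx)^2) is recovered
        to machine precision (fit of its own model class)."""
        from cardioloop.protocols import ProtocolResult

        p_iso, q_mx = 60.0, 120.0
        results = []
        for q in (0.0, 30.0, 60.0, 90.0):
            sv = q * 0.585
            mvp = p_iso * (1.0 - (q / q_mx) ** 2)
            beat = pd.DataFrame({"t": [0.0, 585.0], "p_lv": [mvp, mvp]})
            r = ProtocolResult(condition={}, initial_beat=beat, limit_beat=beat)
            r.limit = {"sv": sv, "mvp": mvp}
            results.append(r)
        fit = pump_function_graph(results, t_cycle=585.0)
        assert fit["p_iso"] == pytest.approx(p_iso, rel=1e-10)
        assert fit["q_mx"] == pytest.approx(q_mx, rel=1e-10)

    def test_pfg_needs_three_conditions(self):
        with pytest.raises(ValueError, match="at least 3"):
            pump_function_graph([])

    def test_starling_recovers_exact_line(self):
        from cardioloop.protocols import ProtocolResult

        results = []
        for p_ed in (5.0, 8.0, 11.0):
            r = ProtocolResult(condition={}, initial_beat=None, limit_beat=None)
            r.limit = {"p_ed": p_ed, "sv": 10.0 + 1.3 * p_ed}
            results.append(r)
        out = starling_curve(results)
        assert out["slope"] == pytest.approx(1.3, rel=1e-12)


@pytest.fixture(scope="module")
def afterload_results(baseline_0d):
    factors = [0.5, 0.75, 1.0, 1.35, 1.65]
    return factors, afterload_sweep(
        baseline_0d["params"], factors, baseline_0d["state"], n_beats=8)


@pytest.fixture(scope="module")
def preload_results(baseline_0d):
    # pulmonary venous inlet areas small enough that the inlet's
    # Bernoulli resistance actually limits filling (walk-down range)
    factors = [0.03, 0.06, 0.09, 0.12]
    return [run_protocol(baseline_0d["params"], {"preload_factor": f},
                         baseline_0d["state"], n_beats=8)
            for f in factors]


class TestClosedLoopProtocols:
    """Perturbation protocols on the calibrated 0D baseline.

    These run multi-beat closed-loop simulations and are the slowest part
    of the suite.
    """

    def test_arterial_elastance_proportional_to_rsys(self, baseline_0d,
                                                     afterload_results):
        """E_a = p_es/SV is proportional to R_sys across the sweep at fixed
        heart rate (linear regression R^2 > 0.95)."""
        factors, results = afterload_results
        r_sys = np.array([baseline_0d["params"].r_sys * f for f in factors])
        e_a = np.array([r.limit["e_a"] for r in results])
        slope, intercept = np.polyfit(r_sys, e_a, 1)
        pred = slope * r_sys + intercept
        r2 = 1 - ((e_a - pred) ** 2).sum() / ((e_a - e_a.mean()) ** 2).sum()
        assert slope > 0
        assert r2 > 0.95

    def test_afterload_step_initial_response(self, afterload_results):
        """+65% afterload: first-beat p_es rises and SV falls vs baseline."""
        factors, results = afterload_results
        base = results[factors.index(1.0)]
        high = results[factors.index(1.65)]
        assert high.initial["p_es"] > base.initial["p_es"]
        assert high.initial["sv"] < base.initial["sv"]

    def test_espvr_slope_orders_with_contractility(self, baseline_0d):
        """ESPVR slope from afterload perturbations is steeper at +20%
        contractility and flatter at -20%."""
        slopes = {}
        for cf in (0.8, 1.0, 1.2):
            results = []
            for af in (0.75, 1.0, 1.4):
                results.append(run_protocol(
                    baseline_0d["params"],
                    {"afterload_factor": af, "contractility_factor": cf},
                    baseline_0d["state"], n_beats=8))
            slopes[cf] = espvr_from_results(results).e_es
        assert slopes[1.2] > slopes[1.0] > slopes[0.8]

    def test_stroke_volume_non_decreasing_in_preload(self, preload_results):
        """Frank-Starling: SV is non-decreasing in end-diastolic pressure."""
        pts = sorted((r.limit["p_ed"], r.limit["sv"]) for r in preload_results)
        sv = [p[1] for p in pts]
        assert all(sv[i + 1] >= sv[i] - 1e-6 for i in range(len(sv) - 1))

    def test_starling_curve_slope_positive(self, preload_results):
        out = starling_curve(preload_results)
        assert out["slope"] > 0

    def test_preload_walkdown_shifts_ved_at_constant_ea(self, preload_results):
        """Preload reduction lowers V_ed while E_a = p_es/SV stays about
        constant (the afterload line pivots only with R_sys)."""
        lo = preload_results[0]
        hi = preload_results[-1]
        assert lo.limit["v_ed"] < hi.limit["v_ed"]
        assert lo.limit["e_a"] == pytest.approx(hi.limit["e_a"], rel=0.25)

    def test_pump_function_graph_decreasing_and_dominated(self, baseline_0d,
                                                          afterload_results):
        """PFG: MVP decreases with mean flow; the quadratic fit holds with
        extreme conditions included (R_sys -> 0, closed aortic valve)."""
        factors, results = afterload_results
        extremes = [
            run_protocol(baseline_0d["params"], {"afterload_factor": 0.05},
                         baseline_0d["state"], n_beats=8),
            run_protocol(baseline_0d["params"], {"aortic_closed": True},
                         baseline_0d["state"], n_beats=8),
        ]
        allres = list(results) + extremes
        fit = pump_function_graph(allres, t_cycle=baseline_0d["params"].cycle_length)
        pts = sorted((r["q"], r["mvp"]) for r in fit["points"])
        q = np.array([p[0] for p in pts])
        mvp = np.array([p[1] for p in pts])
        # monotone decreasing along the afterload sweep
        assert (np.diff(mvp) < 1e-9).all()
        assert fit["p_iso"] > 0 and fit["q_mx"] > q.max()
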