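"""Closed-loop 0D circulation: conservation, signs, integrator, coupling
interface."""

import numpy as np
import pytest

from cardioloop.circulation import (
    _IDX_CAV,
    _IDX_Q,
    CircParams,
    CircState,
    CirculationModel,
    N_STATE,
    rkf45_advance,
    run_standalone_to_limit_cycle,
)


@pytest.fixture(scope="module")
def model():
    p = CircParams()
    m = CirculationModel(p)
    m.triggers = m.default_triggers(20 * p.cycle_length)
    return m


@pytest.fixture(scope="module")
def y0(model):
    return CircState.initial(model.params).y.copy()


class TestDerived:
    def test_imposed_pressures_override_exactly(self, model, y0):
        d = model.derived(0.0, y0, {"lv": 3.21, "rv": 1.23})
        assert d["p_cav"]["lv"] == 3.21
        assert d["p_cav"]["rv"] == 1.23
        # wall-model pressures still reported unchanged
        d0 = model.derived(0.0, y0)
        assert d["p_wall_model"]["lv"] == pytest.approx(d0["p_cav"]["lv"])

    def test_pericardial_pressure_shifts_all_cavities_equally(self, y0):
        p1 = CircParams()
        p1.peri_v_ref = 100.0  # heart volume above reference: p_peri > 0
        p2 = CircParams()
        p2.peri_v_ref = 100.0
        p2.peri_p_scale = 2.0 * p1.peri_p_scale
        m1, m2 = CirculationModel(p1), CirculationModel(p2)
        d1, d2 = m1.derived(0.0, y0), m2.derived(0.0, y0)
        assert d2["p_peri"] > d1["p_peri"]
        shifts = [d2["p_cav"][c] - d1["p_cav"][c] for c in ("la", "ra", "lv", "rv")]
        assert np.ptp(shifts) < 1e-12

    def test_passive_reference_pressures_from_wall_law(self, model, y0):
        """With no activation the cavity pressures reproduce the passive
        wall law evaluated pointwise: p = p_peri + 2 T_m C_m."""
        d = model.derived(0.0, y0)
        for cav, wall, sign in (("la", "la", 1), ("ra", "ra", 1),
                                ("lv", "lvfw", -1), ("rv", "rvfw", 1)):
            w = d["walls"][wall]
            assert w["sigma_a"] == pytest.approx(0.0, abs=1e-12)
            expected = d["p_peri"] + sign * 2.0 * w["t_m"] * w["c_m"]
            assert d["p_cav"][cav] == pytest.approx(expected, rel=1e-12)

    def test_negative_cavity_volume_reported(self, model, y0):
        y = y0.copy()
        y[_IDX_CAV["la"]] = -1.0
        with pytest.raises(FloatingPointError, match="la"):
            model.derived(0.0, y)


class TestDerivs:
    def test_closed_loop_volume_balance_is_exact(self, model, y0):
        """Sum of dV/dt over all 8 compartments vanishes identically."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = y0 * (1.0 + 0.05 * rng.normal(size=N_STATE))
            y[:8] = np.abs(y[:8])
            dy = model.derivs(100.0, y)
            assert abs(dy[:8].sum()) < 1e-12 * np.abs(dy[:8]).max()

    def test_closed_valve_equal_pressures_no_flow_change(self, model, y0):
        """Equal pressures across a resting valve: dq/dt = 0."""
        y = y0.copy()
        y[18:24] = 0.0
        d = model.derived(0.0, y)
        dy = model.derivs(0.0, y)
        for v in ("mitral", "aortic"):
            dp = d["dp_valve"][v]
            # driving term is the pressure difference; derivative scales
            # with it (zero crossing at dp = 0)
            assert np.sign(dy[_IDX_Q[v]]) == np.sign(dp) or dp == 0.0

    def test_positive_pressure_difference_opens_valve(self, model, y0):
        """Positive transvalvular pressure on a closed valve: dq/dt > 0."""
        y = y0.copy()
        y[18:24] = 0.0
        y[_IDX_CAV["la"]] = 40.0  # over-fill the LA: mitral dp > 0
        d = model.derived(0.0, y)
        assert d["dp_valve"]["mitral"] > 0
        dy = model.derivs(0.0, y)
        assert dy[_IDX_Q["mitral"]] > 0


class TestRKF45:
    def test_exponential_decay_within_tolerance(self):
        y, t, dt = np.array([1.0]), 0.0, 0.1
        while t < 1.0 - 1e-12:
            y, t, dt, _ = rkf45_advance(lambda tt, yy: -yy, y, t, dt, t_stop=1.0)
        assert y[0] == pytest.approx(np.exp(-1.0), abs=1e-6)

    def test_halving_tolerance_reduces_error(self):
        def solve(rtol):
            y, t, dt = np.array([1.0]), 0.0, 0.5
            while t < 2.0 - 1e-12:
                y, t, dt, _ = rkf45_advance(
                    lambda tt, yy: -yy, y, t, dt, t_stop=2.0,
                    rtol=rtol, atol=rtol)
            return abs(y[0] - np.exp(-2.0))

        errs = [solve(r) for r in (1e-4, 1e-6, 1e-8)]
        assert errs[0] > errs[1] > errs[2]

    def test_lands_exactly_on_stop_time(self):
        """Steps never pass t_stop and the trajectory lands on it exactly."""
        y, t, dt = np.array([1.0]), 0.0, 10.0
        while t < 0.37:
            y, t, dt, _ = rkf45_advance(lambda tt, yy: -yy, y, t, dt, t_stop=0.37)
            assert t <= 0.37
        assert t == 0.37

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            rkf45_advance(lambda tt, yy: -yy, np.array([1.0]), 0.0, 0.0)

    def test_integrator_lands_on_trigger_events(self, model, y0):
        """Beat integration stops exactly on FSM trigger times."""
        seen = []
        orig = model.derivs

        def spy(t, y, imposed=None, t_last=None):
            seen.append(t)
            return orig(t, y, imposed, t_last=t_last)

        model.derivs = spy
        try:
            model._integrate(y0.copy(), 0.0, model.params.cycle_length, 0.5, None)
        finally:
            model.derivs = orig
        seen = np.asarray(seen)
        for ev in (100.0, 20.0):  # AV exit, LA trigger
            assert np.isclose(seen, ev).any()


class TestLimitCycle:
    def test_blood_volume_conserved_over_20_beats(self, baseline_0d):
        """|sum V(t) - sum V(0)| < 1e-6 of total over 20 beats."""
        total0 = CircState.initial(baseline_0d["params"]).y[:8].sum()
        total1 = baseline_0d["state"].y[:8].sum()
        assert abs(total1 - total0) < 1e-6 * total0

    def test_lv_rv_stroke_volumes_match_within_one_percent(self, baseline_0d):
        rec = baseline_0d["record"]
        sv_lv = rec["v_lv"].max() - rec["v_lv"].min()
        sv_rv = rec["v_rv"].max() - rec["v_rv"].min()
        assert abs(sv_lv - sv_rv) < 0.01 * sv_lv

    def test_baseline_stroke_volume_near_calibration_target(self, baseline_0d):
        from cardioloop.presets import SV_TARGET_ML

        rec = baseline_0d["record"]
        sv = rec["v_lv"].max() - rec["v_lv"].min()
        assert sv == pytest.approx(SV_TARGET_ML, rel=0.10)

    def test_periodicity_residual_decreases(self, baseline_0d):
        hist = np.asarray(baseline_0d["info"]["residual_history"])
        # after the initial transient the residual decreases monotonically
        tail = hist[2:]
        assert (np.diff(tail) < 1e-3).all()
        assert tail[-1] < tail[0]

    def test_doubling_rsys_raises_mean_arterial_pressure(self, baseline_0d):
        """Ohmic relation MAP ~ CO * R_sys: higher resistance, higher MAP."""
        import copy

        p2 = copy.deepcopy(baseline_0d["params"])
        p2.r_sys *= 2.0
        _, rec2, _ = run_standalone_to_limit_cycle(
            p2, n_max_beats=8, record_last=1, state0=baseline_0d["state"])
        assert rec2["p_sysart"].mean() > baseline_0d["record"]["p_sysart"].mean()


class TestCoupledInterface:
    @pytest.fixture()
    def committed(self, model, y0):
        m = CirculationModel(model.params)
        m.triggers = model.triggers
        m.set_state(y0, 0.0, 0.5)
        return m

    def test_trial_is_pure_under_checkpoint(self, committed):
        committed.checkpoint()
        p = {"lv": 1.0}
        v1 = committed.trial_volumes(p, 1.0)
        v2 = committed.trial_volumes(p, 1.0)
        assert v1 == v2

    def test_zero_interval_leaves_volumes_unchanged(self, committed):
        committed.checkpoint()
        v = committed.trial_volumes({"lv": 1.0}, 0.0)
        assert v["lv"] == committed.state[_IDX_CAV["lv"]]

    def test_trial_without_checkpoint_raises(self, committed):
        with pytest.raises(RuntimeError, match="checkpoint"):
            committed.trial_volumes({"lv": 1.0}, 1.0)

    def test_commit_without_trial_raises(self, committed):
        with pytest.raises(RuntimeError, match="trial"):
            committed.commit()

    def test_pressure_sensitivity_is_negative(self, committed):
        """dV_ODE/dp < 0: pushing harder on a cavity empties it (this sign
        is what makes the coupled Schur system solvable)."""
        committed.checkpoint()
        v0 = committed.trial_volumes({"lv": 1.0}, 5.0)["lv"]
        v1 = committed.trial_volumes({"lv": 1.5}, 5.0)["lv"]
        assert v1 < v0

    def test_raising_ejection_pressure_empties_cavity(self, committed):
        """Valve pressure-difference law: a higher imposed LV pressure
        drives a larger aortic outflow, returning a smaller V_LV (the
        dV_ODE/dp < 0 sign that makes the Schur system solvable)."""
        committed.checkpoint()
        v_lo = committed.trial_volumes({"lv": 10.0}, 20.0)["lv"]
        v_hi = committed.trial_volumes({"lv": 14.0}, 20.0)["lv"]
        assert v_hi < v_lo

    def test_commit_finalizes_trial_state(self, committed):
        committed.checkpoint()
        v = committed.trial_volumes({"lv": 1.0}, 2.0)
        committed.commit()
        assert committed.time == 2.0
        assert committed.state[_IDX_CAV["lv"]] == v["lv"]
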