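"""Monolithic 3D solid / 0D fluid coupling.

For each PDE-modeled cavity c, one volume-consistency constraint

    V_c^PDE(u, t) - V_c^ODE(p_c, t) = 0

augments the discretized mechanics equilibrium, making the cavity
pressures p_C additional unknowns.  Each time step solves the block system
with a Newton method; the linearized block system is reduced by a Schur
complement on the (at most 4) pressure unknowns: N_cav + 1 linear solves
with the mechanics tangent K (one per cavity-pressure load derivative,
one for the mechanics residual), a small dense Schur matrix including the
finite-difference 0D pressure sensitivity dV_ODE/dp, the small solve for
the pressure increments, and back-substitution for the displacement
increment.

Two modes: ``full_newton`` iterates until the mixed convergence test
(relative l2 norm of the mechanics residual and absolute infinity norm of
the volume residual, both below eps) passes, with k_max = 20;
``semi_implicit`` performs exactly one Newton iteration per 1 ms step
(linearly-implicit scheme used to reach the limit cycle cheaply).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .circulation import _IDX_CAV, _IDX_Q, _IDX_TUBES, CAVITIES, TUBES, VALVES, CirculationModel
from .fsm import TriggerSchedule
from .mechanics import GeneralizedAlphaParams, GeneralizedAlphaStepper, MechanicsModel, MechState
from .units import kpa_to_mmhg

logger = logging.getLogger(__name__)

__all__ = ["CoupledSystem", "solve_schur_system", "run_heartbeat"]


def solve_schur_system(K_solve, B: np.ndarray, G: np.ndarray, D: np.ndarray,
                       R_alpha: np.ndarray, R_p: np.ndarray):
    """Schur-complement solve of the coupled block system.

        [ K   B ] [du]   [ -R_alpha ]
        [ G  -D ] [dp] = [ -R_p     ]

    ``K_solve`` maps a right-hand side to K^{-1} rhs; B (ndof, N) holds the
    pressure-load derivatives dR_alpha/dp; G (N, ndof) the volume gradients
    dV_PDE/du; D (N, N) the 0D sensitivities dV_ODE/dp.  Returns (du, dp).
    """
    X0 = K_solve(R_alpha)
    n = B.shape[1]
    X = np.column_stack([K_solve(B[:, i]) for i in range(n)])
    S = G @ X + D
    rhs = R_p - G @ X0
    try:
        dp = np.linalg.solve(S, rhs)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "singular Schur matrix; check the sign of dV_ODE/dp "
            "(pushing on a cavity must empty it)"
        ) from exc
    du = -X0 - X @ dp
    return du, dp


@dataclass
class CoupledSystem:
    """State and controls of the coupled 3D-0D simulation."""

    mechanics: MechanicsModel
    circulation: CirculationModel
    pde_cavities: tuple[str, ...] = ("lv",)
    dt: float = 1.0  # ms
    eps: float = 1e-6
    #: absolute mechanics-residual floor (mN): a step whose initial residual
    #: is already at roundoff cannot be reduced by a further factor eps
    r_alpha_floor: float = 1e-6
    k_max_full: int = 20
    k_max_semi: int = 1
    dp_fd: float = 1e-3  # kPa floor of the dV_ODE/dp perturbation
    gen_alpha: GeneralizedAlphaParams = field(default_factory=GeneralizedAlphaParams)
    # runtime state
    state: MechState | None = None
    pressures: dict[str, float] = field(default_factory=dict)
    stepper: GeneralizedAlphaStepper | None = None
    activation_offsets: np.ndarray | None = None  # eikonal t_a per element
    trigger_schedule: TriggerSchedule | None = None

    def __post_init__(self) -> None:
        for c in self.pde_cavities:
            if c not in self.mechanics.cavities:
                raise ValueError(f"PDE cavity {c!r} has no closed surface in the mesh")
        if self.stepper is None:
            self.stepper = GeneralizedAlphaStepper(self.mechanics, self.gen_alpha)

    # -- state snapshot (bitwise-resumable continuation) -----------------------
    def snapshot(self) -> dict:
        c = self.circulation
        return {
            "state": self.state.copy(),
            "pressures": dict(self.pressures),
            "circ": (c._y.copy(), c._t, c._dt, dict(c._p_prev)),
            "stepper_prev": dict(self.stepper._prev_pressures),
        }

    def restore(self, snap: dict) -> None:
        self.state = snap["state"].copy()
        self.pressures = dict(snap["pressures"])
        y, t, dt, p_prev = snap["circ"]
        self.circulation.set_state(y, t, dt)
        self.circulation._p_prev = dict(p_prev)
        self.stepper._prev_pressures = dict(snap["stepper_prev"])

    # -- volumes -------------------------------------------------------------
    def v_pde(self, u: np.ndarray) -> np.ndarray:
        return np.array([self.mechanics.cavity_volume(u, c) for c in self.pde_cavities])

    def volume_residual(self, u: np.ndarray, p: dict[str, float], t1: float) -> np.ndarray:
        """R_p = V_PDE(u) - V_ODE(p) over the checkpointed interval (mL)."""
        v_ode = self.circulation.trial_volumes(p, t1)
        return self.v_pde(u) - np.array([v_ode[c] for c in self.pde_cavities])

    def _dv_ode_dp(self, p: dict[str, float], t1: float,
                   v_base: dict[str, float]) -> np.ndarray:
        """dV_ODE/dp by one-sided finite differences on the trial interface."""
        n = len(self.pde_cavities)
        D = np.zeros((n, n))
        for j, cj in enumerate(self.pde_cavities):
            dp = max(abs(p[cj]) * 1e-3, self.dp_fd)
            p_pert = dict(p)
            p_pert[cj] = p[cj] + dp
            v_pert = self.circulation.trial_volumes(p_pert, t1)
            for i, ci in enumerate(self.pde_cavities):
                D[i, j] = (v_pert[ci] - v_base[ci]) / dp
        return D

    # -- activation ----------------------------------------------------------
    def update_activation(self, t: float) -> None:
        """Per-element absolute activation: latest ventricular trigger plus
        the eikonal arrival-time offset."""
        if self.activation_offsets is None or self.trigger_schedule is None:
            return
        mesh = self.mechanics.mesh
        act = np.empty(len(mesh.tets))
        for cav, region in (("lv", 1), ("rv", 6)):
            mask = mesh.elem_region == region
            if not mask.any():
                continue
            trig = self.trigger_schedule.last_trigger(cav, t)
            act[mask] = trig + self.activation_offsets[mask]
        self.mechanics.activation = act

    # -- one coupled step ------------------------------------------------------
    def step(self, mode: str = "full_newton") -> dict:
        """Advance the coupled system by one dt; returns step diagnostics."""
        if self.state is None:
            raise RuntimeError("coupled system not initialized (state is None)")
        k_max = self.k_max_full if mode == "full_newton" else self.k_max_semi
        t0 = self.state.t
        t1 = t0 + self.dt
        self.update_activation(t1 + 1e-9)
        circ = self.circulation
        circ.checkpoint()

        u = self.state.u.reshape(-1).copy()
        p = dict(self.pressures)
        res_alpha0 = None
        diag = {"t": t1, "iters": 0, "r_alpha_rel": np.inf, "r_p_inf": np.inf}
        converged = False
        for k in range(k_max):
            R_alpha, K = self.stepper.residual_and_tangent(self.state, u, p, self.dt)
            v_ode = circ.trial_volumes(p, t1)
            R_p = self.v_pde(u) - np.array([v_ode[c] for c in self.pde_cavities])
            nr = np.linalg.norm(R_alpha)
            if res_alpha0 is None:
                res_alpha0 = max(nr, 1e-14)
            r_rel = nr / res_alpha0
            r_p = np.abs(R_p).max()
            diag.update(iters=k, r_alpha_rel=r_rel, r_p_inf=r_p)
            alpha_ok = r_rel < self.eps or nr < self.r_alpha_floor
            if mode == "full_newton" and alpha_ok and r_p < self.eps:
                converged = True
                break
            D = self._dv_ode_dp(p, t1, v_ode)
            af = self.gen_alpha.alpha_f
            B = np.column_stack([
                (1.0 - af) * self.mechanics.pressure_load_vector(u, c)
                for c in self.pde_cavities
            ])
            G = np.vstack([
                self.mechanics.cavity_volume_gradient(u, c) for c in self.pde_cavities
            ])
            lu = spla.splu(K)
            du, dp = solve_schur_system(lu.solve, B, G, D, R_alpha, R_p)
            u = u + du
            for i, c in enumerate(self.pde_cavities):
                p[c] = p[c] + dp[i]
        else:
            if mode == "full_newton":
                # final convergence evaluation after the last update
                R_alpha = self.stepper.residual_and_tangent(
                    self.state, u, p, self.dt, with_tangent=False)[0]
                v_ode = circ.trial_volumes(p, t1)
                R_p = self.v_pde(u) - np.array([v_ode[c] for c in self.pde_cavities])
                nr = np.linalg.norm(R_alpha)
                r_rel = nr / res_alpha0
                r_p = np.abs(R_p).max()
                diag.update(iters=k_max, r_alpha_rel=r_rel, r_p_inf=r_p)
                if (r_rel < self.eps or nr < self.r_alpha_floor) and r_p < self.eps:
                    converged = True
                else:
                    raise RuntimeError(
                        f"coupled Newton failed at t = {t1:.1f} ms: "
                        f"|R_alpha|_rel = {r_rel:.3e}, |R_p|_inf = {r_p:.3e} mL "
                        f"after {k_max} iterations"
                    )

        # commit: make sure the 0D trial state corresponds to the accepted p
        circ.trial_volumes(p, t1)
        circ.commit()
        self.state = self.stepper.commit(self.state, u, self.dt, p)
        self.pressures = p
        diag["converged"] = converged or mode != "full_newton"
        return diag

    # -- recording -------------------------------------------------------------
    def record_row(self) -> dict:
        t = self.state.t
        y = self.circulation.state
        d = self.circulation.derived(t, y, {c: self.pressures[c] for c in self.pde_cavities})
        row = {"t": t}
        u = self.state.u.reshape(-1)
        for c in CAVITIES:
            if c in self.pde_cavities:
                row[f"p_{c}"] = kpa_to_mmhg(self.pressures[c])
                row[f"v_{c}"] = self.mechanics.cavity_volume(u, c)
            else:
                row[f"p_{c}"] = kpa_to_mmhg(d["p_cav"][c])
                row[f"v_{c}"] = y[_IDX_CAV[c]]
        for v in VALVES:
            row[f"q_{v}"] = y[_IDX_Q[v]]
        for tu in TUBES:
            row[f"p_{tu}"] = kpa_to_mmhg(d["p_tube"][tu])
            row[f"v_{tu}"] = y[_IDX_TUBES[tu]]
        return row


def run_heartbeat(system: CoupledSystem, mode: str = "full_newton",
                  n_steps: int | None = None, record: bool = True):
    """Run one heartbeat (or ``n_steps`` steps) of the coupled system.

    Returns (BeatRecord DataFrame or None, per-step diagnostics list).
    """
    import pandas as pd

    if mode not in ("full_newton", "semi_implicit"):
        raise ValueError(f"unknown mode {mode!r}")
    cl = system.circulation.params.cycle_length
    n = n_steps if n_steps is not None else int(round(cl / system.dt))
    rows = []
    diags = []
    if record:
        rows.append(system.record_row())
    for _ in range(n):
        diag = system.step(mode)
        diags.append(diag)
        if record:
            rows.append(system.record_row())
        logger.debug(
            "t=%.1f k=%d |R_a|rel=%.2e |R_p|inf=%.2e",
            diag["t"], diag["iters"], diag["r_alpha_rel"], diag["r_p_inf"],
        )
    rec = pd.DataFrame(rows) if record else None
    return rec, diags
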