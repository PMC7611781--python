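"""Closed-loop lumped (0D) model of heart and circulation.

CircAdapt-style modular structure: four elastic tubes (systemic/pulmonary
arteries and veins), four actively contracting chambers whose walls are
driven by a sarcomere model with length-dependent activation, ventricular
interaction through a shared deformable septum (TriSeg: the three
ventricular walls are spherical caps meeting at a common junction ring,
with the septal cap volume and junction radius relaxing toward tension
equilibrium), six inertial valve/inlet connections with Bernoulli and
resistive losses and smooth pressure-driven opening, peripheral
resistances, and a pericardial constraint adding a common intra-pericardial
pressure to all chambers.

The ODE state has 26 components: 4 tube volumes, 4 cavity volumes, 2
sarcomere states (contractility C and contractile sarcomere length L_si)
for each of the 5 walls (LA, RA, LV free wall, RV free wall, septum),
6 valve/inlet flows, and the 2 septal geometry states (midwall cap volume
V_sep_mid, junction radius y_mid).  Pressures, areas, strains, stresses,
tensions and peripheral flows are derived quantities, recomputable
statelessly from state + parameters.

The system is integrated with an adaptive embedded Runge-Kutta-Fehlberg
4(5) pair that lands exactly on trigger and synchronization times.  In
coupled mode, cavity pressures of PDE-modeled cavities are imposed
externally and the model answers with the cavity volumes its valve flows
imply (the V_ODE(p) map of the volume-consistency coupling), through a
checkpoint/trial/commit interface that keeps trial evaluations pure.

I/O units are mmHg / mL / ms; internal computation uses kPa / mL / ms
(geometry in mm) behind a single conversion layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fsm import TriggerSchedule, standard_heart_network
from .units import MM3_PER_ML, RHO_BLOOD, kpa_to_mmhg

__all__ = [
    "WallParams",
    "TubeParams",
    "ValveParams",
    "CircParams",
    "CircState",
    "CirculationModel",
    "rkf45_advance",
    "run_standalone_to_limit_cycle",
]

WALLS = ("la", "ra", "lvfw", "rvfw", "sep")
CAVITIES = ("la", "ra", "lv", "rv")
TUBES = ("sysart", "sysven", "pulmart", "pulmven")
VALVES = ("ven_ra", "tricuspid", "pulmonary", "ven_la", "mitral", "aortic")


@dataclass
class WallParams:
    """One myocardial wall: geometry reference plus sarcomere law.

    Lengths in um (sarcomere) and mm (wall), areas mm^2, volumes mm^3,
    stresses kPa.
    """

    a_ref: float  # midwall reference area at zero fiber strain, mm^2
    v_wall: float  # wall volume, mm^3
    sigma_act: float = 120.0  # active stress scale, kPa
    c_pas: float = 0.4  # passive stress scale, kPa
    k_pas: float = 10.0  # passive exponential rate, 1/um
    l_ref: float = 2.0  # sarcomere length at zero fiber strain, um
    l_si0: float = 1.51  # zero-active-stress contractile length, um
    l_se: float = 0.04  # series elastic element length, um
    v_max: float = 0.007  # unloaded shortening velocity, um/ms
    tau_r: float = 55.0  # contractility rise time constant, ms
    tau_d: float = 33.0  # contractility decay time constant, ms
    tau_a: float = 250.0  # activation duration scale, ms


@dataclass
class TubeParams:
    """Elastic tube compartment: p = p_ref (V / v_ref)^k plus a series
    wave impedance z acting on the valve flow at its junction."""

    v_ref: float  # mL
    p_ref: float  # kPa
    k: float = 1.0
    z: float = 2.0  # kPa ms / mL


@dataclass
class ValveParams:
    """Inertial valve (or always-open venous-atrial inlet)."""

    a_open: float  # effective open orifice area, mm^2
    a_leak: float = 0.5  # closed-state leak area, mm^2
    l_eff: float = 15.0  # effective inertial length, mm
    r_v: float = 0.2e-3  # series viscous resistance, kPa ms / mL
    p_w: float = 0.05  # opening smoothness width, kPa
    diode: bool = True  # False: always open (venous inlet)


@dataclass
class CircParams:
    """Full parameter set of the closed-loop model.

    Defaults are a representative canine-scale parameterization (heart
    rate 103 bpm); the tuned baseline targeting a stroke volume of about
    21 mL lives in :mod:`cardioloop.presets`.
    """

    walls: dict[str, WallParams] = field(default_factory=lambda: {
        "la": WallParams(a_ref=2800.0, v_wall=5000.0, sigma_act=60.0,
                         tau_r=40.0, tau_d=25.0, tau_a=150.0),
        "ra": WallParams(a_ref=2800.0, v_wall=4000.0, sigma_act=60.0,
                         tau_r=40.0, tau_d=25.0, tau_a=150.0),
        "lvfw": WallParams(a_ref=4930.0, v_wall=35700.0, sigma_act=82.0),
        "rvfw": WallParams(a_ref=4675.0, v_wall=13600.0, sigma_act=68.0),
        "sep": WallParams(a_ref=2210.0, v_wall=17000.0, sigma_act=82.0),
    })
    tubes: dict[str, TubeParams] = field(default_factory=lambda: {
        "sysart": TubeParams(v_ref=60.0, p_ref=12.0, k=1.0, z=8.0),
        "sysven": TubeParams(v_ref=300.0, p_ref=0.30, k=1.0, z=1.0),
        "pulmart": TubeParams(v_ref=30.0, p_ref=2.2, k=1.0, z=4.0),
        "pulmven": TubeParams(v_ref=70.0, p_ref=0.45, k=1.0, z=1.0),
    })
    valves: dict[str, ValveParams] = field(default_factory=lambda: {
        "ven_ra": ValveParams(a_open=350.0, diode=False),
        "tricuspid": ValveParams(a_open=400.0),
        "pulmonary": ValveParams(a_open=250.0),
        "ven_la": ValveParams(a_open=350.0, diode=False),
        "mitral": ValveParams(a_open=400.0),
        "aortic": ValveParams(a_open=250.0),
    })
    r_sys: float = 340.0  # kPa ms / mL, systemic vascular resistance
    r_pulm: float = 40.0  # kPa ms / mL
    peri_v_ref: float = 260.0  # mL, pericardial reference volume
    peri_p_scale: float = 0.02  # kPa
    peri_k: float = 10.0
    cycle_length: float = 585.0  # ms (103 bpm)
    av_delay: float = 100.0  # ms
    aa_delay: float = 20.0  # ms
    vv_delay: float = 0.0  # ms
    erp: float = 350.0  # ms
    # TriSeg relaxation time constant for the septal geometry states
    tau_triseg: float = 5.0  # ms


# -- state layout -----------------------------------------------------------

_IDX_TUBES = {t: i for i, t in enumerate(TUBES)}
_IDX_CAV = {c: 4 + i for i, c in enumerate(CAVITIES)}
_IDX_C = {w: 8 + 2 * i for i, w in enumerate(WALLS)}
_IDX_LSI = {w: 9 + 2 * i for i, w in enumerate(WALLS)}
_IDX_Q = {v: 18 + i for i, v in enumerate(VALVES)}
_IDX_VSEP = 24
_IDX_Y = 25
N_STATE = 26

#: valve topology: name -> (upstream, downstream) compartment labels
_VALVE_LINK = {
    "ven_ra": ("sysven", "ra"),
    "tricuspid": ("ra", "rv"),
    "pulmonary": ("rv", "pulmart"),
    "ven_la": ("pulmven", "la"),
    "mitral": ("la", "lv"),
    "aortic": ("lv", "sysart"),
}


@dataclass
class CircState:
    """Typed view of the 26-component ODE state vector."""

    y: np.ndarray

    @classmethod
    def initial(cls, params: CircParams) -> "CircState":
        y = np.zeros(N_STATE)
        for t in TUBES:
            y[_IDX_TUBES[t]] = params.tubes[t].v_ref
        y[_IDX_CAV["la"]] = 18.0
        y[_IDX_CAV["ra"]] = 18.0
        y[_IDX_CAV["lv"]] = 40.0
        y[_IDX_CAV["rv"]] = 40.0
        for w in WALLS:
            y[_IDX_C[w]] = 0.0
            y[_IDX_LSI[w]] = params.walls[w].l_ref - params.walls[w].l_se
        y[_IDX_VSEP] = 12.0  # mL, septal cap bulging toward the RV
        y[_IDX_Y] = 22.0  # mm junction radius
        return cls(y)

    def volume(self, name: str) -> float:
        return float(self.y[_IDX_TUBES[name]] if name in _IDX_TUBES else self.y[_IDX_CAV[name]])

    def total_blood_volume(self) -> float:
        return float(self.y[:8].sum())


# -- geometry helpers -------------------------------------------------------

def _cap_height(v_m, y):
    """Height x of a spherical cap with junction radius y and signed volume
    v_m (mm^3): solves (pi/6) x (x^2 + 3 y^2) = v_m (monotone cubic)."""
    p = 3.0 * y * y
    q = -6.0 * v_m / np.pi
    disc = np.sqrt(q * q / 4.0 + p**3 / 27.0)
    return np.cbrt(-q / 2.0 + disc) + np.cbrt(-q / 2.0 - disc)


class CirculationModel:
    """Closed-loop 0D circulation with optional imposed PDE-cavity pressures.

    Parameter values are packed into arrays at construction; build a fresh
    model (cheap, stateless) after mutating a :class:`CircParams`.
    """

    def __init__(self, params: CircParams | None = None,
                 triggers: TriggerSchedule | None = None):
        self.params = params or CircParams()
        self.triggers = triggers
        self._checkpoint = None
        self._pack()

    def _pack(self) -> None:
        p = self.params
        w = [p.walls[n] for n in WALLS]
        self._w_aref = np.array([x.a_ref for x in w])
        self._w_vwall = np.array([x.v_wall for x in w])
        self._w_sact = np.array([x.sigma_act for x in w])
        self._w_cpas = np.array([x.c_pas for x in w])
        self._w_kpas = np.array([x.k_pas for x in w])
        self._w_lref = np.array([x.l_ref for x in w])
        self._w_lsi0 = np.array([x.l_si0 for x in w])
        self._w_lse = np.array([x.l_se for x in w])
        self._w_vmax = np.array([x.v_max for x in w])
        self._w_taur = np.array([x.tau_r for x in w])
        self._w_taud = np.array([x.tau_d for x in w])
        self._w_taua = np.array([x.tau_a for x in w])
        v = [p.valves[n] for n in VALVES]
        self._v_aopen = np.array([x.a_open for x in v])
        self._v_aleak = np.array([x.a_leak for x in v])
        self._v_leff = np.array([x.l_eff for x in v])
        self._v_rv = np.array([x.r_v for x in v])
        self._v_pw = np.array([x.p_w for x in v])
        self._v_diode = np.array([x.diode for x in v])
        t = [p.tubes[n] for n in TUBES]
        self._t_vref = np.array([x.v_ref for x in t])
        self._t_pref = np.array([x.p_ref for x in t])
        self._t_k = np.array([x.k for x in t])
        self._t_z = np.array([x.z for x in t])
        if (self._v_aopen <= 0).any() or (self._t_vref <= 0).any():
            raise ValueError("valve areas and tube reference volumes must be > 0")
        if p.r_sys <= 0 or p.r_pulm <= 0:
            raise ValueError("peripheral resistances must be > 0")
        # compartment pressure lookup for valves: [cav(4) | tube(4)]
        comp = {**{c: i for i, c in enumerate(CAVITIES)},
                **{t: 4 + i for i, t in enumerate(TUBES)}}
        self._v_up = np.array([comp[_VALVE_LINK[n][0]] for n in VALVES])
        self._v_dn = np.array([comp[_VALVE_LINK[n][1]] for n in VALVES])
        self._v_up_z = np.array(
            [self._t_z[_IDX_TUBES[_VALVE_LINK[n][0]]] if _VALVE_LINK[n][0] in _IDX_TUBES
             else 0.0 for n in VALVES])
        self._v_dn_z = np.array(
            [self._t_z[_IDX_TUBES[_VALVE_LINK[n][1]]] if _VALVE_LINK[n][1] in _IDX_TUBES
             else 0.0 for n in VALVES])
        self._vwall_total_ml = self._w_vwall.sum() / MM3_PER_ML

    # -- trigger helpers ---------------------------------------------------
    def default_triggers(self, t_end: float) -> TriggerSchedule:
        p = self.params
        net = standard_heart_network(
            cycle_length=p.cycle_length, aa_delay=p.aa_delay,
            av_delay=p.av_delay, vv_delay=p.vv_delay, erp=p.erp,
        )
        sched = net.wall_trigger_times(t_end)
        # ventricular walls share their ventricle's trigger
        sched.times["lvfw"] = sched.times["lv"]
        sched.times["sep"] = sched.times["lv"]
        sched.times["rvfw"] = sched.times["rv"]
        return sched

    # -- derived quantities (hot path: arrays) --------------------------------
    def _derived_arrays(self, t: float, y: np.ndarray,
                        imposed: tuple[np.ndarray, np.ndarray] | None = None):
        """Core stateless chain volume -> geometry -> strain -> stress ->
        tension -> pressure -> valve areas.  ``imposed`` is an optional
        (mask(4), values(4)) pair overriding cavity pressures (kPa)."""
        p = self.params
        v_cav = y[4:8]
        if (v_cav <= 0).any():
            bad = CAVITIES[int(np.argmin(v_cav))]
            raise FloatingPointError(f"non-positive cavity volume in {bad!r}")

        v_heart = v_cav.sum() + self._vwall_total_ml
        p_peri = p.peri_p_scale * ((v_heart / p.peri_v_ref) ** p.peri_k - 1.0)

        # wall geometry: a_m, c_m per wall (la, ra, lvfw, rvfw, sep)
        a_m = np.empty(5)
        c_m = np.empty(5)
        sin_a = np.zeros(5)
        cos_a = np.zeros(5)
        # atria: full spheres
        v_m_at = v_cav[:2] * MM3_PER_ML + 0.5 * self._w_vwall[:2]
        r_at = (3.0 * v_m_at / (4.0 * np.pi)) ** (1.0 / 3.0)
        a_m[:2] = 4.0 * np.pi * r_at**2
        c_m[:2] = 1.0 / r_at
        # ventricles: TriSeg caps (order lvfw, rvfw, sep -> indices 2, 3, 4)
        v_lv, v_rv = v_cav[2] * MM3_PER_ML, v_cav[3] * MM3_PER_ML
        v_ms = y[_IDX_VSEP] * MM3_PER_ML
        ym = y[_IDX_Y]
        if ym <= 0:
            raise FloatingPointError("non-positive TriSeg junction radius")
        vw_l, vw_r, vw_s = self._w_vwall[2], self._w_vwall[3], self._w_vwall[4]
        v_m_caps = np.array([
            -v_lv - 0.5 * vw_l - 0.5 * vw_s + v_ms,
            v_rv + 0.5 * vw_r + 0.5 * vw_s + v_ms,
            v_ms,
        ])
        x = _cap_height(v_m_caps, ym)
        r2 = x * x + ym * ym
        a_m[2:] = np.pi * r2
        c_m[2:] = 2.0 * x / r2
        sin_a[2:] = 2.0 * x * ym / r2
        cos_a[2:] = (ym * ym - x * x) / r2

        # wall mechanics (vectorized over the 5 walls)
        z = 3.0 * c_m * self._w_vwall / (2.0 * a_m)
        e_f = 0.5 * np.log(a_m / self._w_aref) - z * z / 12.0 - 0.019 * z**4
        l_s = self._w_lref * np.exp(e_f)
        l_si = y[9:18:2]
        c_state = y[8:18:2]
        sigma_a = (self._w_sact * c_state * np.maximum(l_si - self._w_lsi0, 0.0)
                   * (l_s - l_si) / self._w_lse)
        sigma_p = self._w_cpas * np.expm1(self._w_kpas * (l_s - self._w_lref))
        sigma = sigma_a + sigma_p
        t_m = (self._w_vwall * sigma / (2.0 * a_m)) * (1.0 + z * z / 3.0 + z**4 / 5.0)

        tx = t_m[2] * sin_a[2] + t_m[3] * sin_a[3] + t_m[4] * sin_a[4]
        ty = t_m[2] * cos_a[2] + t_m[3] * cos_a[3] + t_m[4] * cos_a[4]

        p_cav = np.empty(4)
        p_cav[0] = p_peri + 2.0 * t_m[0] * c_m[0]  # LA
        p_cav[1] = p_peri + 2.0 * t_m[1] * c_m[1]  # RA
        p_cav[2] = p_peri - 2.0 * t_m[2] * c_m[2]  # LV (free wall bulges left)
        p_cav[3] = p_peri + 2.0 * t_m[3] * c_m[3]  # RV
        p_wall_model = p_cav.copy()
        if imposed is not None:
            mask, vals = imposed
            p_cav = np.where(mask, vals, p_cav)

        # tubes
        v_tube = y[0:4]
        if (v_tube <= 0).any():
            bad = TUBES[int(np.argmin(v_tube))]
            raise FloatingPointError(f"non-positive tube volume in {bad!r}")
        p_tube = self._t_pref * (v_tube / self._t_vref) ** self._t_k

        q_sys = (p_tube[0] - p_tube[1]) / p.r_sys
        q_pulm = (p_tube[2] - p_tube[3]) / p.r_pulm

        # valves
        q = y[18:24]
        p_all = np.concatenate([p_cav, p_tube])
        delta = (p_all[self._v_up] - self._v_up_z * q) - (
            p_all[self._v_dn] + self._v_dn_z * q)
        s = 1.0 / (1.0 + np.exp(-np.clip(delta / self._v_pw, -40.0, 40.0)))
        a_eff = np.where(self._v_diode,
                         self._v_aleak + (self._v_aopen - self._v_aleak) * s,
                         self._v_aopen)
        return {
            "p_peri": p_peri, "a_m": a_m, "c_m": c_m, "z": z, "e_f": e_f,
            "l_s": l_s, "sigma_a": sigma_a, "sigma_p": sigma_p, "sigma": sigma,
            "t_m": t_m, "triseg_tx": tx, "triseg_ty": ty,
            "p_cav": p_cav, "p_wall_model": p_wall_model, "p_tube": p_tube,
            "q_sys": q_sys, "q_pulm": q_pulm, "q_valve": q,
            "a_eff": a_eff, "dp_valve": delta,
        }

    def derived(self, t: float, y: np.ndarray,
                imposed: dict[str, float] | None = None) -> dict:
        """Derived quantities with labeled dict views (analysis interface)."""
        d = self._derived_arrays(t, y, _imposed_arrays(imposed))
        d = dict(d)
        d["p_cav"] = {c: float(d["p_cav"][i]) for i, c in enumerate(CAVITIES)}
        d["p_wall_model"] = {c: float(d["p_wall_model"][i]) for i, c in enumerate(CAVITIES)}
        d["p_tube"] = {tn: float(d["p_tube"][i]) for i, tn in enumerate(TUBES)}
        d["q_valve"] = {v: float(d["q_valve"][i]) for i, v in enumerate(VALVES)}
        d["a_eff"] = {v: float(d["a_eff"][i]) for i, v in enumerate(VALVES)}
        d["dp_valve"] = {v: float(d["dp_valve"][i]) for i, v in enumerate(VALVES)}
        d["walls"] = {
            w: {k: float(d[k][i]) for k in
                ("a_m", "c_m", "z", "e_f", "l_s", "sigma_a", "sigma_p", "sigma", "t_m")}
            for i, w in enumerate(WALLS)
        }
        return d

    # -- time derivative -----------------------------------------------------
    def derivs(self, t: float, y: np.ndarray,
               imposed: tuple[np.ndarray, np.ndarray] | dict | None = None,
               t_last: np.ndarray | None = None) -> np.ndarray:
        """Right-hand side of the 26-ODE system.

        ``t_last`` optionally carries the per-wall last-trigger times
        (constant between trigger events; precomputed by the integrator).
        """
        if self.triggers is None:
            raise RuntimeError("CirculationModel.triggers not set")
        if isinstance(imposed, dict):
            imposed = _imposed_arrays(imposed)
        p = self.params
        d = self._derived_arrays(t, y, imposed)
        dy = np.zeros(N_STATE)

        # valve flow dynamics: inertance + Bernoulli + viscous resistance
        q = y[18:24]
        a = d["a_eff"]
        v_char = q * MM3_PER_ML / a  # mm/ms
        dp_bern = 0.5 * RHO_BLOOD * v_char * np.abs(v_char)
        inertance = RHO_BLOOD * self._v_leff * MM3_PER_ML / a
        dy[18:24] = (d["dp_valve"] - dp_bern - self._v_rv * q) / inertance

        # volume balances (closed loop: pairwise-cancelling flows)
        q_sys, q_pulm = d["q_sys"], d["q_pulm"]
        dy[_IDX_TUBES["sysart"]] = q[5] - q_sys
        dy[_IDX_TUBES["sysven"]] = q_sys - q[0]
        dy[_IDX_CAV["ra"]] = q[0] - q[1]
        dy[_IDX_CAV["rv"]] = q[1] - q[2]
        dy[_IDX_TUBES["pulmart"]] = q[2] - q_pulm
        dy[_IDX_TUBES["pulmven"]] = q_pulm - q[3]
        dy[_IDX_CAV["la"]] = q[3] - q[4]
        dy[_IDX_CAV["lv"]] = q[4] - q[5]

        # sarcomere dynamics (vectorized over walls)
        l_si = y[9:18:2]
        c_state = y[8:18:2]
        dy[9:18:2] = self._w_vmax * ((d["l_s"] - l_si) / self._w_lse - 1.0)
        if t_last is None:
            t_last = np.array([self.triggers.last_trigger(w, t) for w in WALLS])
        tc = t - t_last
        active = np.isfinite(tc) & (tc >= 0.0)
        tc_safe = np.where(active, tc, 0.0)
        xr = np.minimum(8.0, tc_safe / self._w_taur)
        f_rise = np.where(active, 0.02 * xr**3 * (8.0 - xr) ** 2 * np.exp(-xr), 0.0)
        dl = l_si - self._w_lsi0
        c_l = np.where(dl > 0, np.tanh(4.0 * dl * dl), 0.0)
        t_act = self._w_taua * (0.29 + 0.3 * l_si)
        f_decay = np.where(
            active,
            0.5 * (1.0 + np.sin(np.pi * np.clip((tc_safe - t_act) / self._w_taud, -0.5, 0.5))),
            1.0,
        )
        dy[8:18:2] = c_l * f_rise / self._w_taur - c_state * f_decay / self._w_taud

        # TriSeg septal geometry: relax toward tension equilibrium
        t_m = d["t_m"]
        t_scale = max(1e-3, abs(t_m[2]) + abs(t_m[3]) + abs(t_m[4]))
        v_scale = y[_IDX_CAV["lv"]] + y[_IDX_CAV["rv"]]
        dy[_IDX_VSEP] = -(d["triseg_tx"] / t_scale) * v_scale / p.tau_triseg
        dy[_IDX_Y] = -(d["triseg_ty"] / t_scale) * y[_IDX_Y] / p.tau_triseg

        if not np.isfinite(dy).all():
            bad = int(np.argmax(~np.isfinite(dy)))
            raise FloatingPointError(f"NaN/inf in circulation derivative component {bad}")
        return dy

    # -- coupled-mode checkpoint interface ------------------------------------
    def set_state(self, y: np.ndarray, t: float, dt: float = 1.0) -> None:
        self._y = np.asarray(y, dtype=float).copy()
        self._t = float(t)
        self._dt = float(dt)
        self._p_prev: dict[str, float] = {}

    @property
    def state(self) -> np.ndarray:
        return self._y

    @property
    def time(self) -> float:
        return self._t

    def checkpoint(self) -> None:
        """Freeze the current committed state for trial evaluations."""
        self._checkpoint = (self._y.copy(), self._t, self._dt, dict(self._p_prev))

    def trial_volumes(self, imposed: dict[str, float], t1: float) -> dict[str, float]:
        """V_ODE(p): advance the checkpointed state to ``t1`` with imposed
        PDE-cavity pressures (kPa) and return the resulting cavity volumes
        (mL).  Pure: does not alter the committed state."""
        if self._checkpoint is None:
            raise RuntimeError("trial_volumes called without a checkpoint")
        y0, t0, dt0, p_prev = self._checkpoint
        if t1 < t0 - 1e-12:
            raise ValueError("trial interval ends before the checkpoint time")
        if t1 <= t0 + 1e-12:
            y1, dt1 = y0.copy(), dt0
        else:
            ramp = _PressureRamp(p_prev, imposed, t0, t1)
            y1, dt1 = self._integrate(y0, t0, t1, dt0, ramp)
        self._trial = (y1, t1, dt1, dict(imposed))
        return {c: float(y1[_IDX_CAV[c]]) for c in imposed}

    def commit(self) -> None:
        """Accept the most recent trial advance as the committed state."""
        if not hasattr(self, "_trial"):
            raise RuntimeError("commit called without a trial advance")
        y1, t1, dt1, imposed = self._trial
        self._y, self._t, self._dt = y1, t1, dt1
        self._p_prev = imposed
        self._checkpoint = None
        del self._trial

    def _integrate(self, y, t0, t1, dt, ramp):
        events = self.triggers.events_in(t0, t1) if self.triggers else np.empty(0)
        stops = np.concatenate([events, [t1]])
        t = t0
        for stop in stops:
            if self.triggers is not None:
                t_last = np.array(
                    [self.triggers.last_trigger(w, t + 1e-9) for w in WALLS]
                )
            else:
                t_last = None
            if ramp is None:
                def rhs(tt, yy, tl=t_last):
                    return self.derivs(tt, yy, None, t_last=tl)
            else:
                def rhs(tt, yy, tl=t_last):
                    return self.derivs(tt, yy, ramp(tt), t_last=tl)
            while t < stop - 1e-10:
                y, t, dt, _ = rkf45_advance(rhs, y, t, dt, t_stop=stop)
        return y, dt


def _imposed_arrays(imposed: dict[str, float] | None):
    if not imposed:
        return None
    mask = np.zeros(4, dtype=bool)
    vals = np.zeros(4)
    for c, v in imposed.items():
        i = _IDX_CAV[c] - 4
        mask[i] = True
        vals[i] = v
    return mask, vals


class _PressureRamp:
    """Linear-in-time imposed-pressure interpolation over a coupling step."""

    def __init__(self, p0: dict[str, float], p1: dict[str, float],
                 t0: float, t1: float):
        self.t0, self.t1 = t0, t1
        self.mask, self.v1 = _imposed_arrays(p1)
        self.v0 = self.v1.copy()
        for c, v in p0.items():
            i = _IDX_CAV[c] - 4
            if self.mask[i]:
                self.v0[i] = v

    def __call__(self, t: float):
        if self.t1 <= self.t0:
            return self.mask, self.v1
        w = min(1.0, max(0.0, (t - self.t0) / (self.t1 - self.t0)))
        return self.mask, (1.0 - w) * self.v0 + w * self.v1


# -- adaptive RKF45 ---------------------------------------------------------

_RKF_A = [
    np.array([]),
    np.array([1 / 4]),
    np.array([3 / 32, 9 / 32]),
    np.array([1932 / 2197, -7200 / 2197, 7296 / 2197]),
    np.array([439 / 216, -8.0, 3680 / 513, -845 / 4104]),
    np.array([-8 / 27, 2.0, -3544 / 2565, 1859 / 4104, -11 / 40]),
]
_RKF_C = np.array([0, 1 / 4, 3 / 8, 12 / 13, 1, 1 / 2])
_RKF_B5 = np.array([16 / 135, 0, 6656 / 12825, 28561 / 56430, -9 / 50, 2 / 55])
_RKF_B4 = np.array([25 / 216, 0, 1408 / 2565, 2197 / 4104, -1 / 5, 0])

DT_MIN = 1e-8


def rkf45_advance(f, y, t, dt, t_stop=None, rtol=1e-6, atol=1e-6, scale=None):
    """One adaptive Runge-Kutta-Fehlberg 4(5) step.

    Returns (y_new, t_new, dt_next, accepted).  Never steps past
    ``t_stop``; the step is clipped to land exactly on it.  The step is
    accepted when the component-wise scaled error max|e_i|/(atol*scale_i +
    rtol*|y_i|) < 1, with the classic safety-factor update.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    k = np.empty((6, len(y)))
    while True:
        h = dt if t_stop is None else min(dt, t_stop - t)
        if h < DT_MIN:
            raise RuntimeError(
                f"RKF45 step size underflow at t = {t:.6g} (stiff component?)"
            )
        try:
            k[0] = f(t, y)
            for i in range(1, 6):
                yi = y + h * (_RKF_A[i] @ k[:i])
                k[i] = f(t + _RKF_C[i] * h, yi)
        except FloatingPointError:
            # a stage left the model's admissible region (e.g. a valve-slam
            # overshoot); reject the step and retry smaller
            dt = 0.25 * h
            continue
        y5 = y + h * (_RKF_B5 @ k)
        err = h * ((_RKF_B5 - _RKF_B4) @ k)
        sc = atol * (scale if scale is not None else 1.0) + rtol * np.abs(y)
        enorm = np.max(np.abs(err) / np.maximum(sc, 1e-300))
        if not np.isfinite(enorm):
            dt = 0.25 * h
            continue
        if enorm <= 1.0:
            dt_next = h * min(5.0, max(0.2, 0.9 * max(enorm, 1e-12) ** -0.2))
            return y5, t + h, dt_next, True
        dt = h * max(0.1, 0.9 * enorm**-0.2)


# -- standalone limit cycle --------------------------------------------------

def run_standalone_to_limit_cycle(
    params: CircParams | None = None,
    n_max_beats: int = 20,
    periodicity_tol: float = 5e-3,
    record_last: int = 1,
    sample_dt: float = 1.0,
    state0: CircState | None = None,
):
    """Run the closed-loop 0D model to its periodic limit cycle.

    Beats are simulated until the maximum relative change of the state
    vector between consecutive cycle starts drops below
    ``periodicity_tol`` or ``n_max_beats`` is reached (reported in the
    result, non-fatally).  Returns ``(state, record, info)`` where
    ``record`` is a BeatRecord-style DataFrame of the last
    ``record_last`` beats sampled on a uniform ``sample_dt`` grid.
    """
    params = params or CircParams()
    model = CirculationModel(params)
    cl = params.cycle_length
    t_end = (n_max_beats + record_last + 2) * cl
    model.triggers = model.default_triggers(t_end)
    y = (state0 or CircState.initial(params)).y.copy()
    t, dt = 0.0, 0.5
    residual = np.inf
    resid_hist = []
    n_done = 0
    for _ in range(n_max_beats):
        y_prev = y.copy()
        y, dt = model._integrate(y, t, t + cl, dt, None)
        t += cl
        n_done += 1
        scale = np.maximum(np.abs(y), 1e-6)
        residual = float(np.max(np.abs(y - y_prev) / scale))
        resid_hist.append(residual)
        if residual < periodicity_tol:
            break

    record, y, t, dt = sample_beats(model, y, t, dt, record_last * cl, sample_dt)
    info = {
        "converged": residual < periodicity_tol,
        "n_beats": n_done,
        "periodicity_residual": residual,
        "residual_history": resid_hist,
        "model": model,
        "t": t,
        "y": y,
        "dt": dt,
    }
    return CircState(y.copy()), record, info


def sample_beats(model: CirculationModel, y, t, dt, duration, sample_dt=1.0):
    """Integrate ``duration`` ms recording all signals on a uniform grid.

    Returns (record DataFrame, y, t, dt).  Pressures in mmHg, volumes mL,
    flows mL/ms.
    """
    import pandas as pd

    grid = t + np.arange(0.0, duration + 0.5 * sample_dt, sample_dt)
    rows = []
    for tg in grid:
        if tg > t + 1e-9:
            y, dt = model._integrate(y, t, tg, dt, None)
            t = tg
        d = model.derived(t, y)
        row = {"t": t}
        for c in CAVITIES:
            row[f"p_{c}"] = kpa_to_mmhg(d["p_cav"][c])
            row[f"v_{c}"] = y[_IDX_CAV[c]]
        for v in VALVES:
            row[f"q_{v}"] = y[_IDX_Q[v]]
        for tu in TUBES:
            row[f"p_{tu}"] = kpa_to_mmhg(d["p_tube"][tu])
            row[f"v_{tu}"] = y[_IDX_TUBES[tu]]
        rows.append(row)
    return pd.DataFrame(rows), y, t, dt
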