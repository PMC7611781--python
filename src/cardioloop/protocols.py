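"""Physiological testing protocols and pressure-volume loop analysis.

Implements the standard pV-based assessment of systolic and diastolic
ventricular properties on BeatRecord time series: end-systole detection by
cessation of outflow, the end-systolic pressure-volume relation (ESPVR:
elastance E_es and volume intercept V_d by linear regression over afterload
perturbations), arterial elastance E_a = p_es / SV, mean ventricular
pressure (MVP), the pump function graph (MVP against mean flow, quadratic
at fixed preload and contractility), and the Frank-Starling curve
SV(p_ed).  Protocols perturb afterload (systemic resistance R_sys, or
aortic-valve closure for the isovolumetric extreme), preload (pulmonary
venous cross-section) and contractility (peak active stress) around a
baseline limit cycle.

Records use mmHg / mL / ms (flows in mL/ms).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circulation import (
    CircParams,
    CircState,
    CirculationModel,
    run_standalone_to_limit_cycle,
    sample_beats,
)

__all__ = [
    "EspvrFit",
    "detect_end_systole",
    "espvr_regression",
    "arterial_elastance",
    "mean_ventricular_pressure",
    "stroke_volume",
    "ProtocolResult",
    "run_protocol",
    "afterload_sweep",
    "pump_function_graph",
    "starling_curve",
]

#: outflow-cessation detection threshold (mL/ms)
FLOW_THRESHOLD = 1e-6


@dataclass
class EspvrFit:
    """End-systolic pressure-volume relation p_es = E_es (V_es - V_d)."""

    e_es: float  # mmHg/mL
    v_d: float  # mL
    points: list[tuple[float, float]]  # (V_es, p_es)
    r_squared: float


def _require_columns(beat: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in beat.columns]
    if missing:
        raise KeyError(f"BeatRecord is missing columns {missing}")


def detect_end_systole(beat: pd.DataFrame, cavity: str = "lv",
                       outflow: str | None = None) -> dict:
    """End-systole: first downward crossing of the outflow below threshold
    after peak ejection; p_es and V_es by linear interpolation there.

    Falls back (flagged) to the instant of peak pressure for beats without
    ejection.
    """
    outflow = outflow or ("q_aortic" if cavity == "lv" else "q_pulmonary")
    _require_columns(beat, ["t", f"p_{cavity}", f"v_{cavity}", outflow])
    t = beat["t"].to_numpy()
    q = beat[outflow].to_numpy()
    p = beat[f"p_{cavity}"].to_numpy()
    v = beat[f"v_{cavity}"].to_numpy()
    ipk = int(np.argmax(q))
    flagged = False
    if q[ipk] <= FLOW_THRESHOLD:
        ies = int(np.argmax(p))  # no ejection: fall back to peak pressure
        return {"t_es": float(t[ies]), "p_es": float(p[ies]),
                "v_es": float(v[ies]), "no_ejection": True}
    below = np.where(q[ipk:] < FLOW_THRESHOLD)[0]
    if len(below) == 0:
        ies = len(t) - 1
        t_es, p_es, v_es = t[ies], p[ies], v[ies]
        flagged = True
    else:
        i1 = ipk + below[0]
        i0 = i1 - 1
        # linear interpolation of the crossing time between samples
        w = (q[i0] - FLOW_THRESHOLD) / max(q[i0] - q[i1], 1e-300)
        t_es = t[i0] + w * (t[i1] - t[i0])
        p_es = p[i0] + w * (p[i1] - p[i0])
        v_es = v[i0] + w * (v[i1] - v[i0])
    return {"t_es": float(t_es), "p_es": float(p_es), "v_es": float(v_es),
            "no_ejection": flagged}


def espvr_regression(points) -> EspvrFit:
    """Ordinary least squares of p_es on V_es -> (E_es, V_d)."""
    pts = [(float(v), float(p)) for v, p in points]
    if len(pts) < 2:
        raise ValueError("ESPVR regression needs at least 2 afterload states")
    v = np.array([x[0] for x in pts])
    p = np.array([x[1] for x in pts])
    if np.ptp(v) < 1e-12:
        raise ValueError("identical V_es values: ESPVR slope undefined (vertical)")
    slope, intercept = np.polyfit(v, p, 1)
    pred = slope * v + intercept
    ss_res = float(((p - pred) ** 2).sum())
    ss_tot = float(((p - p.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return EspvrFit(e_es=float(slope), v_d=float(-intercept / slope),
                    points=pts, r_squared=r2)


def stroke_volume(beat: pd.DataFrame, cavity: str = "lv") -> float:
    v = beat[f"v_{cavity}"].to_numpy()
    return float(v.max() - v.min())


def arterial_elastance(beat: pd.DataFrame, cavity: str = "lv") -> float:
    """Effective arterial elastance E_a = p_es / SV (mmHg/mL)."""
    sv = stroke_volume(beat, cavity)
    if sv <= 0:
        raise ValueError("stroke volume must be positive for E_a")
    es = detect_end_systole(beat, cavity)
    return es["p_es"] / sv


def mean_ventricular_pressure(beat: pd.DataFrame, cavity: str = "lv",
                              t_cycle: float | None = None) -> float:
    """MVP = (1/t_cycle) integral of p over the cycle (trapezoid rule)."""
    _require_columns(beat, ["t", f"p_{cavity}"])
    t = beat["t"].to_numpy()
    p = beat[f"p_{cavity}"].to_numpy()
    span = t[-1] - t[0]
    if t_cycle is not None and span < 0.99 * t_cycle:
        raise ValueError(
            f"record spans {span:.1f} ms but a full cycle of {t_cycle:.1f} ms is required"
        )
    if span <= 0:
        raise ValueError("record does not span a cycle")
    return float(np.trapezoid(p, t) / span)


def end_diastolic_point(beat: pd.DataFrame, cavity: str = "lv") -> tuple[float, float]:
    """(p_ed, V_ed) at the end of filling.

    The volume flat-tops while isovolumetric pressure already rises
    (smoothly closing inflow valve), so the point is taken at the first
    sample reaching 99.9% of the filling excursion rather than at argmax.
    """
    v = beat[f"v_{cavity}"].to_numpy()
    p = beat[f"p_{cavity}"].to_numpy()
    thresh = v.max() - 1e-3 * (v.max() - v.min())
    ied = int(np.argmax(v >= thresh))
    return float(p[ied]), float(v[ied])


# -- protocols on the 0D closed loop -----------------------------------------


@dataclass
class ProtocolResult:
    """Per-condition measurements of a perturbation protocol."""

    condition: dict
    initial_beat: pd.DataFrame
    limit_beat: pd.DataFrame
    initial: dict = field(default_factory=dict)
    limit: dict = field(default_factory=dict)


def _measure(beat: pd.DataFrame, cavity: str = "lv") -> dict:
    es = detect_end_systole(beat, cavity)
    p_ed, v_ed = end_diastolic_point(beat, cavity)
    out = {
        "sv": stroke_volume(beat, cavity),
        "p_es": es["p_es"], "v_es": es["v_es"], "t_es": es["t_es"],
        "no_ejection": es["no_ejection"],
        "p_ed": p_ed, "v_ed": v_ed,
        "mvp": mean_ventricular_pressure(beat, cavity),
        "p_max": float(beat[f"p_{cavity}"].max()),
    }
    if not es["no_ejection"] and out["sv"] > 0:
        out["e_a"] = es["p_es"] / out["sv"]
    return out


def _apply_perturbation(params: CircParams, protocol: dict) -> CircParams:
    p = copy.deepcopy(params)
    if "afterload_factor" in protocol:
        p.r_sys = params.r_sys * protocol["afterload_factor"]
    if "preload_factor" in protocol:
        # preload set by the pulmonary venous cross-section (inlet area)
        p.valves["ven_la"].a_open = params.valves["ven_la"].a_open * protocol["preload_factor"]
    if "contractility_factor" in protocol:
        for w in ("lvfw", "sep"):
            p.walls[w].sigma_act = params.walls[w].sigma_act * protocol["contractility_factor"]
    if "aortic_closed" in protocol and protocol["aortic_closed"]:
        p.valves["aortic"].a_open = p.valves["aortic"].a_leak * 1.000001
    return p


def run_protocol(params: CircParams, protocol: dict, baseline_state: CircState,
                 n_beats: int = 8, cavity: str = "lv") -> ProtocolResult:
    """Apply a step perturbation at beat 1 from a baseline limit-cycle state.

    Records the initial-response beat (first beat after the step) and the
    re-stabilized response after ``n_beats`` beats.  ``protocol`` keys:
    ``afterload_factor``, ``preload_factor``, ``contractility_factor``,
    ``aortic_closed``.
    """
    pert = _apply_perturbation(params, protocol)
    model = CirculationModel(pert)
    cl = pert.cycle_length
    t_end = (n_beats + 3) * cl
    model.triggers = model.default_triggers(t_end)
    y = baseline_state.y.copy()
    # initial response: the first post-step beat
    first, y1, t1, dt1 = sample_beats(model, y.copy(), 0.0, 0.5, cl)
    # re-stabilized response after n_beats
    yb, dtb = model._integrate(y.copy(), 0.0, n_beats * cl, 0.5, None)
    limit, _, _, _ = sample_beats(model, yb, n_beats * cl, dtb, cl)
    res = ProtocolResult(condition=dict(protocol), initial_beat=first, limit_beat=limit)
    res.initial = _measure(first, cavity)
    res.limit = _measure(limit, cavity)
    return res


def afterload_sweep(params: CircParams, factors, baseline_state: CircState,
                    n_beats: int = 8, cavity: str = "lv") -> list[ProtocolResult]:
    return [
        run_protocol(params, {"afterload_factor": float(f)}, baseline_state,
                     n_beats=n_beats, cavity=cavity)
        for f in factors
    ]


def espvr_from_results(results, which: str = "limit") -> EspvrFit:
    pts = [(getattr(r, which)["v_es"], getattr(r, which)["p_es"]) for r in results]
    return espvr_regression(pts)


def pump_function_graph(results, which: str = "limit", t_cycle: float | None = None):
    """Pump function graph: MVP against mean flow, with quadratic fit.

    Fits MVP(q) = P_iso (1 - (q / q_mx)^2) by least squares on
    (q^2, MVP); ``results`` must span at least 3 afterload conditions at
    fixed preload and contractility (include the extremes: R_sys -> 0 and
    aortic-valve closure).  Mean flow q = SV / t_cycle in mL/s.
    """
    if len(results) < 3:
        raise ValueError("pump function graph needs at least 3 afterload conditions")
    rows = []
    for r in results:
        m = getattr(r, which)
        tc = t_cycle or (r.limit_beat["t"].iloc[-1] - r.limit_beat["t"].iloc[0])
        q = m["sv"] / tc * 1000.0  # mL/s
        rows.append({"q": q, "mvp": m["mvp"], "sv": m["sv"],
                     "condition": r.condition})
    q2 = np.array([r["q"] ** 2 for r in rows])
    mvp = np.array([r["mvp"] for r in rows])
    # linear LS in (1, q^2): mvp = a + b q^2, P_iso = a, q_mx = sqrt(-a/b)
    A = np.column_stack([np.ones_like(q2), q2])
    (a, b), *_ = np.linalg.lstsq(A, mvp, rcond=None)
    if b >= 0 or a <= 0:
        raise ValueError("pump function data not consistent with a decreasing quadratic")
    return {"points": rows, "p_iso": float(a), "q_mx": float(np.sqrt(-a / b))}


def starling_curve(results, which: str = "limit"):
    """Frank-Starling relation: (p_ed, SV) pairs and their OLS slope.

    ``results`` must span >= 3 preload levels (sorted internally by p_ed);
    slope in mL/mmHg.
    """
    if len(results) < 3:
        raise ValueError("Starling curve needs at least 3 preload levels")
    pts = sorted(
        ((getattr(r, which)["p_ed"], getattr(r, which)["sv"]) for r in results)
    )
    p_ed = np.array([x[0] for x in pts])
    sv = np.array([x[1] for x in pts])
    slope = float(np.polyfit(p_ed, sv, 1)[0])
    return {"points": list(zip(p_ed.tolist(), sv.tolist())), "slope": slope}
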