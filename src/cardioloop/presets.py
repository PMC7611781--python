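"""Shipped parameter presets.

``FSM_TIMING`` mirrors the electro-mechanical synchronization block (heart
rate 103 bpm, cycle length 0.585 s, inter-atrial delay 20 ms,
atrio-ventricular delay 100 ms, inter-ventricular delay 0, effective
refractory period 350 ms).  ``PDE_MODEL`` mirrors the 3D tissue-model
block: passive orthotropic parameters, active-transient parameters (peak
tension 100 kPa LV / 80 kPa RV) and conduction velocities
(1.02, 0.68, 0.34) m/s along fiber / sheet / sheet-normal.  The 0D
circulation preset is the package's representative canine-scale
parameterization calibrated to a stroke volume of about 21 mL at 103 bpm
(cardiac output about 2.1 L/min).
"""

from __future__ import annotations

from .circulation import CircParams
from .geometry import GeometryParams
from .materials import ActiveStressParams, PassiveMaterialParams
from .mechanics import BoundaryConditionSet

__all__ = [
    "FSM_TIMING",
    "PDE_MODEL",
    "baseline_circulation",
    "baseline_geometry",
    "coupled_fixture_geometry",
    "SV_TARGET_ML",
    "HEART_RATE_BPM",
]

#: calibration targets of the baseline parameterization
SV_TARGET_ML = 21.0
HEART_RATE_BPM = 103.0

#: FSM synchronization parameters (times in ms unless noted)
FSM_TIMING = {
    "HR": 103.0,  # beats/min
    "CL": 585.0,  # = 60000 / HR, ms
    "RA": 0.0,  # first RA trigger
    "AA_delay": 20.0,
    "AV_delay": 100.0,
    "VV_delay": 0.0,
    "ERP": 350.0,
}

#: 3D tissue model parameters (names follow the standard symbol set)
PDE_MODEL = {
    # passive biomechanics
    "rho0": 1060.0,  # kg/m^3
    "kappa": 650.0,  # kPa
    "a": 0.7,  # kPa
    "b_ff": 5.0, "b_ss": 6.0, "b_nn": 3.0,
    "b_fs": 10.0, "b_fn": 2.0, "b_ns": 2.0,
    # active biomechanics
    "lambda0": 0.7,  # minimum fiber stretch (dimensionless)
    "t_emd": 15.0,  # ms
    "S_peak_LV": 100.0,  # kPa
    "S_peak_RV": 80.0,  # kPa
    "t_dur": 300.0,  # ms
    "tau_c0": 100.0,  # ms
    "ld": 5.0,
    "ld_up": 500.0,  # ms
    "tau_r": 100.0,  # ms
    # conduction velocities, m/s (= mm/ms)
    "v_f": 1.02, "v_s": 0.68, "v_n": 0.34,
}


def passive_material() -> PassiveMaterialParams:
    return PassiveMaterialParams(
        rho0=PDE_MODEL["rho0"] / 1000.0,  # kg/m^3 -> mg/mm^3
        kappa=PDE_MODEL["kappa"], a=PDE_MODEL["a"],
        b_ff=PDE_MODEL["b_ff"], b_ss=PDE_MODEL["b_ss"], b_nn=PDE_MODEL["b_nn"],
        b_fs=PDE_MODEL["b_fs"], b_fn=PDE_MODEL["b_fn"], b_ns=PDE_MODEL["b_ns"],
    )


def active_material() -> ActiveStressParams:
    return ActiveStressParams(
        s_peak=PDE_MODEL["S_peak_LV"], t_dur=PDE_MODEL["t_dur"],
        tau_c0=PDE_MODEL["tau_c0"], tau_r=PDE_MODEL["tau_r"],
        ld=PDE_MODEL["ld"], ld_up=PDE_MODEL["ld_up"],
        lam0=PDE_MODEL["lambda0"], t_emd=PDE_MODEL["t_emd"],
    )


def baseline_circulation() -> CircParams:
    """Representative canine-scale 0D parameter set (calibrated baseline)."""
    return CircParams()


def baseline_geometry(biventricular: bool = False) -> GeometryParams:
    """Coarse-resolution idealized geometry (3.4 mm target edge length)."""
    return GeometryParams(edge_length=3.4, biventricular=biventricular)


def coupled_fixture_geometry(biventricular: bool = False) -> GeometryParams:
    """Small fixture for coupled 3D-0D runs (about 1-2k tets)."""
    return GeometryParams(edge_length=7.0, biventricular=biventricular)


def default_bcs() -> BoundaryConditionSet:
    return BoundaryConditionSet()
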