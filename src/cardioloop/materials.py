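"""Myocardial constitutive laws: orthotropic passive and length-dependent
active stress.

Passive: nearly incompressible Fung-type orthotropic hyperelasticity
(Usyk-style),

    Psi(C) = kappa/2 (log J)^2 + a/2 (exp Q - 1),
    Q = b_ff Ebar_ff^2 + b_ss Ebar_ss^2 + b_nn Ebar_nn^2
        + 2 b_fs Ebar_fs^2 + 2 b_fn Ebar_fn^2 + 2 b_ns Ebar_ns^2,

with Ebar = (Cbar - I)/2 the modified isochoric Green-Lagrange strain and
the directional strains taken in the local (f0, s0, n0) frame.  The second
Piola-Kirchhoff stress is S_p = 2 dPsi/dC, implemented analytically and
verified against finite differences of the energy in the test suite.

Active: a phenomenological transient

    S_a(t, lam) = S_peak phi(lam) tanh^2(t_s/tau_c) tanh^2((t_dur-t_s)/tau_r)
    phi = tanh(ld (lam - lam0)),  tau_c = tau_c0 + ld_up (1 - phi),
    t_s = t - t_a - t_emd,

nonzero only for 0 < t_s < t_dur, mapped to a stress tensor with full
contractile force along f0 and 40% along s0:

    S_a_tensor = S_a (f0.C f0)^-1 f0 x f0 + 0.4 S_a (s0.C s0)^-1 s0 x s0.

All routines accept complex-valued kinematic inputs so that consistent
tangents can be obtained by complex-step differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PassiveMaterialParams",
    "ActiveStressParams",
    "strain_energy",
    "passive_stress",
    "active_stress_scalar",
    "active_stress_tensor",
    "det3",
    "inv3",
]

#: Sheet-to-fiber ratio of active contractile force.
SHEET_ACTIVE_FRACTION = 0.4

#: Cap on the Fung exponent to avoid overflow at extreme strains.
_Q_CLAMP = 80.0


@dataclass
class PassiveMaterialParams:
    """Passive orthotropic material parameters (reference values for canine
    ventricular myocardium)."""

    rho0: float = 1.06e0  # mg/mm^3 (= 1060 kg/m^3)
    kappa: float = 650.0  # kPa, bulk modulus
    a: float = 0.7  # kPa, stiffness scaling
    b_ff: float = 5.0
    b_ss: float = 6.0
    b_nn: float = 3.0
    b_fs: float = 10.0
    b_fn: float = 2.0
    b_ns: float = 2.0

    def validate(self) -> None:
        if self.kappa <= 0 or self.a <= 0:
            raise ValueError("kappa and a must be positive")
        if min(self.b_ff, self.b_ss, self.b_nn, self.b_fs, self.b_fn, self.b_ns) < 0:
            raise ValueError("exponent coefficients b_* must be >= 0")


@dataclass
class ActiveStressParams:
    """Active stress transient parameters."""

    s_peak: float = 100.0  # kPa (LV nominal; RV nominal 80)
    t_dur: float = 300.0  # ms
    tau_c0: float = 100.0  # ms
    tau_r: float = 100.0  # ms
    ld: float = 5.0  # degree of length dependence
    ld_up: float = 500.0  # ms
    lam0: float = 0.7  # minimum fiber stretch (dimensionless)
    t_emd: float = 15.0  # ms, electromechanical delay

    def validate(self) -> None:
        if self.t_dur <= 0 or self.tau_c0 <= 0 or self.tau_r <= 0:
            raise ValueError("t_dur, tau_c0 and tau_r must be positive")
        if not 0.0 < self.lam0 < 1.0:
            raise ValueError("lam0 must lie in (0, 1)")


# -- small complex-safe tensor algebra --------------------------------------

def det3(A):
    """Determinant of (..., 3, 3) arrays, complex-safe."""
    return (
        A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
        - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
        + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
    )


def inv3(A, det=None):
    """Inverse of (..., 3, 3) arrays via the adjugate, complex-safe."""
    d = det3(A) if det is None else det
    out = np.empty_like(A)
    out[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    out[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    out[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    out[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    out[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    out[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    out[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    out[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    out[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return out / d[..., None, None]


def _log(x):
    # complex-safe log (real part assumed positive: J > 0)
    return np.log(x.astype(complex)) if np.iscomplexobj(x) else np.log(x)


def _fung_Q(C, basis, p: PassiveMaterialParams, J):
    """Exponent Q and local isochoric strain, shared by energy and stress."""
    Cbar = J[..., None, None] ** (-2.0 / 3.0) * C
    eye = np.eye(3)
    Ebar = 0.5 * (Cbar - eye)
    # local-frame components: E_loc = B^T Ebar B with B = [f0 s0 n0]
    Bt = np.swapaxes(basis, -1, -2)
    Eloc = Bt @ Ebar @ basis
    b = np.array([
        [p.b_ff, p.b_fs, p.b_fn],
        [p.b_fs, p.b_ss, p.b_ns],
        [p.b_fn, p.b_ns, p.b_nn],
    ])
    Q = np.einsum("ab,...ab->...", b, Eloc**2)
    return Q, Eloc, b


def strain_energy(C, basis, params: PassiveMaterialParams):
    """Strain-energy density Psi(C) in kPa; C of shape (..., 3, 3).

    ``basis`` holds the fiber triad as columns: basis[..., :, 0] = f0 etc.
    """
    J2 = det3(C)
    J = np.sqrt(J2.astype(complex)) if np.iscomplexobj(C) else np.sqrt(J2)
    Q, _, _ = _fung_Q(C, basis, params, J)
    logJ = _log(J)
    return 0.5 * params.kappa * logJ**2 + 0.5 * params.a * (np.exp(Q) - 1.0)


def passive_stress(C, basis, params: PassiveMaterialParams, clamp: bool = True):
    """Second Piola-Kirchhoff passive stress S_p = 2 dPsi/dC (kPa).

    Analytic: volumetric part kappa log(J) C^{-1}; isochoric part
    J^{-2/3} Dev[Sbar] with Sbar = a exp(Q) B (b o E_loc) B^T and
    Dev[A] = A - (A : C)/3 C^{-1}.
    """
    J2 = det3(C)
    J = np.sqrt(J2.astype(complex)) if np.iscomplexobj(C) else np.sqrt(J2)
    Cinv = inv3(C, det=J2)
    Q, Eloc, b = _fung_Q(C, basis, params, J)
    if clamp and not np.iscomplexobj(C):
        over = Q.real > _Q_CLAMP
        if np.any(over):
            raise FloatingPointError(
                f"Fung exponent overflow (Q > {_Q_CLAMP}) in {int(np.sum(over))} "
                "evaluation(s); strain state outside the material model's range"
            )
    Sbar_loc = params.a * np.exp(Q)[..., None, None] * (b * Eloc)
    Sbar = basis @ Sbar_loc @ np.swapaxes(basis, -1, -2)
    trace = (Sbar * C).sum(axis=(-2, -1))
    S_iso = J[..., None, None] ** (-2.0 / 3.0) * (
        Sbar - (trace / 3.0)[..., None, None] * Cinv
    )
    S_vol = params.kappa * _log(J)[..., None, None] * Cinv
    return S_vol + S_iso


def active_stress_scalar(t, t_a, lam, params: ActiveStressParams):
    """Scalar active stress transient S_a(t, lam) in kPa.

    Vectorized over arrays; zero outside the support 0 < t_s < t_dur.
    ``lam`` may be complex (complex-step through the length dependence).
    """
    t_s = np.asarray(t, dtype=float) - np.asarray(t_a) - params.t_emd
    phi = np.tanh(params.ld * (lam - params.lam0))
    phi = np.where(np.real(lam) > params.lam0, phi, 0.0 * phi)
    tau_c = params.tau_c0 + params.ld_up * (1.0 - phi)
    inside = (t_s > 0.0) & (t_s < params.t_dur)
    t_s_safe = np.where(inside, t_s, 0.5 * params.t_dur)
    g = (
        np.tanh(t_s_safe / tau_c) ** 2
        * np.tanh((params.t_dur - t_s_safe) / params.tau_r) ** 2
    )
    return np.where(inside, params.s_peak * phi * g, 0.0 * g)


def active_stress_tensor(S_a, C, f0, s0):
    """Orthotropic active stress tensor (kPa).

    S_a (f0.Cf0)^-1 f0xf0 + 0.4 S_a (s0.Cs0)^-1 s0xs0; the 1/lam^2 factors
    convert a Cauchy-like fiber stress into second Piola-Kirchhoff space.
    """
    cff = (np.matmul(C, f0[..., None])[..., 0] * f0).sum(-1)
    css = (np.matmul(C, s0[..., None])[..., 0] * s0).sum(-1)
    ff = f0[..., :, None] * f0[..., None, :]
    ss = s0[..., :, None] * s0[..., None, :]
    S_a = np.asarray(S_a)
    return (S_a / cff)[..., None, None] * ff + (
        SHEET_ACTIVE_FRACTION * S_a / css
    )[..., None, None] * ss
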