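"""Nonlinear finite-element mechanics of the ventricular walls.

P1 tetrahedral elements with single-point quadrature (P1-P0), orthotropic
hyperelastic passive stress, eikonal-clocked length-dependent active stress,
follower (pressure) loads on the closed cavity surfaces, omni-directional
basal springs and normal epicardial Robin springs, and generalized-alpha
time integration (spectral radius rho_inf = 0) with mass/stiffness
proportional damping.

Consistent tangents are obtained by element-level complex-step
differentiation of the analytic residual kernels: exact to machine
precision and verified against global finite differences in the tests.
The linear solves use a direct sparse factorization; the solver contract is
residual-based and solver-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import shape_gradients
from .materials import (
    ActiveStressParams,
    PassiveMaterialParams,
    active_stress_scalar,
    active_stress_tensor,
    det3,
    passive_stress,
)
from .mesh import Mesh, enclosed_volume, enclosed_volume_gradient

logger = logging.getLogger(__name__)

__all__ = [
    "BoundaryConditionSet",
    "GeneralizedAlphaParams",
    "MechState",
    "MechanicsModel",
    "unload_backward_displacement",
]

_CSTEP = 1e-30  # complex-step size; derivatives exact to machine precision


@dataclass
class BoundaryConditionSet:
    """Spring-type boundary conditions (stiffness per unit area, kPa/mm).

    ``k_base`` acts omni-directionally on the basal cut plane; ``k_epi``
    acts along the reference epicardial normal (Robin), optionally scaled
    by a per-node field (e.g. the apicobasal coordinate).
    """

    k_base: float = 2.0
    k_epi: float = 0.2
    k_epi_field: np.ndarray | None = None  # per-node scaling of k_epi

    def validate(self) -> None:
        if self.k_base < 0 or self.k_epi < 0:
            raise ValueError("spring stiffnesses must be >= 0")


@dataclass
class GeneralizedAlphaParams:
    """Generalized-alpha integrator, parameterized by spectral radius."""

    rho_inf: float = 0.0
    beta_mass: float = 0.1  # 1/ms, mass-proportional damping
    beta_stiff: float = 0.1  # ms, stiffness-proportional damping

    @property
    def alpha_m(self) -> float:
        return (2.0 * self.rho_inf - 1.0) / (self.rho_inf + 1.0)

    @property
    def alpha_f(self) -> float:
        return self.rho_inf / (self.rho_inf + 1.0)

    @property
    def beta(self) -> float:
        return 0.25 * (1.0 - self.alpha_m + self.alpha_f) ** 2

    @property
    def gamma(self) -> float:
        return 0.5 - self.alpha_m + self.alpha_f


@dataclass
class MechState:
    """Nodal displacement / velocity / acceleration (mm, mm/ms, mm/ms^2)."""

    u: np.ndarray
    v: np.ndarray
    a: np.ndarray
    t: float = 0.0

    @classmethod
    def zero(cls, n_nodes: int, t: float = 0.0) -> "MechState":
        z = np.zeros((n_nodes, 3))
        return cls(z.copy(), z.copy(), z.copy(), t)

    def copy(self) -> "MechState":
        return MechState(self.u.copy(), self.v.copy(), self.a.copy(), self.t)


class MechanicsModel:
    """Assembled FE model of the ventricular walls on a fixed mesh.

    Parameters
    ----------
    mesh : labeled tet mesh with closed cavity surfaces and fibers.
    passive : passive material parameters (single set for both ventricles).
    active : active transient parameters; ``s_peak_rv`` overrides the peak
        tension in RV-labeled elements (region 6).
    bcs : spring boundary conditions.
    activation : per-element absolute electrical activation times t_a (ms),
        or None for a passive model.  The active-stress clock per element is
        t_s = t - t_a - t_emd.
    """

    def __init__(
        self,
        mesh: Mesh,
        passive: PassiveMaterialParams | None = None,
        active: ActiveStressParams | None = None,
        bcs: BoundaryConditionSet | None = None,
        activation: np.ndarray | None = None,
        s_peak_rv: float = 80.0,
    ):
        if mesh.fibers is None:
            raise ValueError("mechanics requires a mesh with a fiber field")
        self.mesh = mesh
        self.passive = passive or PassiveMaterialParams()
        self.active = active or ActiveStressParams()
        self.passive.validate()
        self.active.validate()
        self.bcs = bcs or BoundaryConditionSet()
        self.bcs.validate()
        self.activation = activation
        self.n_nodes = len(mesh.nodes)
        self.ndof = 3 * self.n_nodes

        self.grads, self.vols = shape_gradients(mesh.nodes, mesh.tets)
        fib = mesh.fibers
        self.basis = np.stack([fib.f0, fib.s0, fib.n0], axis=2)  # columns
        self.s_peak_elem = np.where(
            mesh.elem_region == 6, s_peak_rv, self.active.s_peak
        ).astype(float)

        # lumped mass (mg): rho0 * V_e / 4 to each vertex
        mass = np.zeros(self.n_nodes)
        np.add.at(mass, mesh.tets, (self.passive.rho0 * self.vols / 4.0)[:, None])
        self.mass = mass  # per node, isotropic

        self._setup_springs()
        self._setup_cavities()
        self._setup_index_maps()

        # reference stiffness for Rayleigh damping (assembled once)
        self._K0 = None

    # -- precomputation ----------------------------------------------------
    def _setup_springs(self) -> None:
        mesh = self.mesh
        base_area = np.zeros(self.n_nodes)
        if "base" in mesh.surfaces:
            tris = mesh.surfaces["base"]
            p = mesh.nodes[tris]
            areas = 0.5 * np.linalg.norm(
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
            )
            np.add.at(base_area, tris, (areas / 3.0)[:, None])
        self.base_area = base_area

        epi_area = np.zeros(self.n_nodes)
        epi_normal = np.zeros((self.n_nodes, 3))
        if "epi" in mesh.surfaces:
            tris = mesh.surfaces["epi"]
            p = mesh.nodes[tris]
            cr = 0.5 * np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
            areas = np.linalg.norm(cr, axis=1)
            np.add.at(epi_area, tris, (areas / 3.0)[:, None])
            np.add.at(epi_normal, tris, (cr / 3.0)[:, None, :])
        nrm = np.linalg.norm(epi_normal, axis=1)
        nrm[nrm == 0] = 1.0
        self.epi_area = epi_area
        self.epi_normal = epi_normal / nrm[:, None]
        scale = self.bcs.k_epi_field if self.bcs.k_epi_field is not None else 1.0
        self.k_epi_node = self.bcs.k_epi * scale * self.epi_area
        self.k_base_node = self.bcs.k_base * self.base_area

    def _setup_cavities(self) -> None:
        self.cavities = self.mesh.cavity_labels()
        self.cavity_tris = {c: self.mesh.cavity_surface(c) for c in self.cavities}
        # pressure acts on the full closed cavity surface: the lids are the
        # explicitly discretized valve faces and carry the cavity pressure,
        # which also makes the load vector work-conjugate to the enclosed
        # volume (dR/dp aligns with dV/du)
        self.load_tris = dict(self.cavity_tris)
        for c in self.cavities:
            from .mesh import surface_is_closed

            if not surface_is_closed(self.cavity_tris[c]):
                raise ValueError(f"cavity surface {c!r} is not closed")

    def _setup_index_maps(self) -> None:
        tets = self.mesh.tets
        dofs = (3 * tets[:, :, None] + np.arange(3)).reshape(len(tets), 12)
        self._elem_rows = np.repeat(dofs, 12, axis=1).reshape(-1)
        self._elem_cols = np.tile(dofs, (1, 12)).reshape(-1)
        self._tri_idx = {}
        for c in self.cavities:
            tris = self.load_tris[c]
            tdofs = (3 * tris[:, :, None] + np.arange(3)).reshape(len(tris), 9)
            rows = np.repeat(tdofs, 9, axis=1).reshape(-1)
            cols = np.tile(tdofs, (1, 9)).reshape(-1)
            self._tri_idx[c] = (tdofs, rows, cols)

    # -- kinematics ---------------------------------------------------------
    def kinematics(self, u: np.ndarray):
        """Per-element deformation measures from nodal displacements.

        Returns dict with F, J, C, Cbar, Ebar, lam_f (fiber stretch).
        Raises on inverted elements (det F <= 0) for real input.
        """
        ue = u.reshape(self.n_nodes, 3)[self.mesh.tets]  # (E,4,3)
        F = np.eye(3) + np.einsum("eai,eaj->eij", ue, self.grads)
        J = det3(F)
        if not np.iscomplexobj(u) and (J.real <= 0).any():
            bad = int(np.argmin(J.real))
            raise FloatingPointError(f"inverted element {bad} (J = {J[bad]:.3e})")
        C = np.einsum("eki,ekj->eij", F, F)
        Jm23 = J ** (-2.0 / 3.0) if np.iscomplexobj(u) else J ** (-2.0 / 3.0)
        Cbar = Jm23[:, None, None] * C
        Ebar = 0.5 * (Cbar - np.eye(3))
        f0 = self.basis[:, :, 0]
        lam = np.sqrt(np.einsum("ei,eij,ej->e", f0, C, f0))
        return {"F": F, "J": J, "C": C, "Cbar": Cbar, "Ebar": Ebar, "lam_f": lam}

    # -- element kernels (complex-safe) --------------------------------------
    def _element_forces(self, ue, t: float | None):
        """Internal nodal forces per element, (..., E, 4, 3).

        ``ue`` may be complex and may carry extra leading batch axes (used
        for the batched complex-step tangent).
        """
        F = np.eye(3) + np.swapaxes(ue, -1, -2) @ self.grads
        C = np.swapaxes(F, -1, -2) @ F
        S = passive_stress(C, self.basis, self.passive, clamp=not np.iscomplexobj(ue))
        if self.activation is not None and t is not None:
            f0 = self.basis[:, :, 0]
            s0 = self.basis[:, :, 1]
            lam = np.sqrt(((C @ f0[:, :, None])[..., 0] * f0).sum(-1))
            unit = ActiveStressParams(
                s_peak=1.0, t_dur=self.active.t_dur, tau_c0=self.active.tau_c0,
                tau_r=self.active.tau_r, ld=self.active.ld,
                ld_up=self.active.ld_up, lam0=self.active.lam0,
                t_emd=self.active.t_emd,
            )
            sa = self.s_peak_elem * active_stress_scalar(t, self.activation, lam, unit)
            S = S + active_stress_tensor(sa, C, f0, s0)
        P = F @ S
        return self.vols[:, None, None] * (self.grads @ np.swapaxes(P, -1, -2))

    def _tri_forces(self, xe, p: float):
        """Follower pressure nodal forces on cavity triangles, (T, 3, 3).

        Triangles are oriented outward w.r.t. the blood pool, so the force
        on the wall is +p * (area vector)/3 per node; equals the exact
        surface integral of -p J F^-T n0 over each reference triangle.
        """
        cr = 0.5 * np.cross(xe[:, 1] - xe[:, 0], xe[:, 2] - xe[:, 0])
        return np.broadcast_to((p / 3.0) * cr[:, None, :], xe.shape).copy()

    # -- residual and tangent -------------------------------------------------
    def static_residual(self, u: np.ndarray, pressures: dict[str, float] | None = None,
                        t: float | None = None) -> np.ndarray:
        """R(u) = F_int(u) - F_ext(p); flat (3N,) array (mN)."""
        un = u.reshape(self.n_nodes, 3)
        R = np.zeros_like(un, dtype=u.dtype)
        fe = self._element_forces(un[self.mesh.tets], t)
        np.add.at(R, self.mesh.tets, fe)
        # springs
        R += self.k_base_node[:, None] * un
        R += (self.k_epi_node * np.einsum("ni,ni->n", un, self.epi_normal))[
            :, None
        ] * self.epi_normal
        # follower loads
        pressures = pressures or {}
        for c, p in pressures.items():
            tris = self.load_tris[c]
            xe = (self.mesh.nodes[tris] + un[tris])
            ft = self._tri_forces(xe, p)
            np.subtract.at(R, tris, ft)
        return R.reshape(-1)

    def assemble(self, u: np.ndarray, pressures: dict[str, float] | None = None,
                 t: float | None = None):
        """Residual and consistent tangent of the static part.

        Returns (R, K) with K in CSR.  The tangent is assembled from
        element-level complex-step derivatives of the same kernels that
        build R, so it is consistent by construction.
        """
        R = self.static_residual(u, pressures, t)
        un = u.reshape(self.n_nodes, 3)

        # all 12 element dofs perturbed at once in a broadcast batch axis
        E = len(self.mesh.tets)
        ue = np.repeat(un[self.mesh.tets][None].astype(complex), 12, axis=0)
        for dof in range(12):
            a, i = divmod(dof, 3)
            ue[dof, :, a, i] += 1j * _CSTEP
        fe = self._element_forces(ue, t)  # (12, E, 4, 3)
        Ke = (fe.imag / _CSTEP).reshape(12, E, 12).transpose(1, 2, 0)
        data = [np.ascontiguousarray(Ke).reshape(-1)]
        rows = [self._elem_rows]
        cols = [self._elem_cols]

        pressures = pressures or {}
        for c, p in pressures.items():
            if p == 0.0:
                continue
            tris = self.load_tris[c]
            tdofs, trows, tcols = self._tri_idx[c]
            xe = (self.mesh.nodes[tris] + un[tris]).astype(complex)
            T = len(tris)
            Kt = np.empty((T, 9, 9))
            for dof in range(9):
                a, i = divmod(dof, 3)
                xe[:, a, i] += 1j * _CSTEP
                ft = self._tri_forces(xe, p)
                Kt[:, :, dof] = -ft.imag.reshape(T, 9) / _CSTEP
                xe[:, a, i] -= 1j * _CSTEP
            data.append(Kt.reshape(-1))
            rows.append(trows)
            cols.append(tcols)

        # spring tangents (linear)
        diag_dofs = 3 * np.arange(self.n_nodes)[:, None] + np.arange(3)
        kb = np.repeat(self.k_base_node, 3)
        data.append(kb)
        rows.append(diag_dofs.reshape(-1))
        cols.append(diag_dofs.reshape(-1))
        ke_blocks = (
            self.k_epi_node[:, None, None]
            * self.epi_normal[:, :, None]
            * self.epi_normal[:, None, :]
        )
        data.append(ke_blocks.reshape(-1))
        rows.append(np.repeat(diag_dofs, 3, axis=1).reshape(-1))
        cols.append(np.tile(diag_dofs, (1, 3)).reshape(-1))

        K = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, self.ndof),
        ).tocsc()
        return R, K

    def pressure_load_vector(self, u: np.ndarray, cavity: str) -> np.ndarray:
        """dR/dp for one cavity: minus the follower load at unit pressure."""
        un = u.reshape(self.n_nodes, 3)
        tris = self.load_tris[cavity]
        xe = self.mesh.nodes[tris] + un[tris]
        ft = self._tri_forces(xe, 1.0)
        out = np.zeros_like(un)
        np.subtract.at(out, tris, ft)
        return out.reshape(-1)

    # -- cavity volumes -------------------------------------------------------
    def cavity_volume(self, u: np.ndarray, cavity: str) -> float:
        """Deformed cavity volume in mL (divergence theorem on endo+lid)."""
        x = self.mesh.nodes + u.reshape(self.n_nodes, 3)
        return enclosed_volume(x, self.cavity_tris[cavity]) / 1000.0

    def cavity_volume_gradient(self, u: np.ndarray, cavity: str) -> np.ndarray:
        """dV/du (mL per mm), flat (3N,)."""
        x = self.mesh.nodes + u.reshape(self.n_nodes, 3)
        return enclosed_volume_gradient(x, self.cavity_tris[cavity]).reshape(-1) / 1000.0

    # -- reference stiffness (damping) ----------------------------------------
    def reference_stiffness(self) -> sp.csc_matrix:
        if self._K0 is None:
            act, self.activation = self.activation, None
            try:
                _, self._K0 = self.assemble(np.zeros(self.ndof))
            finally:
                self.activation = act
        return self._K0

    # -- static solves --------------------------------------------------------
    def solve_static(self, pressures: dict[str, float], u0: np.ndarray | None = None,
                     n_load_steps: int = 32, tol: float = 1e-8,
                     max_iter: int = 30, t: float | None = None) -> np.ndarray:
        """Quasi-static inflation by incremental Newton continuation.

        Pressures are ramped in ``n_load_steps`` equal increments from zero
        (or from the state implied by ``u0``); each step converges the
        relative residual below ``tol``.
        """
        u = np.zeros(self.ndof) if u0 is None else u0.copy()
        for step in range(1, n_load_steps + 1):
            frac = step / n_load_steps
            p_step = {c: frac * p for c, p in pressures.items()}
            u = self._newton(u, p_step, tol, max_iter, t)
        return u

    def _newton(self, u, pressures, tol, max_iter, t=None):
        R, K = self.assemble(u, pressures, t)
        r0 = np.linalg.norm(R)
        scale = max(r0, 1e-12)
        for it in range(max_iter):
            nr = np.linalg.norm(R)
            if nr / scale < tol or nr < 1e-9:
                return u
            du = spla.spsolve(K, -R)
            # backtracking line search on the residual norm
            alpha = 1.0
            accepted = False
            for _ in range(10):
                try:
                    R_new = self.static_residual(u + alpha * du, pressures, t)
                except FloatingPointError:
                    alpha *= 0.5
                    continue
                if np.linalg.norm(R_new) < np.linalg.norm(R):
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                raise RuntimeError(
                    "static Newton line search failed; load increment too "
                    "large for the current state"
                )
            u = u + alpha * du
            R, K = self.assemble(u, pressures, t)
        raise RuntimeError(
            f"static Newton did not converge (|R| = {np.linalg.norm(R):.3e} "
            f"after {max_iter} iterations)"
        )


def unload_backward_displacement(
    mesh: Mesh,
    p_ed: dict[str, float],
    passive: PassiveMaterialParams | None = None,
    bcs: BoundaryConditionSet | None = None,
    tol: float = 0.1,
    max_iter: int = 20,
    n_load_steps: int = 8,
) -> Mesh:
    """Estimate the unloaded reference mesh by backward displacement.

    Fixed point: given the imaged (loaded) geometry and the end-diastolic
    pressures ``p_ed`` (kPa per cavity), iterate
    ``X_ref <- X_image - u(inflate(X_ref, p_ed))`` until the reinflated
    reference matches the image within ``tol`` mm.
    """
    if all(p == 0.0 for p in p_ed.values()):
        return mesh
    x_image = mesh.nodes.copy()
    ref = Mesh(mesh.nodes.copy(), mesh.tets, mesh.elem_region, mesh.surfaces, mesh.fibers)
    prev_mismatch = np.inf
    grow_count = 0
    for it in range(max_iter):
        model = MechanicsModel(ref, passive=passive, bcs=bcs)
        u = model.solve_static(p_ed, n_load_steps=n_load_steps)
        x_inflated = ref.nodes + u.reshape(-1, 3)
        mismatch = np.linalg.norm(x_inflated - x_image, axis=1).max()
        logger.info("backward displacement iter %d: mismatch %.4f mm", it, mismatch)
        if mismatch < tol:
            return ref
        grow_count = grow_count + 1 if mismatch > prev_mismatch else 0
        if grow_count >= 3:
            raise RuntimeError(
                "backward-displacement iteration diverging; "
                "consider ramping the end-diastolic load"
            )
        prev_mismatch = mismatch
        ref = Mesh(
            ref.nodes - (x_inflated - x_image), mesh.tets, mesh.elem_region,
            mesh.surfaces, mesh.fibers,
        )
    raise RuntimeError(f"backward displacement: no convergence in {max_iter} iterations")


class GeneralizedAlphaStepper:
    """Implicit generalized-alpha time stepping for the mechanics model.

    With spectral radius rho_inf = 0 the scheme annihilates the highest
    frequency in one step (alpha_m = -1, alpha_f = 0, beta = 1,
    gamma = 3/2).  Rayleigh damping C = beta_mass M + beta_stiff K0 uses
    the reference-configuration stiffness.
    """

    def __init__(self, model: MechanicsModel, params: GeneralizedAlphaParams | None = None):
        self.model = model
        self.p = params or GeneralizedAlphaParams()
        n = model.n_nodes
        self.M = sp.diags(np.repeat(model.mass, 3)).tocsc()
        K0 = model.reference_stiffness()
        self.C = (self.p.beta_mass * self.M + self.p.beta_stiff * K0).tocsc()

    def _newmark(self, state: MechState, u_new: np.ndarray, dt: float):
        b, g = self.p.beta, self.p.gamma
        un, vn, an = state.u.reshape(-1), state.v.reshape(-1), state.a.reshape(-1)
        a_new = (u_new - un - dt * vn) / (b * dt * dt) - (0.5 / b - 1.0) * an
        v_new = vn + dt * ((1.0 - g) * an + g * a_new)
        return v_new, a_new

    def residual_and_tangent(self, state: MechState, u_new: np.ndarray,
                             pressures: dict[str, float], dt: float,
                             with_tangent: bool = True):
        """Generalized-alpha residual R_alpha(u_new) and its tangent."""
        am, af, b, g = self.p.alpha_m, self.p.alpha_f, self.p.beta, self.p.gamma
        t_new = state.t + dt
        v_new, a_new = self._newmark(state, u_new, dt)
        vn, an = state.v.reshape(-1), state.a.reshape(-1)
        a_mid = (1.0 - am) * a_new + am * an
        v_mid = (1.0 - af) * v_new + af * vn
        if with_tangent:
            Rs, Ks = self.model.assemble(u_new, pressures, t_new)
        else:
            Rs = self.model.static_residual(u_new, pressures, t_new)
            Ks = None
        R = self.M @ a_mid + self.C @ v_mid + (1.0 - af) * Rs
        if af != 0.0:
            R = R + af * self.model.static_residual(
                state.u.reshape(-1), self._prev_pressures, state.t
            )
        if not with_tangent:
            return R, None
        K = (
            ((1.0 - am) / (b * dt * dt)) * self.M
            + ((1.0 - af) * g / (b * dt)) * self.C
            + (1.0 - af) * Ks
        ).tocsc()
        return R, K

    _prev_pressures: dict[str, float] = {}

    def commit(self, state: MechState, u_new: np.ndarray, dt: float,
               pressures: dict[str, float]) -> MechState:
        v_new, a_new = self._newmark(state, u_new, dt)
        self._prev_pressures = dict(pressures)
        n = self.model.n_nodes
        return MechState(
            u_new.reshape(n, 3).copy(), v_new.reshape(n, 3).copy(),
            a_new.reshape(n, 3).copy(), state.t + dt,
        )
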