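"""Idealized ventricular geometry fixtures.

Generates truncated prolate-ellipsoid ventricular shells meshed with a
structured hexahedral grid split into conforming tetrahedra (Kuhn split),
with labeled endocardial / epicardial / basal surfaces and flat triangulated
lids closing each cavity at the base plane.  Also provides harmonic
(Laplace) transmural and apicobasal coordinates and the rule-based fiber
architecture with a linear transmural helix-angle profile (+60 deg at the
endocardium to -60 deg at the epicardium by default).

The biventricular variant adds the right ventricle as a second, thinner
truncated-ellipsoid shell placed beside the left one.  Ventricular
interaction through a shared deformable septum is represented in the lumped
circulation (TriSeg), not in the 3D fixture.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .fem import laplace_solve, shape_gradients
from .mesh import FiberField, Mesh, tet_volumes

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryParams",
    "VentricularCoordinates",
    "generate_idealized_ventricles",
    "compute_ventricular_coordinates",
    "assign_fibers_rule_based",
    "helix_angles",
    "truncated_ellipsoid_shell_volumes",
]


@dataclass
class GeometryParams:
    """Geometry of one truncated prolate-ellipsoid shell.

    ``short_axis`` and ``long_axis`` are the *endocardial* semi-axes (mm);
    the wall is uniformly ``thickness`` mm thick; the base plane sits at
    z = ``base_truncation`` * ``long_axis`` above the ellipsoid center
    (apex at z = -``long_axis``).
    """

    thickness: float = 10.0
    long_axis: float = 32.0
    short_axis: float = 15.0
    base_truncation: float = 0.25
    edge_length: float = 3.4
    biventricular: bool = False
    # RV shell used when biventricular is set
    rv_thickness: float = 4.0
    rv_long_axis: float = 28.0
    rv_short_axis: float = 12.0

    def validate(self) -> None:
        if self.edge_length <= 0:
            raise ValueError("edge_length must be positive")
        if self.thickness >= self.short_axis:
            raise ValueError(
                "degenerate geometry: thickness "
                f"{self.thickness} mm >= endocardial radius {self.short_axis} mm"
            )
        if not 0.0 <= self.base_truncation < 1.0:
            raise ValueError("base_truncation must lie in [0, 1)")
        if self.biventricular and self.rv_thickness >= self.rv_short_axis:
            raise ValueError("degenerate RV geometry: thickness >= radius")


@dataclass
class VentricularCoordinates:
    """Harmonic ventricular coordinates per node, each in [0, 1].

    ``transmural`` is 0 on the endocardium and 1 on the epicardium;
    ``apicobasal`` is 0 at the apex and 1 on the basal cut plane.
    """

    transmural: np.ndarray
    apicobasal: np.ndarray


# -- structured shell meshing ----------------------------------------------

_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _shell_grid(a_endo, c_endo, h, z_base, edge):
    """Node array + index maps for one structured ellipsoidal shell."""
    a_mid = a_endo + 0.5 * h
    c_mid = c_endo + 0.5 * h
    u_base_mid = math.acos(max(-1.0, min(1.0, -z_base / c_mid)))
    meridian = u_base_mid * math.sqrt(0.5 * (a_mid**2 + c_mid**2))
    n_u = max(3, int(round(meridian / edge)))
    n_phi = max(8, int(round(2 * math.pi * a_mid / edge)))
    n_k = max(2, int(round(h / edge)))

    per_shell = 1 + n_u * n_phi
    nodes = np.zeros(((n_k + 1) * per_shell, 3))
    for k in range(n_k + 1):
        xi = k / n_k
        a = a_endo + xi * h
        c = c_endo + xi * h
        u_base = math.acos(max(-1.0, min(1.0, -z_base / c)))
        base = k * per_shell
        nodes[base] = (0.0, 0.0, -c)  # apex pole
        u = u_base * np.arange(1, n_u + 1) / n_u
        phi = 2 * math.pi * np.arange(n_phi) / n_phi
        uu, pp = np.meshgrid(u, phi, indexing="ij")
        pts = np.stack(
            [a * np.sin(uu) * np.cos(pp), a * np.sin(uu) * np.sin(pp), -c * np.cos(uu)],
            axis=-1,
        )
        nodes[base + 1 : base + per_shell] = pts.reshape(-1, 3)

    def idx(k, i, j):
        # i = 0 is the apex pole (j ignored); i in 1..n_u rings, j modulo n_phi
        if i == 0:
            return k * per_shell
        return k * per_shell + 1 + (i - 1) * n_phi + (j % n_phi)

    return nodes, idx, n_u, n_phi, n_k


def _kuhn_tets(idx, n_u, n_phi, n_k):
    """Conforming tetrahedralization of the structured shell grid."""
    tets = []
    for k in range(n_k):
        for i in range(n_u):
            for j in range(n_phi):
                # hex corner lookup in local (du, dphi, dk)
                def corner(d):
                    return idx(k + d[2], i + d[0], j + d[1])

                for perm in _KUHN_PERMS:
                    d = [0, 0, 0]
                    tet = [corner(d)]
                    for axis in perm:
                        d[axis] += 1
                        tet.append(corner(list(d)))
                    if len(set(tet)) == 4:  # drop apex-collapsed degenerates
                        tets.append(tet)
    return np.asarray(tets, dtype=np.int64)


def _orient_tets(nodes, tets):
    vol = tet_volumes(nodes, tets)
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    vol = tet_volumes(nodes, tets)
    if (vol <= 1e-12).any():
        raise RuntimeError("degenerate tetrahedra after orientation fix")
    return tets


def _boundary_faces(tets):
    """Boundary faces oriented outward with respect to the solid."""
    # local faces of tet (0,1,2,3), outward for positive orientation
    local = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
    faces = tets[:, local].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def _classify_shell_surfaces(nodes, faces, n_per_shell, n_k, z_base):
    """Split boundary faces into endo (inner shell), epi (outer), base."""
    shell_of = faces // n_per_shell
    on_endo = (shell_of == 0).all(axis=1)
    on_epi = (shell_of == n_k).all(axis=1)
    z = nodes[faces, 2]
    on_base = np.isclose(z, z_base, atol=1e-9).all(axis=1)
    endo = faces[on_endo & ~on_base]
    epi = faces[on_epi & ~on_base]
    base = faces[on_base]
    leftover = faces[~(on_endo & ~on_base) & ~(on_epi & ~on_base) & ~on_base]
    if len(leftover):
        raise RuntimeError(f"{len(leftover)} boundary faces left unclassified")
    return endo, epi, base


def _lid(idx, n_u, n_phi):
    """Flat fan triangulation of the endocardial base ring, normal +z."""
    ring = [idx(0, n_u, j) for j in range(n_phi)]
    return np.asarray(
        [[ring[0], ring[j], ring[j + 1]] for j in range(1, n_phi - 1)], dtype=np.int64
    )


def _build_shell(params: GeometryParams, rv: bool, x_offset: float):
    if rv:
        a, c, h = params.rv_short_axis, params.rv_long_axis, params.rv_thickness
    else:
        a, c, h = params.short_axis, params.long_axis, params.thickness
    z_base = params.base_truncation * params.long_axis  # shared base plane
    nodes, idx, n_u, n_phi, n_k = _shell_grid(a, c, h, z_base, params.edge_length)
    nodes[:, 0] += x_offset
    tets = _orient_tets(nodes, _kuhn_tets(idx, n_u, n_phi, n_k))
    per_shell = 1 + n_u * n_phi
    faces = _boundary_faces(tets)
    endo, epi, base = _classify_shell_surfaces(nodes, faces, per_shell, n_k, z_base)
    # cavity surface orientation: outward of the blood pool = flip endo faces
    endo_cav = endo[:, [0, 2, 1]]
    lid = _lid(idx, n_u, n_phi)
    return nodes, tets, endo_cav, epi, base, lid


def generate_idealized_ventricles(params: GeometryParams | None = None, **kw) -> Mesh:
    """Generate the idealized LV (or biventricular) tetrahedral fixture.

    Deterministic: identical parameters produce bitwise-identical meshes.
    The transmural element-layer count is ``max(2, round(thickness/edge))``,
    so at least two element layers are generated across the wall whenever
    the target edge length does not exceed half the wall thickness (and, by
    the floor of 2, in every generated fixture).
    """
    if params is None:
        params = GeometryParams(**kw)
    elif kw:
        raise TypeError("pass either GeometryParams or keyword overrides, not both")
    params.validate()

    nodes, tets, endo, epi, base, lid = _build_shell(params, rv=False, x_offset=0.0)
    surfaces = {"endo_lv": endo, "epi": epi, "base": base, "lid_lv": lid}
    regions = np.ones(len(tets), dtype=np.int64)

    if params.biventricular:
        gap = 2.0
        off = (
            params.short_axis + params.thickness
            + params.rv_short_axis + params.rv_thickness + gap
        )
        rn, rt, rendo, repi, rbase, rlid = _build_shell(params, rv=True, x_offset=off)
        shift = len(nodes)
        nodes = np.vstack([nodes, rn])
        tets = np.vstack([tets, rt + shift])
        regions = np.concatenate([regions, np.full(len(rt), 6, dtype=np.int64)])
        surfaces["endo_rv"] = rendo + shift
        surfaces["lid_rv"] = rlid + shift
        surfaces["epi"] = np.vstack([surfaces["epi"], repi + shift])
        surfaces["base"] = np.vstack([surfaces["base"], rbase + shift])

    mesh = Mesh(nodes, tets, regions, surfaces)
    mesh.check()
    return mesh


# -- analytic reference volume ---------------------------------------------

def truncated_ellipsoid_shell_volumes(params: GeometryParams) -> dict[str, float]:
    """Closed-form cavity and wall volumes of the truncated ellipsoid (mm^3).

    The cavity is the endocardial ellipsoid below the base plane
    z_b = f * c_endo:  V = pi a^2 c (2/3 + t - t^3/3) with t = z_b / c.
    """

    def cap(a, c, z_b):
        t = min(1.0, z_b / c)
        return math.pi * a**2 * c * (2.0 / 3.0 + t - t**3 / 3.0)

    a, c, h = params.short_axis, params.long_axis, params.thickness
    z_b = params.base_truncation * c
    v_endo = cap(a, c, z_b)
    v_epi = cap(a + h, c + h, z_b)
    return {"cavity": v_endo, "wall": v_epi - v_endo, "epi_total": v_epi}


# -- coordinates ------------------------------------------------------------

def compute_ventricular_coordinates(mesh: Mesh) -> VentricularCoordinates:
    """Harmonic transmural and apicobasal coordinates via Laplace solves.

    Transmural: 0 on the endocardium (all cavities), 1 on the epicardium.
    Apicobasal: 0 at the apex point set (lowest node per connected region),
    1 on the basal cut plane.
    """
    for label in ("epi", "base"):
        if label not in mesh.surfaces:
            raise KeyError(f"mesh is missing required surface label {label!r}")
    endo_labels = [s for s in mesh.surfaces if s.startswith("endo_")]
    if not endo_labels:
        raise KeyError("mesh is missing required surface label 'endo_*'")

    endo_nodes = np.unique(np.concatenate([mesh.surfaces[s].ravel() for s in endo_labels]))
    epi_nodes = np.unique(mesh.surfaces["epi"].ravel())
    base_nodes = np.unique(mesh.surfaces["base"].ravel())

    dir_tm = {int(i): 0.0 for i in endo_nodes}
    dir_tm.update({int(i): 1.0 for i in epi_nodes})
    transmural = laplace_solve(mesh.nodes, mesh.tets, dir_tm)

    # apex point set: per region, nodes within a small band of the minimum z
    apex_nodes = []
    for reg in np.unique(mesh.elem_region):
        reg_nodes = np.unique(mesh.tets[mesh.elem_region == reg].ravel())
        z = mesh.nodes[reg_nodes, 2]
        apex_nodes.append(reg_nodes[z <= z.min() + 1e-9])
    apex_nodes = np.unique(np.concatenate(apex_nodes))
    dir_ab = {int(i): 0.0 for i in apex_nodes}
    dir_ab.update({int(i): 1.0 for i in base_nodes})
    apicobasal = laplace_solve(mesh.nodes, mesh.tets, dir_ab)
    return VentricularCoordinates(transmural=transmural, apicobasal=apicobasal)


# -- rule-based fibers -------------------------------------------------------

def _local_frames(mesh: Mesh, coords: VentricularCoordinates):
    """Per-element (circumferential, apicobasal, transmural) unit frame.

    The transmural direction is the gradient of the transmural coordinate;
    the circumferential direction is long-axis x transmural.  Where that
    cross product degenerates (apex cap), the x-axis projected into the
    plane normal to the transmural direction is used instead (deterministic
    tie-break), and the fallback is logged.
    """
    grads, _ = shape_gradients(mesh.nodes, mesh.tets)
    g = np.einsum("eai,ea->ei", grads, coords.transmural[mesh.tets])
    gn = np.linalg.norm(g, axis=1)
    gn[gn == 0] = 1.0
    et = g / gn[:, None]

    zhat = np.array([0.0, 0.0, 1.0])
    c = np.cross(np.broadcast_to(zhat, et.shape), et)
    cn = np.linalg.norm(c, axis=1)
    degenerate = cn < 1e-8
    if degenerate.any():
        logger.info(
            "circumferential direction undefined for %d apex elements; "
            "falling back to projected x-axis",
            int(degenerate.sum()),
        )
        xhat = np.array([1.0, 0.0, 0.0])
        proj = xhat - np.einsum("ei,i->e", et[degenerate], xhat)[:, None] * et[degenerate]
        c[degenerate] = proj
        cn[degenerate] = np.linalg.norm(proj, axis=1)
    chat = c / cn[:, None]
    lhat = np.cross(et, chat)  # apex-to-base tangential direction
    return chat, lhat, et


def assign_fibers_rule_based(
    mesh: Mesh,
    coords: VentricularCoordinates,
    angle_endo: float = 60.0,
    angle_epi: float = -60.0,
) -> FiberField:
    """Rule-based fiber triads with linear transmural helix-angle profile.

    The helix angle (of f0 against the local circumferential direction,
    measured in the local tangent plane) interpolates linearly from
    ``angle_endo`` at transmural coordinate 0 to ``angle_epi`` at 1.
    The sheet direction s0 is transmural and n0 completes the right-handed
    triad.
    """
    chat, lhat, et = _local_frames(mesh, coords)
    xi = coords.transmural[mesh.tets].mean(axis=1)
    alpha = np.deg2rad(angle_endo + (angle_epi - angle_endo) * xi)
    f0 = np.cos(alpha)[:, None] * chat + np.sin(alpha)[:, None] * lhat
    # s0: transmural direction, re-orthogonalized against f0
    s0 = et - np.einsum("ei,ei->e", et, f0)[:, None] * f0
    s0 /= np.linalg.norm(s0, axis=1)[:, None]
    n0 = np.cross(f0, s0)
    field = FiberField(f0, s0, n0)
    field.check(tol=1e-10)
    return field


def helix_angles(mesh: Mesh, coords: VentricularCoordinates, fibers: FiberField) -> np.ndarray:
    """Measured per-element helix angle of f0 (degrees).

    Angle of f0 against the local circumferential direction, in the local
    tangent plane spanned by (circumferential, apicobasal) directions.
    """
    chat, lhat, _ = _local_frames(mesh, coords)
    return np.rad2deg(
        np.arctan2(
            np.einsum("ei,ei->e", fibers.f0, lhat),
            np.einsum("ei,ei->e", fibers.f0, chat),
        )
    )
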