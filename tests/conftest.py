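"""Shared fixtures: analytic meshes (rod, cube, icosphere, spherical shell),
the coarse idealized ventricle, and the session-cached coupled run."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cardioloop.geometry import (
    GeometryParams,
    _kuhn_tets,
    assign_fibers_rule_based,
    compute_ventricular_coordinates,
    generate_idealized_ventricles,
)
from cardioloop.mesh import FiberField, Mesh, tet_volumes

# ---------------------------------------------------------------- structured


def structured_box_mesh(nx, ny, nz, lx, ly, lz):
    """Box [0,lx]x[0,ly]x[0,lz] split into conforming tets."""
    nodes = np.array(
        [(i * lx / nx, j * ly / ny, k * lz / nz)
         for i in range(nx + 1) for j in range(ny + 1) for k in range(nz + 1)],
        dtype=float,
    )

    def idx(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                def corner(d):
                    return idx(i + d[0], j + d[1], k + d[2])

                for perm in perms:
                    d = [0, 0, 0]
                    tet = [corner(d)]
                    for ax in perm:
                        d[ax] += 1
                        tet.append(corner(d))
                    tets.append(tet)
    tets = np.asarray(tets)
    v = tet_volumes(nodes, tets)
    tets[v < 0] = tets[v < 0][:, [0, 1, 3, 2]]
    return Mesh(nodes, tets, np.ones(len(tets), dtype=np.int64), {})


def axis_fibers(n_elem, f_axis=(1.0, 0.0, 0.0), s_axis=(0.0, 1.0, 0.0)):
    f0 = np.tile(np.asarray(f_axis, float), (n_elem, 1))
    s0 = np.tile(np.asarray(s_axis, float), (n_elem, 1))
    n0 = np.cross(f0, s0)
    return FiberField(f0, s0, n0)


@pytest.fixture(scope="session")
def rod_mesh():
    """1-element-wide rod along x, 20 mm long, 1 mm cross-section."""
    return structured_box_mesh(20, 1, 1, 20.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def cube_mesh():
    return structured_box_mesh(8, 8, 8, 20.0, 20.0, 20.0)


def icosphere(radius=10.0, subdivisions=3):
    """Triangulated sphere: icosahedron with ``subdivisions`` refinements.

    Returns (nodes, tris) with outward orientation; 20 * 4^n faces.
    """
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array([
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array([
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ])
    verts = list(map(tuple, verts))
    for _ in range(subdivisions):
        cache = {}
        new_faces = []

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = np.asarray(verts[a]) + np.asarray(verts[b])
                m /= np.linalg.norm(m)
                verts.append(tuple(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = np.asarray(new_faces)
    nodes = radius * np.asarray(verts)
    return nodes, faces


def spherical_shell_mesh(r_in=10.0, r_out=15.0, edge=2.5):
    """Closed thick spherical shell with labeled inner/outer surfaces."""
    r_mid = 0.5 * (r_in + r_out)
    n_u = max(6, int(round(math.pi * r_mid / edge)))
    n_phi = max(8, int(round(2 * math.pi * r_mid / edge)))
    n_k = max(2, int(round((r_out - r_in) / edge)))
    per_shell = 2 + (n_u - 1) * n_phi
    nodes = np.zeros(((n_k + 1) * per_shell, 3))
    for k in range(n_k + 1):
        r = r_in + (r_out - r_in) * k / n_k
        base = k * per_shell
        nodes[base] = (0, 0, -r)
        nodes[base + per_shell - 1] = (0, 0, r)
        row = base + 1
        for i in range(1, n_u):
            th = math.pi * i / n_u
            for j in range(n_phi):
                ph = 2 * math.pi * j / n_phi
                nodes[row] = (r * math.sin(th) * math.cos(ph),
                              r * math.sin(th) * math.sin(ph),
                              -r * math.cos(th))
                row += 1

    def idx(k, i, j):
        if i == 0:
            return k * per_shell
        if i == n_u:
            return k * per_shell + per_shell - 1
        return k * per_shell + 1 + (i - 1) * n_phi + (j % n_phi)

    tets = _kuhn_tets(idx, n_u, n_phi, n_k)
    v = tet_volumes(nodes, tets)
    tets[v < 0] = tets[v < 0][:, [0, 1, 3, 2]]
    from cardioloop.geometry import _boundary_faces

    faces = _boundary_faces(tets)
    shell_of = faces // per_shell
    inner = faces[(shell_of == 0).all(axis=1)]
    outer = faces[(shell_of == n_k).all(axis=1)]
    mesh = Mesh(
        nodes, tets, np.ones(len(tets), dtype=np.int64),
        {"endo_lv": inner[:, [0, 2, 1]],  # outward w.r.t. the cavity
         "lid_lv": np.empty((0, 3), dtype=np.int64),
         "epi": outer,
         "base": outer},  # omni springs on the outer surface (gauge fixing)
    )
    # radial/tangential triads
    cen = nodes[tets].mean(axis=1)
    rhat = cen / np.linalg.norm(cen, axis=1)[:, None]
    zxr = np.cross(np.array([0.0, 0.0, 1.0]), rhat)
    bad = np.linalg.norm(zxr, axis=1) < 1e-8
    zxr[bad] = np.cross(np.array([1.0, 0.0, 0.0]), rhat[bad])
    f0 = zxr / np.linalg.norm(zxr, axis=1)[:, None]
    s0 = rhat - np.einsum("ei,ei->e", rhat, f0)[:, None] * f0
    s0 /= np.linalg.norm(s0, axis=1)[:, None]
    mesh.fibers = FiberField(f0, s0, np.cross(f0, s0))
    return mesh


def two_tet_mesh():
    """Two tets sharing a face; the smallest nontrivial assembly fixture."""
    nodes = np.array([
        (0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0), (1.0, 1.0, 1.0),
    ])
    tets = np.array([(0, 1, 2, 3), (1, 2, 3, 4)])
    v = tet_volumes(nodes, tets)
    tets[v < 0] = tets[v < 0][:, [0, 1, 3, 2]]
    # basal springs on the z = 0 face suppress rigid-body modes
    return Mesh(nodes, tets, np.ones(2, dtype=np.int64),
                {"base": np.array([[0, 2, 1]])})


# ------------------------------------------------------------ LV fixtures


@pytest.fixture(scope="session")
def coarse_lv():
    """Coarse preset LV (3.4 mm edge) with coordinates and fibers."""
    mesh = generate_idealized_ventricles(GeometryParams(edge_length=3.4))
    coords = compute_ventricular_coordinates(mesh)
    mesh.fibers = assign_fibers_rule_based(mesh, coords)
    return mesh, coords


@pytest.fixture(scope="session")
def small_lv():
    """Small LV for mechanics tests (about 1k tets)."""
    mesh = generate_idealized_ventricles(GeometryParams(edge_length=9.0))
    coords = compute_ventricular_coordinates(mesh)
    mesh.fibers = assign_fibers_rule_based(mesh, coords)
    return mesh, coords


# ------------------------------------------------------------ 0D baseline


@pytest.fixture(scope="session")
def baseline_0d():
    """Baseline 0D limit cycle shared by protocol tests."""
    from cardioloop.circulation import CircParams, run_standalone_to_limit_cycle

    params = CircParams()
    state, record, info = run_standalone_to_limit_cycle(
        params, n_max_beats=20, record_last=1)
    return {"params": params, "state": state, "record": record, "info": info}


# ------------------------------------------------------------ coupled run


@pytest.fixture(scope="session")
def coupled_run():
    """One staged coupled run, cached for the whole session.

    Staging: 0D warmup, 32-step inflation, one semi-implicit stabilization
    beat, then the SAME beat simulated twice from a snapshot: once with the
    fully converging Newton (k_max 20, eps 1e-6) and once semi-implicitly
    (one iteration per step).  Several tests assert on different aspects of
    this single simulation: per-step constraint satisfaction, isovolumetric
    behavior, interface flow balance and semi-implicit versus fully
    implicit agreement.
    """
    from cardioloop.coupling import run_heartbeat
    from cardioloop.simulate import CoupledRunConfig, build_coupled_system

    cfg = CoupledRunConfig(warmup_beats=8)
    system, info = build_coupled_system(cfg)
    rec_warm, dg_warm = run_heartbeat(system, mode="semi_implicit")
    snap = system.snapshot()
    rec_full, dg_full = run_heartbeat(system, mode="full_newton")
    system.restore(snap)
    rec_semi, dg_semi = run_heartbeat(system, mode="semi_implicit")
    return {
        "cfg": cfg, "system": system, "info": info,
        "warm": (rec_warm, dg_warm),
        "full": (rec_full, dg_full),
        "semi": (rec_semi, dg_semi),
    }
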