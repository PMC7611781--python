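"""Labeled tetrahedral meshes, closed cavity surfaces, and mesh I/O.

A :class:`Mesh` holds a tetrahedral volume discretization of the ventricular
myocardium together with labeled boundary triangulations.  Each cavity is
closed by a triangulated membrane ("lid") spanning the basal valve plane, so
that ``endo_lv + lid_lv`` (and analogously for the RV) forms a closed,
consistently outward-oriented surface.  Cavity volumes are evaluated on those
closed surfaces with the divergence theorem, which is the quantity the
3D-0D volume constraint couples on.

Supported formats: a plain-text triplet (``.pts`` nodes, ``.elem`` elements
with region tag, ``.lon`` fiber vectors) with a JSON sidecar for surface
labels, and a minimal ASCII VTU (unstructured grid, tet cells only).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Mesh",
    "FiberField",
    "surface_is_closed",
    "surface_area_vector",
    "enclosed_volume",
    "enclosed_volume_gradient",
    "tet_volumes",
    "read_mesh",
    "write_mesh",
]


@dataclass
class FiberField:
    """Per-element orthonormal fiber/sheet/sheet-normal triads.

    ``f0`` is the myocyte (fiber) direction, ``s0`` the sheet direction,
    ``n0`` the sheet normal; each row triple forms a right-handed orthonormal
    basis.
    """

    f0: np.ndarray  # (M, 3)
    s0: np.ndarray  # (M, 3)
    n0: np.ndarray  # (M, 3)

    def __post_init__(self) -> None:
        self.f0 = np.asarray(self.f0, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.n0 = np.asarray(self.n0, dtype=float)

    def check(self, tol: float = 1e-10) -> None:
        """Raise if any triad is not right-handed orthonormal to ``tol``."""
        for name, v in (("f0", self.f0), ("s0", self.s0), ("n0", self.n0)):
            err = np.abs(np.linalg.norm(v, axis=1) - 1.0).max()
            if err > tol:
                raise ValueError(f"{name} not unit length (max err {err:.2e})")
        for a, b, nm in (
            (self.f0, self.s0, "f0.s0"),
            (self.f0, self.n0, "f0.n0"),
            (self.s0, self.n0, "s0.n0"),
        ):
            err = np.abs(np.einsum("ij,ij->i", a, b)).max()
            if err > tol:
                raise ValueError(f"triad not orthogonal: |{nm}| = {err:.2e}")
        cross = np.cross(self.f0, self.s0)
        err = np.abs(cross - self.n0).max()
        if err > 1e-8:
            raise ValueError(f"triad not right-handed (|f0 x s0 - n0| = {err:.2e})")


@dataclass
class Mesh:
    """Labeled tetrahedral mesh with cavity surfaces.

    Attributes
    ----------
    nodes : (N, 3) float array, positions in mm.
    tets : (M, 4) int array, 0-based node indices, positively oriented.
    elem_region : (M,) int array, region label per tet (1 = LV myocardium,
        6 = RV wall, following the common multilabel convention).
    surfaces : mapping from label to (K, 3) triangle arrays.  Recognized
        labels: ``endo_lv``, ``endo_rv``, ``epi``, ``base``, ``lid_lv``,
        ``lid_rv``.  Cavity surfaces (endo + lid) are oriented outward with
        respect to the enclosed blood pool.
    fibers : optional :class:`FiberField`.
    """

    nodes: np.ndarray
    tets: np.ndarray
    elem_region: np.ndarray
    surfaces: dict[str, np.ndarray] = field(default_factory=dict)
    fibers: FiberField | None = None

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.elem_region = np.asarray(self.elem_region, dtype=np.int64)
        self.surfaces = {k: np.asarray(v, dtype=np.int64) for k, v in self.surfaces.items()}

    # -- cavity plumbing ---------------------------------------------------
    def cavity_labels(self) -> list[str]:
        out = []
        if "endo_lv" in self.surfaces:
            out.append("lv")
        if "endo_rv" in self.surfaces:
            out.append("rv")
        return out

    def cavity_surface(self, cavity: str) -> np.ndarray:
        """Closed triangle list (endo + lid) of ``cavity`` in {'lv','rv'}."""
        cavity = cavity.lower()
        endo = self.surfaces.get(f"endo_{cavity}")
        lid = self.surfaces.get(f"lid_{cavity}")
        if endo is None or lid is None:
            raise KeyError(f"mesh has no closed surface for cavity {cavity!r}")
        return np.vstack([endo, lid])

    def cavity_volume(self, cavity: str, coords: np.ndarray | None = None) -> float:
        """Enclosed cavity volume in mm^3 via the divergence theorem."""
        tris = self.cavity_surface(cavity)
        x = self.nodes if coords is None else coords
        return enclosed_volume(x, tris)

    def check(self) -> None:
        """Validate structural invariants (orientation, closed surfaces)."""
        vol = tet_volumes(self.nodes, self.tets)
        if (vol <= 0).any():
            bad = int(np.argmin(vol))
            raise ValueError(f"tet {bad} not positively oriented (vol {vol[bad]:.3e})")
        for cav in self.cavity_labels():
            tris = self.cavity_surface(cav)
            if not surface_is_closed(tris):
                raise ValueError(f"cavity surface {cav!r} is not edge-closed")
            if enclosed_volume(self.nodes, tris) <= 0:
                raise ValueError(f"cavity surface {cav!r} not outward-oriented")


# -- geometric primitives ---------------------------------------------------

def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tets (positive for right-handed ordering)."""
    p = nodes[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def surface_is_closed(tris: np.ndarray) -> bool:
    """True iff every edge of the triangulation is shared by exactly 2 faces."""
    edges = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool((counts == 2).all())


def surface_area_vector(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Integral of the outward normal over the surface (zero if closed)."""
    p = nodes[tris]
    return 0.5 * np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]).sum(axis=0)


def enclosed_volume(nodes: np.ndarray, tris: np.ndarray) -> float:
    """Volume enclosed by a closed oriented surface, V = (1/3) oint x.n dG.

    Evaluates exactly as V = (1/6) sum_T x1 . (x2 x x3); translation
    invariant when the surface is closed.
    """
    p = nodes[tris]
    return float(np.einsum("ij,ij->", p[:, 0], np.cross(p[:, 1], p[:, 2])) / 6.0)


def enclosed_volume_gradient(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """dV/dx as a dense (N, 3) array (nonzero only on surface nodes)."""
    grad = np.zeros_like(nodes)
    p = nodes[tris]
    g0 = np.cross(p[:, 1], p[:, 2]) / 6.0
    g1 = np.cross(p[:, 2], p[:, 0]) / 6.0
    g2 = np.cross(p[:, 0], p[:, 1]) / 6.0
    np.add.at(grad, tris[:, 0], g0)
    np.add.at(grad, tris[:, 1], g1)
    np.add.at(grad, tris[:, 2], g2)
    return grad


# -- I/O --------------------------------------------------------------------

_SURFACE_SIDECAR = "surfaces.json"


def write_mesh(path: str | Path, mesh: Mesh, fmt: str | None = None) -> None:
    """Write ``mesh`` in the given format.

    ``fmt`` is one of ``"triplet"`` (``<stem>.pts/.elem/.lon`` plus a JSON
    surface sidecar) or ``"vtu"`` (ASCII VTU).  Inferred from the path suffix
    when omitted.
    """
    path = Path(path)
    fmt = fmt or ("vtu" if path.suffix == ".vtu" else "triplet")
    if fmt == "triplet":
        _write_triplet(path, mesh)
    elif fmt == "vtu":
        _write_vtu(path, mesh)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


def read_mesh(path: str | Path, fmt: str | None = None) -> Mesh:
    """Read a mesh written by :func:`write_mesh`."""
    path = Path(path)
    fmt = fmt or ("vtu" if path.suffix == ".vtu" else "triplet")
    if fmt == "triplet":
        return _read_triplet(path)
    if fmt == "vtu":
        return _read_vtu(path)
    raise ValueError(f"unknown mesh format {fmt!r}")


def _stem(path: Path) -> Path:
    return path.with_suffix("") if path.suffix in (".pts", ".elem", ".lon") else path


def _write_triplet(path: Path, mesh: Mesh) -> None:
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    with open(stem.with_suffix(".pts"), "w") as f:
        f.write(f"{len(mesh.nodes)}\n")
        for x, y, z in mesh.nodes:
            f.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
    with open(stem.with_suffix(".elem"), "w") as f:
        f.write(f"{len(mesh.tets)}\n")
        for tet, reg in zip(mesh.tets, mesh.elem_region):
            f.write("Tt " + " ".join(str(i) for i in tet) + f" {reg}\n")
    if mesh.fibers is not None:
        with open(stem.with_suffix(".lon"), "w") as f:
            f.write("3\n")  # three vectors per element: f0 s0 n0
            for a, b, c in zip(mesh.fibers.f0, mesh.fibers.s0, mesh.fibers.n0):
                row = np.concatenate([a, b, c])
                f.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    sidecar = {k: v.tolist() for k, v in mesh.surfaces.items()}
    with open(stem.parent / (stem.name + "." + _SURFACE_SIDECAR), "w") as f:
        json.dump(sidecar, f)


def _read_triplet(path: Path) -> Mesh:
    stem = _stem(path)
    pts_file = stem.with_suffix(".pts")
    with open(pts_file) as f:
        n = int(f.readline())
        nodes = np.loadtxt(f, max_rows=n, ndmin=2)
    if len(nodes) != n:
        raise ValueError(f"{pts_file}: header says {n} nodes, found {len(nodes)}")
    tets, regions = [], []
    elem_file = stem.with_suffix(".elem")
    with open(elem_file) as f:
        m = int(f.readline())
        for lineno, line in enumerate(f, start=2):
            parts = line.split()
            if not parts:
                continue
            if parts[0] != "Tt":
                raise ValueError(
                    f"{elem_file}:{lineno}: non-tet cell type {parts[0]!r}"
                )
            if len(parts) != 6:
                raise ValueError(f"{elem_file}:{lineno}: expected 'Tt i j k l region'")
            tets.append([int(p) for p in parts[1:5]])
            regions.append(int(parts[5]))
    if len(tets) != m:
        raise ValueError(f"{elem_file}: header says {m} elements, found {len(tets)}")
    fibers = None
    lon_file = stem.with_suffix(".lon")
    if lon_file.exists():
        with open(lon_file) as f:
            nvec = int(f.readline())
            data = np.loadtxt(f, ndmin=2)
        if nvec not in (1, 3) or data.shape[1] != 3 * nvec:
            raise ValueError(f"{lon_file}: expected 1 or 3 vectors per element")
        if len(data) != len(tets):
            raise ValueError(
                f"{lon_file}: {len(data)} rows for {len(tets)} elements"
            )
        f0 = data[:, 0:3]
        norms = np.linalg.norm(f0, axis=1)
        if np.abs(norms - 1.0).max() > 1e-8:
            warnings.warn("fiber file contains non-unit vectors; normalizing")
            f0 = f0 / norms[:, None]
        if nvec == 3:
            s0 = data[:, 3:6]
            s0 = s0 - np.einsum("ij,ij->i", s0, f0)[:, None] * f0
            s0 /= np.linalg.norm(s0, axis=1)[:, None]
            n0 = np.cross(f0, s0)
        else:  # single-vector file: complete an arbitrary orthonormal triad
            ref = np.tile([0.0, 0.0, 1.0], (len(f0), 1))
            swap = np.abs(f0[:, 2]) > 0.9
            ref[swap] = [1.0, 0.0, 0.0]
            s0 = np.cross(ref, f0)
            s0 /= np.linalg.norm(s0, axis=1)[:, None]
            n0 = np.cross(f0, s0)
        fibers = FiberField(f0, s0, n0)
    surfaces = {}
    sidecar = stem.parent / (stem.name + "." + _SURFACE_SIDECAR)
    if sidecar.exists():
        with open(sidecar) as f:
            surfaces = {k: np.asarray(v, dtype=np.int64) for k, v in json.load(f).items()}
    return Mesh(nodes, np.asarray(tets), np.asarray(regions), surfaces, fibers)


# Minimal ASCII VTU (UnstructuredGrid, tet cells).  Cell data carries the
# region label and fiber vectors; surface labels travel in a JSON sidecar.

def _write_vtu(path: Path, mesh: Mesh, point_data: dict | None = None,
               cell_data: dict | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    n, m = len(mesh.nodes), len(mesh.tets)
    cd = {"region": mesh.elem_region}
    if mesh.fibers is not None:
        cd.update(f0=mesh.fibers.f0, s0=mesh.fibers.s0, n0=mesh.fibers.n0)
    if cell_data:
        cd.update(cell_data)
    pd = dict(point_data or {})

    def arr(f, name, data, ncomp):
        data = np.asarray(data)
        f.write(
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n'
        )
        np.savetxt(f, data.reshape(-1, ncomp), fmt="%.17g")
        f.write("</DataArray>\n")

    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n')
        f.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        f.write(f'<UnstructuredGrid>\n<Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n')
        f.write("<Points>\n")
        arr(f, "Points", mesh.nodes, 3)
        f.write("</Points>\n<Cells>\n")
        f.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        np.savetxt(f, mesh.tets, fmt="%d")
        f.write('</DataArray>\n<DataArray type="Int64" Name="offsets" format="ascii">\n')
        np.savetxt(f, np.arange(4, 4 * m + 1, 4)[:, None], fmt="%d")
        f.write('</DataArray>\n<DataArray type="UInt8" Name="types" format="ascii">\n')
        np.savetxt(f, np.full((m, 1), 10), fmt="%d")  # VTK_TETRA
        f.write("</DataArray>\n</Cells>\n")
        f.write("<CellData>\n")
        for name, data in cd.items():
            data = np.asarray(data)
            ncomp = 1 if data.ndim == 1 else data.shape[1]
            arr(f, name, data, ncomp)
        f.write("</CellData>\n<PointData>\n")
        for name, data in pd.items():
            data = np.asarray(data)
            ncomp = 1 if data.ndim == 1 else data.shape[1]
            arr(f, name, data, ncomp)
        f.write("</PointData>\n")
        f.write("</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
    sidecar = path.parent / (path.stem + "." + _SURFACE_SIDECAR)
    with open(sidecar, "w") as f:
        json.dump({k: v.tolist() for k, v in mesh.surfaces.items()}, f)


def _read_vtu(path: Path) -> Mesh:
    import xml.etree.ElementTree as ET

    tree = ET.parse(path)
    piece = tree.getroot().find(".//Piece")
    if piece is None:
        raise ValueError(f"{path}: no UnstructuredGrid Piece found")

    def get_array(parent, name):
        for da in parent.iter("DataArray"):
            if da.get("Name") == name:
                vals = np.fromstring(da.text.replace("\n", " "), sep=" ")
                ncomp = int(da.get("NumberOfComponents", "1"))
                return vals.reshape(-1, ncomp) if ncomp > 1 else vals
        return None

    pts = get_array(piece.find("Points"), "Points")
    cells = piece.find("Cells")
    conn = get_array(cells, "connectivity").astype(np.int64)
    types = get_array(cells, "types").astype(int)
    if not (types == 10).all():
        bad = set(types[types != 10].tolist())
        raise ValueError(f"{path}: non-tetrahedral cell types {sorted(bad)} rejected")
    tets = conn.reshape(-1, 4)
    celldata = piece.find("CellData")
    region = None
    fibers = None
    if celldata is not None:
        region = get_array(celldata, "region")
        f0 = get_array(celldata, "f0")
        s0 = get_array(celldata, "s0")
        n0 = get_array(celldata, "n0")
        if f0 is not None and s0 is not None and n0 is not None:
            fibers = FiberField(f0, s0, n0)
    if region is None:
        region = np.ones(len(tets))
    surfaces = {}
    sidecar = path.parent / (path.stem + "." + _SURFACE_SIDECAR)
    if sidecar.exists():
        with open(sidecar) as f:
            surfaces = {k: np.asarray(v, dtype=np.int64) for k, v in json.load(f).items()}
    return Mesh(pts, tets, region.astype(np.int64), surfaces, fibers)
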