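"""Small P1 finite-element helpers shared by geometry and mechanics.

Linear (P1) tetrahedral elements with single-point quadrature throughout:
shape-function gradients are constant per element, which keeps assembly fully
vectorizable over elements.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["shape_gradients", "laplace_solve", "p1_stiffness"]


def shape_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Constant P1 shape gradients and volumes per tet.

    Returns ``(grads, vols)`` with ``grads`` of shape (M, 4, 3) such that
    grad(u_h)|_e = sum_a u_a grads[e, a], and ``vols`` the tet volumes.
    """
    p = nodes[tets]
    e = p[:, 1:] - p[:, 0:1]  # (M, 3, 3) edge matrix rows
    det = np.linalg.det(e)
    vols = det / 6.0
    if (vols <= 0).any():
        raise ValueError("non-positively-oriented tets in shape_gradients")
    einv = np.linalg.inv(e)  # (M, 3, 3); columns are gradients of N1..N3
    g = einv.transpose(0, 2, 1)  # (M, 3, 3): row a -> grad N_{a+1}
    g0 = -g.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g], axis=1), vols


def p1_stiffness(nodes: np.ndarray, tets: np.ndarray) -> sp.csr_matrix:
    """Assemble the scalar P1 Laplace stiffness matrix."""
    grads, vols = shape_gradients(nodes, tets)
    ke = np.einsum("eai,ebi,e->eab", grads, grads, vols)  # (M, 4, 4)
    rows = np.repeat(tets, 4, axis=1).reshape(-1)
    cols = np.tile(tets, (1, 4)).reshape(-1)
    n = len(nodes)
    return sp.coo_matrix((ke.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()


def laplace_solve(nodes: np.ndarray, tets: np.ndarray,
                  dirichlet: dict[int, float]) -> np.ndarray:
    """Solve Laplace's equation with nodal Dirichlet data, natural elsewhere.

    ``dirichlet`` maps node index -> value.  Used for harmonic ventricular
    coordinates (e.g. transmural: endo = 0, epi = 1).
    """
    K = p1_stiffness(nodes, tets)
    n = len(nodes)
    fixed = np.fromiter(dirichlet.keys(), dtype=np.int64)
    vals = np.fromiter((dirichlet[i] for i in fixed), dtype=float)
    free = np.setdiff1d(np.arange(n), fixed)
    u = np.zeros(n)
    u[fixed] = vals
    rhs = -K[free][:, fixed] @ vals
    u[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)
    return u
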