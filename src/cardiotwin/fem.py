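"""Linear (P1) finite elements on tetrahedra: gradients, stiffness, lumped mass.

Shared by the monodomain diffusion operator and the Laplace solves that
define the ventricular coordinate fields.  Coordinates are taken in the
caller's length unit; the stiffness of an element scales as volume *
grad*grad, so unit conversion is handled by the caller via the tensor.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "tet_volumes",
    "shape_gradients",
    "stiffness_matrix",
    "lumped_mass",
    "solve_laplace_dirichlet",
]


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for right-handed ordering)."""
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def shape_gradients(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the 4 barycentric shape functions per element.

    Returns ``(grads, vols)`` with ``grads`` of shape (n_el, 4, 3) and
    ``vols`` the absolute element volumes.
    """
    x = nodes[tets]  # (n_el, 4, 3)
    e = x[:, 1:, :] - x[:, :1, :]  # (n_el, 3, 3) rows = edge vectors
    vol6 = np.einsum("ij,ij->i", np.cross(e[:, 0], e[:, 1]), e[:, 2])
    inv = np.linalg.inv(e)  # (n_el, 3, 3); column k = grad of lambda_{k+1}
    g = np.transpose(inv, (0, 2, 1))  # (n_el, 3, 3) rows = grads 1..3
    g0 = -g.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g], axis=1)
    return grads, np.abs(vol6) / 6.0


def stiffness_matrix(nodes: np.ndarray, tets: np.ndarray,
                     tensors: np.ndarray | None = None) -> sp.csr_matrix:
    """Assemble the anisotropic stiffness matrix K_ab = sum_el V grad_a . D grad_b.

    ``tensors`` is (n_el, 3, 3) or None for the identity (Laplace).
    """
    grads, vols = shape_gradients(nodes, tets)
    if tensors is None:
        dg = grads
    else:
        dg = np.einsum("eij,eaj->eai", tensors, grads)
    ke = np.einsum("eai,ebi->eab", grads, dg) * vols[:, None, None]
    n = nodes.shape[0]
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n))
    return k.tocsr()


def lumped_mass(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Row-lumped mass: a quarter of each element volume to each vertex."""
    _, vols = shape_gradients(nodes, tets)
    m = np.zeros(nodes.shape[0])
    np.add.at(m, tets.ravel(), np.repeat(vols / 4.0, 4))
    return m


def solve_laplace_dirichlet(nodes: np.ndarray, tets: np.ndarray,
                            fixed_idx: np.ndarray,
                            fixed_val: np.ndarray) -> np.ndarray:
    """Harmonic interpolation of boundary values over the mesh."""
    fixed_idx = np.asarray(fixed_idx, dtype=int)
    if fixed_idx.size == 0:
        raise ValueError("no Dirichlet nodes given")
    n = nodes.shape[0]
    k = stiffness_matrix(nodes, tets)
    u = np.zeros(n)
    u[fixed_idx] = fixed_val
    free = np.ones(n, dtype=bool)
    free[fixed_idx] = False
    kff = k[free][:, free]
    rhs = -k[free][:, ~free] @ u[~free]
    u[free] = spla.spsolve(kff.tocsc(), rhs)
    return u
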