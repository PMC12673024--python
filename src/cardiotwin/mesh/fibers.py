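"""Rule-based myocardial fiber architecture.

The helix angle interpolates linearly in the transmural coordinate from
``alpha_endo`` on the endocardium to ``alpha_epi`` on the epicardium.
Per element, a local orthonormal frame (circumferential, longitudinal,
transmural) is built from the gradients of the coordinate fields; the
fiber is the circumferential axis rotated towards the longitudinal axis
by the helix angle.  Sheet direction is taken transmural and the sheet
normal completes the frame.
"""

from __future__ import annotations

import numpy as np

from .. import fem
from .build import BiventricularMesh
from .coords import VentricularCoordinates

__all__ = ["assign_fibers"]


def _normalize(v: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    bad = norm[:, 0] < 1e-12
    out = np.where(bad[:, None], fallback, v / np.where(norm < 1e-12, 1, norm))
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def assign_fibers(mesh: BiventricularMesh, coords: VentricularCoordinates,
                  alpha_endo_deg: float = 60.0,
                  alpha_epi_deg: float = -60.0) -> BiventricularMesh:
    """Attach per-element fiber / sheet / sheet-normal unit vectors."""
    grads, _ = fem.shape_gradients(mesh.nodes, mesh.tets)

    def el_grad(field: np.ndarray) -> np.ndarray:
        return np.einsum("eai,ea->ei", grads, field[mesh.tets])

    g_tm = el_grad(coords.transmural)
    g_ab = el_grad(coords.apicobasal)

    # transmural axis; radial fallback for degenerate gradients
    cent = mesh.element_centroids()
    radial = cent.copy()
    radial[:, 2] = 0.0
    radial = _normalize(radial, np.tile([1.0, 0.0, 0.0], (cent.shape[0], 1)))
    e_t = _normalize(g_tm, radial)

    # longitudinal axis: apicobasal gradient orthogonalized against e_t
    zhat = np.tile([0.0, 0.0, 1.0], (cent.shape[0], 1))
    g_l = g_ab - np.einsum("ei,ei->e", g_ab, e_t)[:, None] * e_t
    fallback_l = zhat - np.einsum("ei,ei->e", zhat, e_t)[:, None] * e_t
    e_l = _normalize(g_l, _normalize(fallback_l, zhat))

    e_c = np.cross(e_t, e_l)
    nrm = np.linalg.norm(e_c, axis=1, keepdims=True)
    bad = nrm[:, 0] < 1e-9
    if np.any(bad):
        # e_t parallel to e_l (apex cap): rebuild a perpendicular pair
        alt = np.cross(e_t[bad], np.tile([1.0, 0.0, 0.0], (int(bad.sum()), 1)))
        alt2 = np.cross(e_t[bad], np.tile([0.0, 1.0, 0.0], (int(bad.sum()), 1)))
        use2 = np.linalg.norm(alt, axis=1) < 1e-6
        alt[use2] = alt2[use2]
        e_c[bad] = alt
        e_l[bad] = np.cross(e_t[bad], e_c[bad])
        e_l[bad] /= np.linalg.norm(e_l[bad], axis=1, keepdims=True)
        nrm = np.linalg.norm(e_c, axis=1, keepdims=True)
    e_c /= nrm

    tm_el = coords.transmural[mesh.tets].mean(axis=1)
    alpha = np.deg2rad(alpha_endo_deg
                       + (alpha_epi_deg - alpha_endo_deg) * tm_el)
    fib = np.cos(alpha)[:, None] * e_c + np.sin(alpha)[:, None] * e_l
    fib /= np.linalg.norm(fib, axis=1, keepdims=True)

    sheet = e_t
    normal = np.cross(fib, sheet)
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)

    mesh.fibers = fib
    mesh.sheets = sheet
    mesh.sheet_normals = normal
    return mesh
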