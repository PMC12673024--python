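"""Universal ventricular coordinates on biventricular meshes.

Per-node normalized fields: the transmural coordinate is a harmonic
interpolation (Laplace solve with Dirichlet boundary values), the
apicobasal coordinate a normalized geodesic distance, plus an angular
coordinate and a ventricle label:

- ``transmural``: 0 on endocardium, 1 on epicardium.  In the septum the
  RV-facing surface plays the role of the epicardium (the septal wall
  spans LV endo to RV endo).
- ``apicobasal``: 0 at the apex cap, 1 on the base plane.
- ``rotational``: angle about the long axis in [-pi, pi), origin at the
  anterior LV-RV junction, increasing towards the free wall so that the
  septum sits at negative values.
- ``transventricular``: 0 for LV (incl. septum), 1 for RV free wall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .. import fem
from .build import (
    edge_graph,
    REGION_RV,
    REGION_SEPTUM,
    TAG_BASE,
    TAG_EPI,
    TAG_LV_ENDO,
    TAG_RV_ENDO,
    BiventricularMesh,
)

__all__ = ["VentricularCoordinates", "compute_ventricular_coordinates"]

LV = 0
RV = 1


@dataclass
class VentricularCoordinates:
    apicobasal: np.ndarray       # (n,) in [0, 1], 0 = apex
    transmural: np.ndarray       # (n,) in [0, 1], 0 = endo
    rotational: np.ndarray       # (n,) in [-pi, pi)
    transventricular: np.ndarray  # (n,) int, 0 = LV, 1 = RV

    def validate(self) -> None:
        for name, f, lo, hi in (("apicobasal", self.apicobasal, 0.0, 1.0),
                                ("transmural", self.transmural, 0.0, 1.0)):
            if np.any(f < lo - 1e-9) or np.any(f > hi + 1e-9):
                raise ValueError(f"{name} out of [{lo}, {hi}]")
        if np.any(self.rotational < -np.pi) or np.any(self.rotational >= np.pi):
            raise ValueError("rotational out of [-pi, pi)")


def compute_ventricular_coordinates(mesh: BiventricularMesh
                                    ) -> VentricularCoordinates:
    tags = set(np.unique(mesh.face_tags).tolist())
    for needed in (TAG_LV_ENDO, TAG_EPI, TAG_BASE):
        if needed not in tags:
            raise ValueError(
                f"mesh lacks boundary faces with tag {needed}; cannot "
                "compute ventricular coordinates")

    n = mesh.n_nodes

    # transmural: endo surfaces 0, epi 1; septal RV-facing surface counts
    # as the far (value 1) side of the septal wall
    endo_nodes = np.concatenate([
        mesh.boundary_nodes(TAG_LV_ENDO),
        mesh.boundary_nodes(TAG_RV_ENDO, region=REGION_RV),
    ])
    far_nodes = np.concatenate([
        mesh.boundary_nodes(TAG_EPI),
        mesh.boundary_nodes(TAG_RV_ENDO, region=REGION_SEPTUM),
    ])
    far_nodes = np.setdiff1d(far_nodes, endo_nodes)
    fixed = np.concatenate([endo_nodes, far_nodes])
    vals = np.concatenate([np.zeros(endo_nodes.size), np.ones(far_nodes.size)])
    transmural = np.clip(
        fem.solve_laplace_dirichlet(mesh.nodes, mesh.tets, fixed, vals), 0, 1)

    # apicobasal: normalized geodesic distance between the apex and the
    # base plane, d_apex / (d_apex + d_base), computed per ventricle so
    # each ventricle spans the full [0, 1] range from its own apex.  (A
    # pure Laplace solve with a small apex patch concentrates almost the
    # whole range near the apex; geodesic normalization stays close to
    # arc length.)
    base_nodes = mesh.boundary_nodes(TAG_BASE)
    apicobasal = np.zeros(n)
    rv_el_mask = mesh.region == REGION_RV
    lv_nodeset = np.unique(mesh.tets[~rv_el_mask])
    rv_nodeset = np.unique(mesh.tets[rv_el_mask])
    for nodeset, els in ((lv_nodeset, mesh.tets[~rv_el_mask]),
                         (rv_nodeset, mesh.tets[rv_el_mask])):
        if nodeset.size == 0:
            continue
        graph = edge_graph(mesh.nodes, els)[nodeset][:, nodeset]
        local = -np.ones(n, dtype=int)
        local[nodeset] = np.arange(nodeset.size)
        zmin = mesh.nodes[nodeset, 2].min()
        apex = np.flatnonzero(mesh.nodes[nodeset, 2] < zmin + 1.5 * mesh.edge_mm)
        base_l = local[np.intersect1d(base_nodes, nodeset)]
        apex = np.setdiff1d(apex, base_l)
        d_apex = dijkstra(graph, directed=False, indices=apex, min_only=True)
        d_base = dijkstra(graph, directed=False, indices=base_l, min_only=True)
        with np.errstate(invalid="ignore"):
            ab = d_apex / (d_apex + d_base)
        ab[~np.isfinite(ab)] = 0.0
        # LV assigned first; RV overwrites only its exclusive nodes
        if nodeset is lv_nodeset:
            apicobasal[nodeset] = ab
        else:
            excl = np.setdiff1d(nodeset, lv_nodeset)
            apicobasal[excl] = ab[local[excl]]
    apicobasal = np.clip(apicobasal, 0.0, 1.0)

    # transventricular: RV free wall only
    tv = np.zeros(n, dtype=np.int8)
    rv_el = mesh.region == REGION_RV
    rv_nodes = np.unique(mesh.tets[rv_el])
    lv_nodes = np.unique(mesh.tets[~rv_el])
    tv[np.setdiff1d(rv_nodes, lv_nodes)] = RV

    # rotational: angle about the z axis, shifted so 0 is the anterior
    # LV-RV junction (most counterclockwise extent of the septum)
    phi = np.arctan2(mesh.nodes[:, 1], mesh.nodes[:, 0])
    sept_el = mesh.region == REGION_SEPTUM
    if np.any(sept_el):
        cent = mesh.nodes[mesh.tets[sept_el]].mean(axis=1)
        phi_sept = np.arctan2(cent[:, 1], cent[:, 0])
        phi0 = float(np.quantile(phi_sept, 0.98))
    else:
        phi0 = 0.0
    rotational = np.mod(phi - phi0 + np.pi, 2 * np.pi) - np.pi

    coords = VentricularCoordinates(apicobasal=apicobasal,
                                    transmural=transmural,
                                    rotational=rotational,
                                    transventricular=tv)
    coords.validate()
    return coords
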