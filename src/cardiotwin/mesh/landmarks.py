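"""Stimulation landmarks: early activation sites, RV apex, CV probes.

Five early activation sites (EAS), paced simultaneously, mimic the
His-Purkinje-mediated physiological pattern of ventricular
depolarization: two LV septal (mid and basal), one LV anterior
paraseptal, one LV inferior free wall, and one RV septal site, all
endocardial.  An RV apical site supports pacing for CV measurement,
which uses two probes on the RV septal endocardium separated by about
2 cm of geodesic distance along the apicobasal axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .build import (
    REGION_RV,
    REGION_SEPTUM,
    TAG_LV_ENDO,
    TAG_RV_ENDO,
    BiventricularMesh,
    edge_graph,
)
from .coords import VentricularCoordinates

__all__ = ["EasSite", "LandmarkSet", "default_eas_spec", "place_landmarks"]


@dataclass(frozen=True)
class EasSite:
    """Target position of one EAS in ventricular coordinates."""

    name: str
    surface: str          # 'lv_endo' | 'rv_septal_endo' | 'rv_endo'
    apicobasal: float
    rotational: float     # radians; ignored for rv_septal surfaces
    onset_ms: float = 0.0


def default_eas_spec() -> list[EasSite]:
    return [
        EasSite("lv-septal-mid", "lv_septal_endo", 0.40, 0.0),
        EasSite("lv-septal-basal", "lv_septal_endo", 0.70, 0.0),
        EasSite("lv-anterior-paraseptal", "lv_endo", 0.50, 0.35),
        EasSite("lv-inferior-freewall", "lv_endo", 0.45, -2.60),
        EasSite("rv-septal", "rv_septal_endo", 0.45, 0.0),
    ]


@dataclass
class LandmarkSet:
    eas: list[tuple[np.ndarray, float]]   # (node set, onset ms) x 5
    rv_apex: np.ndarray                   # node set
    cv_probe_a: int
    cv_probe_b: int
    probe_distance_mm: float

    def validate(self) -> None:
        if len(self.eas) != 5:
            raise ValueError(f"expected exactly 5 EAS, got {len(self.eas)}")
        onsets = {t for _, t in self.eas}
        if len(onsets) != 1:
            raise ValueError("EAS onsets must be simultaneous")
        if not (18.0 <= self.probe_distance_mm <= 22.0):
            raise ValueError(
                f"CV probe separation {self.probe_distance_mm:.1f} mm outside "
                "the 20 +/- 2 mm window")


def _surface_nodes(mesh: BiventricularMesh, surface: str) -> np.ndarray:
    if surface == "lv_endo":
        return mesh.boundary_nodes(TAG_LV_ENDO)
    if surface == "rv_endo":
        return mesh.boundary_nodes(TAG_RV_ENDO)
    if surface == "rv_septal_endo":
        return mesh.boundary_nodes(TAG_RV_ENDO, region=REGION_SEPTUM)
    if surface == "lv_septal_endo":
        sept = mesh.boundary_nodes(TAG_LV_ENDO, region=REGION_SEPTUM)
        return sept if sept.size else mesh.boundary_nodes(TAG_LV_ENDO)
    raise ValueError(f"unknown surface {surface!r}")


def _pick_site(mesh, coords, nodes, ab_target, rot_target, use_rot,
               radius_mm) -> np.ndarray:
    # UVC-space distance with rotational arc scaled to a physical length
    scale_ab = float(np.ptp(mesh.nodes[:, 2]))
    d2 = ((coords.apicobasal[nodes] - ab_target) * scale_ab) ** 2
    if use_rot:
        drot = np.arctan2(np.sin(coords.rotational[nodes] - rot_target),
                          np.cos(coords.rotational[nodes] - rot_target))
        d2 = d2 + (drot * 15.0) ** 2
    best = nodes[int(np.argmin(d2))]
    if np.sqrt(d2.min()) > max(3.0 * mesh.edge_mm, 2.0):
        warnings.warn(
            f"EAS target (ab={ab_target}, rot={rot_target}) is {np.sqrt(d2.min()):.1f} "
            "length-units from the nearest surface node; using nearest node",
            stacklevel=3)
    near = nodes[np.linalg.norm(mesh.nodes[nodes] - mesh.nodes[best], axis=1)
                 <= radius_mm]
    return near


def place_landmarks(mesh: BiventricularMesh, coords: VentricularCoordinates,
                    eas_spec: list[EasSite] | None = None,
                    site_radius_mm: float = 2.0,
                    probe_separation_mm: float = 20.0) -> LandmarkSet:
    spec = default_eas_spec() if eas_spec is None else eas_spec
    if len(spec) != 5:
        raise ValueError(f"expected exactly 5 EAS in the spec, got {len(spec)}")
    eas = []
    for site in spec:
        nodes = _surface_nodes(mesh, site.surface)
        chosen = _pick_site(mesh, coords, nodes, site.apicobasal,
                            site.rotational,
                            site.surface in ("lv_endo", "rv_endo"),
                            site_radius_mm)
        eas.append((chosen, site.onset_ms))

    # RV apical pacing site: most apical RV endocardial patch
    rv_endo = mesh.boundary_nodes(TAG_RV_ENDO)
    ab = coords.apicobasal[rv_endo]
    apex_node = rv_endo[int(np.argmin(ab))]
    if coords.apicobasal[apex_node] >= 0.1:
        warnings.warn("RV apex site has apicobasal >= 0.1; geometry is "
                      "unusually truncated", stacklevel=2)
    rv_apex = rv_endo[np.linalg.norm(
        mesh.nodes[rv_endo] - mesh.nodes[apex_node], axis=1) <= site_radius_mm]

    # CV probes on the RV septal endocardium, separated along the
    # apicobasal axis by ~probe_separation_mm of geodesic distance
    sept = mesh.boundary_nodes(TAG_RV_ENDO, region=REGION_SEPTUM)
    if sept.size < 2:
        raise ValueError("no RV septal endocardial surface to place CV probes")
    graph = edge_graph(mesh.nodes, mesh.tets)
    ab_s = coords.apicobasal[sept]
    rot_s = coords.rotational[sept]
    rot_mid = np.median(rot_s)
    start_score = np.abs(ab_s - 0.2) + 0.3 * np.abs(rot_s - rot_mid)
    ia = int(np.argmin(start_score))
    # geodesic through the wall-hugging edge graph: a surface-only
    # subgraph on a stair-stepped lattice boundary badly overestimates
    # distances because neighboring surface nodes need not share edges
    dist_all = dijkstra(graph, directed=False, indices=int(sept[ia]),
                        min_only=True)
    dist = dist_all[sept]
    # the pair must lie along the apicobasal axis (same rotational line):
    # a circumferential detour sits on one isochrone of an apex-paced
    # front and would inflate the apparent CV
    towards_base = ab_s > ab_s[ia]
    cand = np.empty(0, dtype=int)
    for rot_tol in (0.15, 0.3, 0.6, np.inf):
        on_line = np.abs(rot_s - rot_s[ia]) <= rot_tol
        cand = np.flatnonzero(np.isfinite(dist) & towards_base & on_line)
        if cand.size:
            break
    if cand.size == 0:
        raise ValueError("RV septal surface disconnected; cannot place probes")
    ib = int(cand[np.argmin(np.abs(dist[cand] - probe_separation_mm))])
    sep = float(dist[ib])
    if abs(sep - probe_separation_mm) > 2.0:
        warnings.warn(
            f"CV probe separation {sep:.1f} mm deviates from the requested "
            f"{probe_separation_mm:.0f} mm; septal surface too short",
            stacklevel=2)
    lm = LandmarkSet(eas=eas, rv_apex=rv_apex,
                     cv_probe_a=int(sept[ia]), cv_probe_b=int(sept[ib]),
                     probe_distance_mm=sep)
    if 18.0 <= sep <= 22.0:
        lm.validate()
    return lm
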