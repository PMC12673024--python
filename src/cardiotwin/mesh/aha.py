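"""AHA 17-segment division of the LV and segment-wise wall thickness.

Segments follow the standard convention: six basal (1 anterior, 2
anteroseptal, 3 inferoseptal, 4 inferior, 5 inferolateral, 6
anterolateral), six mid-cavity (7-12, same order), four apical
(13 anterior, 14 septal, 15 inferior, 16 lateral) and the apex cap (17).
Bands are cut in the apicobasal coordinate, sectors in the rotational
coordinate.

Wall thickness per segment is the mean distance from the segment's
endocardial surface nodes to the opposing outer surface (epicardium, or
the RV-facing surface for septal segments), the end-diastolic geometry
being the only geometry the mesh represents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .build import (
    REGION_RV,
    REGION_SEPTUM,
    TAG_EPI,
    TAG_LV_ENDO,
    TAG_RV_ENDO,
    BiventricularMesh,
)
from .coords import VentricularCoordinates

__all__ = ["AHASegmentation", "WallThicknessMap", "segment_lv",
           "measure_wall_thickness"]

_AB_APEX_CAP = 0.12
_AB_APICAL = 1.0 / 3.0
_AB_MID = 2.0 / 3.0


@dataclass
class AHASegmentation:
    """Per-element AHA segment id (1-17 for LV elements, 0 for RV)."""

    segment: np.ndarray  # (n_el,) int

    def element_counts(self) -> dict[int, int]:
        return {s: int(np.sum(self.segment == s)) for s in range(1, 18)}


@dataclass
class WallThicknessMap:
    thickness_mm: np.ndarray     # (17,) per segment, NaN = missing
    segment_area_mm2: np.ndarray  # (17,) endocardial surface area weights
    lv_average_mm: float

    def as_dict(self) -> dict[int, float]:
        return {s + 1: float(self.thickness_mm[s]) for s in range(17)}


def _sector6(angle: np.ndarray) -> np.ndarray:
    """Sector 1..6 from the anterior-junction angle, septum in sectors 2-3."""
    a = np.mod(-angle, 2 * np.pi)
    return 1 + np.minimum((a / (np.pi / 3)).astype(int), 5)


def _sector4(angle: np.ndarray) -> np.ndarray:
    a = np.mod(-angle + np.pi / 4, 2 * np.pi)
    return 13 + np.minimum((a / (np.pi / 2)).astype(int), 3)


def segment_lv(mesh: BiventricularMesh, coords: VentricularCoordinates
               ) -> AHASegmentation:
    seg = np.zeros(mesh.n_elements, dtype=int)
    lv_el = mesh.region != REGION_RV
    ab = coords.apicobasal[mesh.tets].mean(axis=1)
    rot = np.arctan2(
        np.sin(coords.rotational[mesh.tets]).mean(axis=1),
        np.cos(coords.rotational[mesh.tets]).mean(axis=1))

    basal = lv_el & (ab >= _AB_MID)
    mid = lv_el & (ab >= _AB_APICAL) & (ab < _AB_MID)
    apical = lv_el & (ab >= _AB_APEX_CAP) & (ab < _AB_APICAL)
    cap = lv_el & (ab < _AB_APEX_CAP)

    seg[basal] = _sector6(rot[basal])
    seg[mid] = 6 + _sector6(rot[mid])
    seg[apical] = _sector4(rot[apical])
    seg[cap] = 17
    return AHASegmentation(segment=seg)


def measure_wall_thickness(mesh: BiventricularMesh,
                           coords: VentricularCoordinates,
                           segmentation: AHASegmentation) -> WallThicknessMap:
    lv_endo_faces = mesh.face_tags == TAG_LV_ENDO
    outer_faces = (mesh.face_tags == TAG_EPI) | (
        (mesh.face_tags == TAG_RV_ENDO)
        & (mesh.region[mesh.face_owner] == REGION_SEPTUM))
    outer_faces &= mesh.region[mesh.face_owner] != REGION_RV
    if not np.any(lv_endo_faces) or not np.any(outer_faces):
        raise ValueError("mesh lacks LV endo or outer surface faces")

    outer_nodes = np.unique(mesh.faces[outer_faces])
    tree = cKDTree(mesh.nodes[outer_nodes])

    # per-endo-face: segment of the owning element, area, thickness from
    # its vertices' nearest outer-surface distance
    faces = mesh.faces[lv_endo_faces]
    seg_f = segmentation.segment[mesh.face_owner[lv_endo_faces]]
    tri = mesh.nodes[faces]
    area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    endo_nodes, inv = np.unique(faces, return_inverse=True)
    d_node, _ = tree.query(mesh.nodes[endo_nodes])
    d_face = d_node[inv.reshape(-1, 3)].mean(axis=1)

    thickness = np.full(17, np.nan)
    areas = np.zeros(17)
    for s in range(1, 18):
        m = seg_f == s
        if not np.any(m):
            continue  # missing segment propagates as NaN
        areas[s - 1] = area[m].sum()
        thickness[s - 1] = np.average(d_face[m], weights=area[m])

    ok = ~np.isnan(thickness)
    lv_avg = float(np.average(thickness[ok], weights=areas[ok]))
    return WallThicknessMap(thickness_mm=thickness, segment_area_mm2=areas,
                            lv_average_mm=lv_avg)
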