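"""Idealized biventricular and slab tetrahedral meshes.

Geometries are voxelized on a regular lattice (spacing = target edge
length) and each cube is split into six tetrahedra sharing the main
diagonal (Kuhn subdivision), which is conforming across neighboring
cubes.  The biventricle is two truncated intersecting ellipsoidal
shells: a thick-walled LV and a thin-walled RV crescent wrapped around
it; the septum is the part of the LV wall facing the RV cavity.

All lengths are mm.  Mesh generation is deterministic given parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GeometryParams",
    "BiventricularMesh",
    "REGION_LV",
    "REGION_RV",
    "REGION_SEPTUM",
    "TAG_LV_ENDO",
    "TAG_RV_ENDO",
    "TAG_EPI",
    "TAG_BASE",
    "build_idealized_biventricle",
    "build_slab",
]

REGION_LV = 1
REGION_RV = 2
REGION_SEPTUM = 3

TAG_LV_ENDO = 1
TAG_RV_ENDO = 2
TAG_EPI = 3
TAG_BASE = 4

# Kuhn subdivision: 6 tets per cube, all sharing diagonal 0-7.
# Cube vertex bits: index = dx + 2*dy + 4*dz.
_KUHN = np.array([
    [0, 1, 3, 7],
    [0, 1, 5, 7],
    [0, 2, 3, 7],
    [0, 2, 6, 7],
    [0, 4, 5, 7],
    [0, 4, 6, 7],
])


@dataclass(frozen=True)
class GeometryParams:
    """Idealized biventricular geometry (all lengths mm)."""

    lv_epi_semi: tuple[float, float, float] = (30.0, 30.0, 42.0)
    lv_wall_base_mm: float = 10.0
    lv_wall_apex_mm: float = 10.0
    rv_center: tuple[float, float, float] = (14.0, 0.0, 0.0)
    rv_epi_semi: tuple[float, float, float] = (26.0, 24.0, 39.0)
    rv_wall_mm: float = 5.0
    base_z_mm: float = 8.0
    edge_mm: float = 1.5
    scale: float = 1.0

    def validate(self) -> None:
        walls = (self.lv_wall_base_mm, self.lv_wall_apex_mm, self.rv_wall_mm)
        if any(w <= 0 for w in walls):
            raise ValueError("wall thicknesses must be positive")
        if self.edge_mm > min(walls) * self.scale / 2.0 + 1e-9:
            raise ValueError(
                f"target edge {self.edge_mm} mm exceeds half the thinnest "
                f"wall ({min(walls) * self.scale} mm); refine the mesh")
        if min(self.lv_epi_semi) <= max(self.lv_wall_base_mm,
                                        self.lv_wall_apex_mm):
            raise ValueError("LV wall thicker than the chamber radius")
        if min(self.rv_epi_semi) <= self.rv_wall_mm:
            raise ValueError("RV wall thicker than the chamber radius")


@dataclass
class BiventricularMesh:
    """Tetrahedral biventricular mesh with labels, tags and (later) fibers."""

    nodes: np.ndarray          # (n, 3) mm
    tets: np.ndarray           # (m, 4) int
    region: np.ndarray         # (m,) REGION_*
    faces: np.ndarray          # (f, 3) boundary triangles
    face_tags: np.ndarray      # (f,) TAG_*
    face_owner: np.ndarray     # (f,) owning tet index
    edge_mm: float
    geometry: GeometryParams | None = None
    fibers: np.ndarray | None = None   # (m, 3) unit vectors
    sheets: np.ndarray | None = None
    sheet_normals: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def boundary_nodes(self, tag: int, region: int | None = None) -> np.ndarray:
        """Unique node indices of boundary faces with ``tag`` (optionally
        restricted to faces owned by elements of ``region``)."""
        mask = self.face_tags == tag
        if region is not None:
            mask &= self.region[self.face_owner] == region
        return np.unique(self.faces[mask])

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def validate(self) -> None:
        from ..fem import tet_volumes
        if self.tets.min() < 0 or self.tets.max() >= self.n_nodes:
            raise ValueError("element references out-of-range node")
        vols = tet_volumes(self.nodes, self.tets)
        if np.any(vols <= 0):
            raise ValueError(f"{np.sum(vols <= 0)} inverted tetrahedra")
        if self.fibers is not None:
            norms = np.linalg.norm(self.fibers, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValueError("fibers are not unit vectors")
        # single connected component
        n_comp, _ = connected_components(_node_adjacency(self.nodes, self.tets),
                                         directed=False)
        if n_comp != 1:
            raise ValueError(f"mesh has {n_comp} connected components")


def _node_adjacency(nodes: np.ndarray, tets: np.ndarray) -> sp.csr_matrix:
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    rows = np.concatenate([tets[:, a] for a, _ in pairs])
    cols = np.concatenate([tets[:, b] for _, b in pairs])
    n = nodes.shape[0]
    return sp.coo_matrix((np.ones(rows.size), (rows, cols)),
                         shape=(n, n)).tocsr()


def edge_graph(nodes: np.ndarray, tets: np.ndarray) -> sp.csr_matrix:
    """Undirected edge graph weighted by Euclidean edge length (mm)."""
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    rows = np.concatenate([tets[:, a] for a, _ in pairs])
    cols = np.concatenate([tets[:, b] for _, b in pairs])
    edges = np.unique(np.sort(np.stack([rows, cols], axis=1), axis=1), axis=0)
    w = np.linalg.norm(nodes[edges[:, 0]] - nodes[edges[:, 1]], axis=1)
    n = nodes.shape[0]
    g = sp.coo_matrix((w, (edges[:, 0], edges[:, 1])), shape=(n, n))
    return g.maximum(g.T).tocsr()


def _tets_from_cubes(cube_idx: np.ndarray, grid_shape: tuple[int, int, int]
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Kuhn-split included cubes; returns (corner node multi-ids, tets)."""
    nx, ny, nz = grid_shape  # lattice node counts
    ci, cj, ck = cube_idx.T

    def nid(di, dj, dk):
        return (ci + di) * ny * nz + (cj + dj) * nz + (ck + dk)

    corners = np.stack([nid(b & 1, (b >> 1) & 1, (b >> 2) & 1)
                        for b in range(8)], axis=1)  # (n_cubes, 8)
    tets = corners[:, _KUHN].reshape(-1, 4)  # (n_cubes*6, 4)
    return corners, tets


def _voxel_mesh(include: np.ndarray, origin: np.ndarray, h: float):
    """Build tets from an include mask over cubes; returns nodes, tets, cube ids."""
    cube_idx = np.argwhere(include)
    if cube_idx.shape[0] == 0:
        raise ValueError("empty geometry: no voxels included")
    grid_shape = (include.shape[0] + 1, include.shape[1] + 1,
                  include.shape[2] + 1)
    _, tets_raw = _tets_from_cubes(cube_idx, grid_shape)
    used, tets = np.unique(tets_raw, return_inverse=True)
    tets = tets.reshape(-1, 4)
    ny, nz = grid_shape[1], grid_shape[2]
    ii = used // (ny * nz)
    jj = (used // nz) % ny
    kk = used % nz
    nodes = origin[None, :] + h * np.stack([ii, jj, kk], axis=1).astype(float)
    cube_of_tet = np.repeat(np.arange(cube_idx.shape[0]), 6)
    return nodes, tets, cube_idx, cube_of_tet


def _fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    from ..fem import tet_volumes
    vols = tet_volumes(nodes, tets)
    flip = vols < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()
    return tets


def _boundary_faces(tets: np.ndarray):
    """Boundary triangles (appearing once) with their owning tet."""
    combos = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    faces = np.concatenate([tets[:, c] for c in combos])
    owner = np.tile(np.arange(tets.shape[0]), 4)
    key = np.sort(faces, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True,
                                 return_counts=True)
    sel = first[counts == 1]
    return faces[sel], owner[sel]


def _largest_component(nodes, tets, extra_el_arrays):
    n_comp, labels = connected_components(_node_adjacency(nodes, tets),
                                          directed=False)
    if n_comp == 1:
        return nodes, tets, extra_el_arrays
    keep_label = np.bincount(labels).argmax()
    el_keep = labels[tets[:, 0]] == keep_label
    tets = tets[el_keep]
    used, tets = np.unique(tets, return_inverse=True)
    tets = tets.reshape(-1, 4)
    nodes = nodes[used]
    extra = [a[el_keep] for a in extra_el_arrays]
    return nodes, tets, extra


class _BivGeometry:
    """Implicit-region tests for the two-ellipsoid biventricle."""

    def __init__(self, p: GeometryParams):
        s = p.scale
        self.lv_epi = np.array(p.lv_epi_semi) * s
        self.lv_c = np.zeros(3)
        self.w_base = p.lv_wall_base_mm * s
        self.w_apex = p.lv_wall_apex_mm * s
        self.rv_c = np.array(p.rv_center) * s
        self.rv_epi = np.array(p.rv_epi_semi) * s
        # thinner apical cap (w/2 along the long axis) so the RV cavity
        # reaches near the RV tip, as in real anatomy
        w = p.rv_wall_mm * s
        self.rv_endo = self.rv_epi - np.array([w, w, 0.5 * w])
        self.z_base = p.base_z_mm * s
        self.z_apex = -self.lv_epi[2]

    @staticmethod
    def _inside(pts, center, semi):
        q = (pts - center) / semi
        return np.einsum("ij,ij->i", q, q) < 1.0

    def _lv_wall_local(self, pts):
        z = pts[:, 2]
        frac = np.clip((z - self.z_apex) / (self.z_base - self.z_apex), 0, 1)
        return self.w_apex + (self.w_base - self.w_apex) * frac

    def in_lv_epi(self, pts):
        return self._inside(pts, self.lv_c, self.lv_epi)

    def in_lv_endo(self, pts):
        w = self._lv_wall_local(pts)
        semi = self.lv_epi[None, :] - w[:, None]
        if np.any(semi <= 0):
            raise ValueError("LV wall thicker than chamber radius")
        q = (pts - self.lv_c) / semi
        return np.einsum("ij,ij->i", q, q) < 1.0

    def in_rv_epi(self, pts):
        return self._inside(pts, self.rv_c, self.rv_epi)

    def in_rv_endo_ell(self, pts):
        return self._inside(pts, self.rv_c, self.rv_endo)

    def classify(self, pts):
        """0 outside, 1 LV wall, 2 RV wall, 3 septum, 4 LV cavity, 5 RV cavity."""
        below = pts[:, 2] <= self.z_base
        lv_epi = self.in_lv_epi(pts)
        lv_endo = self.in_lv_endo(pts)
        rv_epi = self.in_rv_epi(pts)
        rv_endo = self.in_rv_endo_ell(pts)
        out = np.zeros(pts.shape[0], dtype=np.int8)
        lv_wall = below & lv_epi & ~lv_endo
        septum = lv_wall & rv_epi
        rv_cav = below & rv_endo & ~lv_epi
        rv_wall = below & rv_epi & ~rv_endo & ~lv_epi
        lv_cav = below & lv_endo
        out[lv_wall] = 1
        out[septum] = 3
        out[rv_wall] = 2
        out[lv_cav] = 4
        out[rv_cav] = 5
        return out


def build_idealized_biventricle(params: GeometryParams | None = None,
                                seed: int | None = None) -> BiventricularMesh:
    """Voxelize and tetrahedralize the idealized biventricular geometry.

    ``seed`` is accepted for API uniformity; construction is fully
    deterministic in the parameters.
    """
    p = params or GeometryParams()
    p.validate()
    geo = _BivGeometry(p)
    h = p.edge_mm

    lo = np.minimum(geo.lv_c - geo.lv_epi, geo.rv_c - geo.rv_epi) - h
    hi = np.maximum(geo.lv_c + geo.lv_epi, geo.rv_c + geo.rv_epi) + h
    hi[2] = geo.z_base + h
    n_cubes = np.ceil((hi - lo) / h).astype(int)
    origin = lo

    ci = np.arange(n_cubes[0])
    cj = np.arange(n_cubes[1])
    ck = np.arange(n_cubes[2])
    cc = np.stack(np.meshgrid(ci, cj, ck, indexing="ij"), axis=-1)
    centers = origin + (cc + 0.5) * h
    cls = geo.classify(centers.reshape(-1, 3)).reshape(cc.shape[:3])
    include = (cls == 1) | (cls == 2) | (cls == 3)

    nodes, tets, cube_idx, cube_of_tet = _voxel_mesh(include, origin, h)
    cube_cls = cls[cube_idx[:, 0], cube_idx[:, 1], cube_idx[:, 2]][cube_of_tet]
    region = np.where(cube_cls == 2, REGION_RV,
                      np.where(cube_cls == 3, REGION_SEPTUM, REGION_LV))
    tets = _fix_orientation(nodes, tets)
    nodes, tets, (region, cube_of_tet) = _largest_component(
        nodes, tets, [region, cube_of_tet])

    faces, owner = _boundary_faces(tets)
    face_tags = _classify_faces(nodes, faces, owner, cube_idx, cube_of_tet,
                                origin, h, geo)
    mesh = BiventricularMesh(nodes=nodes, tets=tets, region=region,
                             faces=faces, face_tags=face_tags,
                             face_owner=owner, edge_mm=h, geometry=p)
    mesh.validate()
    return mesh


def _classify_faces(nodes, faces, owner, cube_idx, cube_of_tet, origin, h, geo):
    """Tag each boundary triangle by the region just outside of it."""
    tags = np.empty(faces.shape[0], dtype=np.int8)
    tri = nodes[faces]  # (f, 3, 3)
    cube = cube_idx[cube_of_tet[owner]]  # (f, 3) lattice cube of owner
    center = origin + (cube + 0.5) * h
    for axis in range(3):
        const = np.all(np.isclose(tri[:, :, axis], tri[:, :1, axis]), axis=1)
        if axis == 0:
            plane_axis = np.where(const, 0, -1)
        else:
            plane_axis = np.where(const & (plane_axis < 0), axis, plane_axis)
    # outside voxel center: mirror the owner center across the face plane
    out_pts = center.copy()
    rows = np.arange(faces.shape[0])
    pa = plane_axis
    plane_coord = tri[rows, 0, pa]
    sign = np.where(plane_coord > center[rows, pa], 1.0, -1.0)
    out_pts[rows, pa] = center[rows, pa] + sign * h

    above_base = out_pts[:, 2] > geo.z_base
    cls_out = geo.classify(out_pts)
    tags[:] = TAG_EPI
    tags[cls_out == 5] = TAG_RV_ENDO
    tags[cls_out == 4] = TAG_LV_ENDO
    tags[above_base] = TAG_BASE
    return tags


def build_slab(lx_mm: float, ly_mm: float, lz_mm: float,
               edge_mm: float) -> BiventricularMesh:
    """Rectangular slab mesh (region LV); used for engine validation."""
    n = np.maximum(np.round(np.array([lx_mm, ly_mm, lz_mm]) / edge_mm), 1)
    n = n.astype(int)
    include = np.ones(tuple(n), dtype=bool)
    nodes, tets, cube_idx, cube_of_tet = _voxel_mesh(
        include, np.zeros(3), edge_mm)
    tets = _fix_orientation(nodes, tets)
    faces, owner = _boundary_faces(tets)
    mesh = BiventricularMesh(
        nodes=nodes, tets=tets,
        region=np.full(tets.shape[0], REGION_LV),
        faces=faces, face_tags=np.full(faces.shape[0], TAG_EPI, dtype=np.int8),
        face_owner=owner, edge_mm=edge_mm, geometry=None)
    mesh.validate()
    return mesh
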