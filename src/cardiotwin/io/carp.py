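"""CARP-style mesh triplet I/O (.pts / .elem / .lon).

``.pts``: node count on the first line, then one ``x y z`` per node
(coordinates in mm here).  ``.elem``: element count, then
``Tt n0 n1 n2 n3 region`` per tetrahedron (0-based node indices).
``.lon``: header ``1`` (one direction per element), then one unit fiber
vector per element.  Non-unit vectors are normalized on read with a
warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

__all__ = ["write_pts", "read_pts", "write_elem", "read_elem",
           "write_lon", "read_lon", "write_carp_mesh", "read_carp_mesh"]


def write_pts(path, nodes: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(f"{nodes.shape[0]}\n")
        np.savetxt(fh, nodes, fmt="%.9g")


def read_pts(path) -> np.ndarray:
    with open(path) as fh:
        first = fh.readline()
        try:
            n = int(first.strip())
        except ValueError as e:
            raise ValueError(f"{path}: line 1: expected node count, got "
                             f"{first.strip()!r}") from e
        nodes = np.loadtxt(fh, ndmin=2)
    if nodes.shape != (n, 3):
        raise ValueError(f"{path}: expected {n} x/y/z rows, got "
                         f"{nodes.shape}")
    return nodes


def write_elem(path, tets: np.ndarray, region: np.ndarray | None = None) -> None:
    region = np.zeros(tets.shape[0], dtype=int) if region is None else region
    with open(path, "w") as fh:
        fh.write(f"{tets.shape[0]}\n")
        for row, reg in zip(tets, region):
            fh.write(f"Tt {row[0]} {row[1]} {row[2]} {row[3]} {int(reg)}\n")


def read_elem(path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        first = fh.readline()
        try:
            n = int(first.strip())
        except ValueError as e:
            raise ValueError(f"{path}: line 1: expected element count") from e
        tets = np.empty((n, 4), dtype=int)
        region = np.empty(n, dtype=int)
        for i in range(n):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 6 or parts[0] != "Tt":
                raise ValueError(
                    f"{path}: line {i + 2}: expected 'Tt n0 n1 n2 n3 region', "
                    f"got {line.strip()!r}")
            tets[i] = [int(v) for v in parts[1:5]]
            region[i] = int(parts[5])
    return tets, region


def write_lon(path, fibers: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("1\n")
        np.savetxt(fh, fibers, fmt="%.9g")


def read_lon(path) -> np.ndarray:
    with open(path) as fh:
        first = fh.readline()
        if first.strip() not in ("1", "2"):
            raise ValueError(f"{path}: line 1: expected direction count 1 or 2")
        fibers = np.loadtxt(fh, ndmin=2)[:, :3]
    norms = np.linalg.norm(fibers, axis=1)
    bad = np.abs(norms - 1.0) > 1e-6
    if np.any(bad):
        warnings.warn(f"{path}: {int(bad.sum())} non-unit fiber vectors "
                      "normalized on read", stacklevel=2)
        nz = norms > 1e-12
        fibers[nz] /= norms[nz, None]
    return fibers


def write_carp_mesh(basepath, mesh) -> None:
    """Write a BiventricularMesh as basepath.{pts,elem,lon}."""
    base = Path(basepath)
    write_pts(base.with_suffix(".pts"), mesh.nodes)
    write_elem(base.with_suffix(".elem"), mesh.tets, mesh.region)
    if mesh.fibers is not None:
        write_lon(base.with_suffix(".lon"), mesh.fibers)


def read_carp_mesh(basepath):
    """Read basepath.{pts,elem[,lon]} into a BiventricularMesh.

    Boundary faces are re-derived; surface tags are not stored in the
    triplet and are left untagged (0)."""
    from ..mesh.build import BiventricularMesh, _boundary_faces
    base = Path(basepath)
    nodes = read_pts(base.with_suffix(".pts"))
    tets, region = read_elem(base.with_suffix(".elem"))
    lon = base.with_suffix(".lon")
    fibers = read_lon(lon) if lon.exists() else None
    faces, owner = _boundary_faces(tets)
    edge = float(np.median(np.linalg.norm(
        nodes[tets[:, 1]] - nodes[tets[:, 0]], axis=1)))
    return BiventricularMesh(nodes=nodes, tets=tets, region=region,
                             faces=faces, face_tags=np.zeros(faces.shape[0],
                                                             dtype=np.int8),
                             face_owner=owner, edge_mm=edge, fibers=fibers)
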