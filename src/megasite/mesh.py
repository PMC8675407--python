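"""Icosahedral spherical meshes: subdivision, Euler characteristic, downsampling.

A recursively subdivided icosahedron with ``n`` rounds of 1-to-4 triangle
splitting (edge midpoints projected to the unit sphere) has

    V = 10 * 4**n + 2,   E = 30 * 4**n,   F = 20 * 4**n,

so chi = V - E + F = 2 at every depth, as for any sphere-topology surface.
FreeSurfer's standard inter-subject surface corresponds to n = 7 (163,842
vertices per hemisphere); n = 4 (2,562 vertices) is a common downsampled
analysis resolution.

Subdivision keeps the parent vertices first and appends midpoints, so a
coarser mesh of the same family is an exact vertex-prefix of any finer one;
``downsample`` relies on this nesting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError


@dataclass
class TriMesh:
    """Triangulated surface: (V, 3) float vertices and (F, 3) int faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise DataError("face references an out-of-range vertex index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) sorted-index array."""
        return unique_edges(self.faces)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def unique_edges(faces: np.ndarray) -> np.ndarray:
    pairs = np.asarray(faces)[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2)
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0)


def euler_characteristic(mesh: TriMesh) -> int:
    """chi = V - E + F, with E the count of unique undirected edges.

    Equals 2 for any sphere-topology surface, 0 for a torus, and adds over
    disjoint components.
    """
    return int(mesh.n_vertices - mesh.n_edges + mesh.n_faces)


def icosahedron() -> TriMesh:
    """The regular icosahedron on the unit sphere (V=12, E=30, F=20)."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=np.int64,
    )
    return TriMesh(verts, faces)


def subdivide(mesh: TriMesh) -> TriMesh:
    """One round of 1-to-4 subdivision with midpoints projected to the sphere.

    Midpoints shared between adjacent triangles are deduplicated exactly by
    keying on the (sorted) parent edge, never on floating-point coordinates.
    """
    V = mesh.vertices
    F = mesh.faces
    edge_pairs = F[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2)
    edge_pairs = np.sort(edge_pairs, axis=1)
    uniq, inverse = np.unique(edge_pairs, axis=0, return_inverse=True)
    mids = V[uniq[:, 0]] + V[uniq[:, 1]]
    mids /= np.linalg.norm(mids, axis=1, keepdims=True)
    mid_index = len(V) + inverse.reshape(-1, 3)  # (F, 3): m01, m12, m20
    a, b, c = F[:, 0], F[:, 1], F[:, 2]
    m01, m12, m20 = mid_index[:, 0], mid_index[:, 1], mid_index[:, 2]
    new_faces = np.concatenate(
        [
            np.stack([a, m01, m20], axis=1),
            np.stack([b, m12, m01], axis=1),
            np.stack([c, m20, m12], axis=1),
            np.stack([m01, m12, m20], axis=1),
        ]
    )
    return TriMesh(np.vstack([V, mids]), new_faces)


def subdivide_icosahedron(n: int) -> TriMesh:
    """Icosahedron subdivided ``n`` times; V = 10*4**n + 2 vertices."""
    if n < 0:
        raise ConfigurationError("recursion depth n must be non-negative")
    mesh = icosahedron()
    for _ in range(int(n)):
        mesh = subdivide(mesh)
    return mesh


def icosphere_depth(n_vertices: int) -> int:
    """Recursion depth from a vertex count of the form 10*4**n + 2."""
    n = 0
    while 10 * 4**n + 2 < n_vertices:
        n += 1
    if 10 * 4**n + 2 != n_vertices:
        raise DataError(f"{n_vertices} vertices is not an icosahedral count")
    return n


def _check_nested(src: TriMesh, dst: TriMesh) -> None:
    n_src = icosphere_depth(src.n_vertices)
    n_dst = icosphere_depth(dst.n_vertices)
    if n_dst > n_src:
        raise DataError("destination mesh is finer than the source mesh")
    if not np.allclose(src.vertices[: dst.n_vertices], dst.vertices, atol=1e-12):
        raise DataError("meshes are not nested members of the same family")


def geodesic_smooth(values: np.ndarray, mesh: TriMesh, fwhm: float) -> np.ndarray:
    """Gaussian smoothing in great-circle distance, truncated at 3 sigma.

    ``fwhm`` is in radians on the unit sphere; 0 disables smoothing.
    """
    values = np.asarray(values, dtype=float)
    if fwhm <= 0:
        return values.copy()
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    cos_cut = math.cos(min(3.0 * sigma, math.pi))
    out = np.empty_like(values)
    V = mesh.vertices
    for i in range(len(V)):
        cosd = np.clip(V @ V[i], -1.0, 1.0)
        nbr = np.nonzero(cosd >= cos_cut)[0]
        d = np.arccos(cosd[nbr])
        w = np.exp(-0.5 * (d / sigma) ** 2)
        out[i] = (w @ values[nbr]) / w.sum()
    return out


def nearest_vertex_assignment(src: TriMesh, dst: TriMesh) -> np.ndarray:
    """Index of the geodesically nearest dst vertex for each src vertex.

    On the unit sphere geodesic order equals chordal order, so the nearest
    vertex maximizes the dot product.  Ties break toward the lowest dst index.
    """
    assign = np.empty(src.n_vertices, dtype=np.int64)
    dstV = dst.vertices
    step = max(1, 2**22 // max(1, dst.n_vertices))
    for start in range(0, src.n_vertices, step):
        block = src.vertices[start : start + step]
        cosd = block @ dstV.T
        assign[start : start + len(block)] = np.argmax(cosd, axis=1)
    return assign


def downsample(
    values: np.ndarray,
    src: TriMesh,
    dst: TriMesh,
    kind: str = "pointwise",
    smooth_fwhm: float = 0.0,
) -> np.ndarray:
    """Aggregate per-vertex data from a finer to a coarser nested mesh.

    After optional geodesic Gaussian smoothing on the source mesh, each source
    vertex is assigned to its nearest destination vertex; ``kind="areal"``
    sums assigned values (totals conserved, appropriate for surface area),
    ``kind="pointwise"`` averages them (appropriate for thickness).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != src.n_vertices:
        raise DataError("values length does not match the source mesh")
    if not np.all(np.isfinite(values)):
        raise DataError("values must be finite")
    if kind not in ("areal", "pointwise"):
        raise ConfigurationError(f"unknown downsampling kind {kind!r}")
    _check_nested(src, dst)
    vals = geodesic_smooth(values, src, smooth_fwhm)
    assign = nearest_vertex_assignment(src, dst)
    sums = np.zeros(dst.n_vertices, dtype=float)
    np.add.at(sums, assign, vals)
    if kind == "areal":
        return sums
    counts = np.bincount(assign, minlength=dst.n_vertices).astype(float)
    if np.any(counts == 0):  # cannot happen for nested meshes, but be safe
        counts[counts == 0] = 1.0
    return sums / counts


# ---------------------------------------------------------------------------
# I/O: simple ASCII meshes, GIFTI, per-vertex data columns


def write_mesh_ascii(mesh: TriMesh, path) -> None:
    """Write counts header, vertex lines, then 0-based face lines."""
    with open(path, "w") as fh:
        fh.write(f"{mesh.n_vertices} {mesh.n_faces}\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        for a, b, c in mesh.faces:
            fh.write(f"{a} {b} {c}\n")


def read_mesh_ascii(path) -> TriMesh:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise DataError(f"{path}: expected 'n_vertices n_faces' header")
        nv, nf = int(header[0]), int(header[1])
        verts = np.loadtxt(fh, max_rows=nv, ndmin=2)
        faces = np.loadtxt(fh, max_rows=nf, dtype=np.int64, ndmin=2)
    if verts.shape != (nv, 3) or faces.shape != (nf, 3):
        raise DataError(f"{path}: truncated mesh file")
    return TriMesh(verts, faces)


def read_mesh_gifti(path) -> TriMesh:
    import nibabel as nib

    img = nib.load(str(path))
    verts = faces = None
    for arr in img.darrays:
        if arr.intent == 1008:  # NIFTI_INTENT_POINTSET
            verts = arr.data
        elif arr.intent == 1009:  # NIFTI_INTENT_TRIANGLE
            faces = arr.data
    if verts is None or faces is None:
        raise DataError(f"{path}: GIFTI file lacks pointset/triangle arrays")
    return TriMesh(verts, faces)


def write_vertex_data(values: np.ndarray, path) -> None:
    """Per-vertex data as a two-column TSV (vertex index, value)."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write("vertex\tvalue\n")
        for i, v in enumerate(values):
            fh.write(f"{i}\t{v:.17g}\n")


def read_vertex_data(path) -> np.ndarray:
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    return data[np.argsort(data[:, 0]), 1]
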