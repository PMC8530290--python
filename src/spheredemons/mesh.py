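"""Spherical mesh geometry: triangulated unit spheres, geodesics, sampling.

Everything downstream — demons registration, deformation algebra, the
simulation protocol — operates on :class:`SphericalMesh`, a closed
triangulation of the unit sphere.  Points on the sphere are represented as
unit 3-vectors; distances are great-circle arc lengths in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "SphericalMesh",
    "make_icosphere",
    "geodesic_distance",
    "interpolate_scalar",
    "resample_labels",
    "vertex_area",
    "GeometryError",
]

_UNIT_TOL = 1e-9


class GeometryError(ValueError):
    """Raised when a mesh or query violates a geometric contract."""


@dataclass
class SphericalMesh:
    """A closed triangulation of the unit sphere.

    Parameters
    ----------
    vertices : (N, 3) float array
        Unit vectors (each row has norm 1 within 1e-9).
    faces : (F, 3) int array
        Vertex index triples, counterclockwise seen from outside.
    medial_wall : (N,) bool array, optional
        True where a vertex belongs to the medial wall (excluded from
        functional features and statistics, but present in the geometry).
    """

    vertices: np.ndarray
    faces: np.ndarray
    medial_wall: Optional[np.ndarray] = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be an (F, 3) array")

    # -- basic counts ------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        """Check all mesh invariants; raise :class:`GeometryError` on failure."""
        norms = np.linalg.norm(self.vertices, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise GeometryError("vertex norms deviate from 1 beyond tolerance")
        f = self.faces
        if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
            raise GeometryError("degenerate face: repeated vertex index")
        if self.face_areas().min() <= 0:
            raise GeometryError("degenerate face: zero area")
        n_edges = len(self.edges())
        euler = self.n_vertices - n_edges + self.n_faces
        if euler != 2:
            raise GeometryError(f"Euler characteristic {euler} != 2 (mesh not closed)")
        vols = self.signed_volumes()
        if not ((vols > 0).all() or (vols < 0).all()):
            raise GeometryError("inconsistent face orientation")

    def signed_volumes(self, positions: Optional[np.ndarray] = None) -> np.ndarray:
        """Signed volume of the origin tetrahedron of each face.

        With ``positions`` given, volumes are computed for the same face
        topology at those coordinates (used by the fold check).
        """
        p = self.vertices if positions is None else positions
        a, b, c = p[self.faces[:, 0]], p[self.faces[:, 1]], p[self.faces[:, 2]]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def face_areas(self, positions: Optional[np.ndarray] = None) -> np.ndarray:
        """Euclidean (flat-triangle) area of each face."""
        p = self.vertices if positions is None else positions
        a, b, c = p[self.faces[:, 0]], p[self.faces[:, 1]], p[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2) with first index < second."""
        if "edges" not in self._cache:
            e = np.vstack(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            )
            e.sort(axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    def mean_edge_length(self) -> float:
        """Mean great-circle edge length in radians."""
        e = self.edges()
        return float(
            np.mean(geodesic_distance(self.vertices[e[:, 0]], self.vertices[e[:, 1]]))
        )

    # -- connectivity structures ------------------------------------------
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric vertex adjacency matrix (boolean, CSR)."""
        if "adjacency" not in self._cache:
            e = self.edges()
            i = np.concatenate([e[:, 0], e[:, 1]])
            j = np.concatenate([e[:, 1], e[:, 0]])
            a = sparse.csr_matrix(
                (np.ones(len(i)), (i, j)), shape=(self.n_vertices, self.n_vertices)
            )
            self._cache["adjacency"] = a
        return self._cache["adjacency"]

    def averaging_operator(self) -> sparse.csr_matrix:
        """Row-stochastic one-ring averaging operator (self included)."""
        if "avg_op" not in self._cache:
            a = self.adjacency() + sparse.eye(self.n_vertices, format="csr")
            inv_deg = 1.0 / np.asarray(a.sum(axis=1)).ravel()
            self._cache["avg_op"] = sparse.diags(inv_deg) @ a
        return self._cache["avg_op"]

    def vertex_face_lists(self) -> list:
        """faces incident to each vertex (list of int arrays)."""
        if "vfaces" not in self._cache:
            lists: list = [[] for _ in range(self.n_vertices)]
            for fi, (i, j, k) in enumerate(self.faces):
                lists[i].append(fi)
                lists[j].append(fi)
                lists[k].append(fi)
            self._cache["vfaces"] = [np.asarray(l, dtype=np.int64) for l in lists]
        return self._cache["vfaces"]

    def kdtree(self) -> cKDTree:
        if "kdtree" not in self._cache:
            self._cache["kdtree"] = cKDTree(self.vertices)
        return self._cache["kdtree"]

    def candidate_faces(self):
        """Padded per-vertex candidate-face table for point location.

        Row ``v`` lists every face incident to ``v`` or to a one-ring
        neighbor of ``v`` (padded with face 0 under a False mask).
        """
        if "cand_faces" not in self._cache:
            vfaces = self.vertex_face_lists()
            adj = self.adjacency()
            indptr, indices = adj.indptr, adj.indices
            rows = []
            for v in range(self.n_vertices):
                nbrs = indices[indptr[v] : indptr[v + 1]]
                rows.append(
                    np.unique(np.concatenate([vfaces[v]] + [vfaces[u] for u in nbrs]))
                )
            width = max(len(r) for r in rows)
            table = np.zeros((self.n_vertices, width), dtype=np.int64)
            mask = np.zeros((self.n_vertices, width), dtype=bool)
            for v, r in enumerate(rows):
                table[v, : len(r)] = r
                mask[v, : len(r)] = True
            self._cache["cand_faces"] = (table, mask)
        return self._cache["cand_faces"]

    def smooth(self, values: np.ndarray, passes: int) -> np.ndarray:
        """Apply ``passes`` rounds of one-ring averaging to per-vertex data."""
        out = np.asarray(values, dtype=np.float64)
        op = self.averaging_operator()
        for _ in range(passes):
            out = op @ out
        return out


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def make_icosphere(subdivisions: int) -> SphericalMesh:
    """Build a geodesic icosphere with ``10 * 4**s + 2`` vertices.

    Each subdivision splits every triangle into four and reprojects new
    vertices onto the unit sphere.  ``subdivisions=0`` is the icosahedron.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
    mesh = SphericalMesh(verts, faces)
    # icosahedron face order above is CCW from outside; keep orientation positive
    if mesh.signed_volumes().mean() < 0:
        mesh = SphericalMesh(verts, faces[:, ::-1])
    return mesh


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    midpoint: dict = {}
    vlist = list(verts)

    def mid(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        if key not in midpoint:
            m = vlist[i] + vlist[j]
            m = m / np.linalg.norm(m)
            midpoint[key] = len(vlist)
            vlist.append(m)
        return midpoint[key]

    new_faces = []
    for i, j, k in faces:
        a, b, c = mid(i, j), mid(j, k), mid(k, i)
        new_faces += [[i, a, c], [j, b, a], [k, c, b], [a, b, c]]
    return np.asarray(vlist), np.asarray(new_faces, dtype=np.int64)


# ---------------------------------------------------------------------------
# geodesics
# ---------------------------------------------------------------------------

def geodesic_distance(p: np.ndarray, q: np.ndarray, check: bool = True) -> np.ndarray:
    """Great-circle distance (radians) between unit vectors, elementwise.

    Accepts single vectors or (N, 3) arrays with broadcasting.  Uses the
    atan2 form, which is accurate near 0 and pi.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if check:
        for v in (p, q):
            n = np.linalg.norm(v, axis=-1)
            if not np.allclose(n, 1.0, atol=1e-6):
                raise ValueError("geodesic_distance requires unit vectors")
    cross = np.linalg.norm(np.cross(p, q), axis=-1)
    dot = np.einsum("...i,...i->...", p, q)
    return np.arctan2(cross, dot)


# ---------------------------------------------------------------------------
# point location and sampling
# ---------------------------------------------------------------------------

def locate(
    mesh: SphericalMesh,
    queries: np.ndarray,
    positions: Optional[np.ndarray] = None,
):
    """Locate queries on the mesh by central (gnomonic) projection.

    For a closed positively-oriented mesh enclosing the origin, the ray
    from the origin through each query direction crosses exactly one face.
    Returns ``(face_indices, barycentric_weights)`` where weights are the
    normalized coefficients of the query in the face's vertex basis.

    ``positions`` substitutes alternative vertex coordinates for the same
    topology (used to interpolate over a *warped* copy of the mesh).
    """
    q = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    pos = mesh.vertices if positions is None else positions
    tree = mesh.kdtree() if positions is None else cKDTree(pos)

    _, nearest = tree.query(q, k=1)
    n = q.shape[0]

    # candidate faces: faces incident to the nearest vertex or its one-ring
    table, tmask = mesh.candidate_faces()
    cand = table[nearest]
    cmask = tmask[nearest]

    tri = pos[mesh.faces[cand]]          # (n, max_c, 3 verts, 3 xyz)
    # solve q = w0*v0 + w1*v1 + w2*v2 for each candidate face
    mats = np.swapaxes(tri, -1, -2)      # (n, max_c, 3 xyz, 3 verts)
    w = _solve_bary(mats, q[:, None, :])
    s = w.sum(axis=-1)
    # same-sign coefficients (all >= 0 after sign fix) mean containment
    w = np.where(s[..., None] < 0, -w, w)
    s = np.abs(s)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = w / s[..., None]
    w = np.where(cmask[..., None], w, -np.inf)
    minw = np.nan_to_num(w.min(axis=-1), nan=-np.inf)
    best = minw.argmax(axis=1)
    rows = np.arange(n)
    best_min = minw[rows, best]
    face_out = cand[rows, best]
    bary_out = w[rows, best]

    # fallback: brute force over all faces for unresolved queries
    bad = best_min < -1e-9
    if bad.any():
        idx = np.where(bad)[0]
        tri_all = pos[mesh.faces]                    # (F, 3, 3)
        mats_all = np.swapaxes(tri_all, -1, -2)
        for i in idx:
            w_all = _solve_bary(mats_all, q[i][None, :])
            s_all = w_all.sum(axis=-1)
            w_all = np.where(s_all[:, None] < 0, -w_all, w_all)
            with np.errstate(divide="ignore", invalid="ignore"):
                w_all = w_all / np.abs(s_all)[:, None]
            minw_all = np.nan_to_num(w_all.min(axis=-1), nan=-np.inf)
            j = int(minw_all.argmax())
            if minw_all[j] < -1e-6:
                raise GeometryError(f"query {i} not locatable on any face")
            face_out[i] = j
            bary_out[i] = w_all[j]

    bary_out = np.clip(bary_out, 0.0, None)
    bary_out /= bary_out.sum(axis=1, keepdims=True)
    return face_out, bary_out


def _solve_bary(mats: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Batched solve of 3x3 systems; singular systems yield NaN rows."""
    b = np.broadcast_to(rhs, mats.shape[:-2] + (3,))[..., None]
    try:
        return np.linalg.solve(mats, b)[..., 0]
    except np.linalg.LinAlgError:
        flat = mats.reshape(-1, 3, 3)
        r = np.ascontiguousarray(b[..., 0]).reshape(-1, 3)
        out = np.full_like(r, np.nan)
        for i in range(flat.shape[0]):
            try:
                out[i] = np.linalg.solve(flat[i], r[i])
            except np.linalg.LinAlgError:
                pass
        return out.reshape(mats.shape[:-2] + (3,))


def interpolate_scalar(
    mesh: SphericalMesh,
    values: np.ndarray,
    queries: np.ndarray,
    positions: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Barycentric interpolation of per-vertex data at unit-vector queries.

    ``values`` may be (N,) or (N, C); the result matches, one row per query.
    A query exactly at a vertex returns that vertex's value.
    """
    values = np.asarray(values, dtype=np.float64)
    single = np.asarray(queries).ndim == 1
    face_idx, bary = locate(mesh, queries, positions=positions)
    tri = mesh.faces[face_idx]                       # (Q, 3)
    if values.ndim == 1:
        out = np.einsum("qi,qi->q", bary, values[tri])
    else:
        out = np.einsum("qi,qic->qc", bary, values[tri])
    return out[0] if single else out


def resample_labels(
    mesh: SphericalMesh, labels: np.ndarray, queries: np.ndarray
) -> np.ndarray:
    """Nearest-vertex label transfer (labels are never averaged).

    Each query takes the label of its geodesically nearest mesh vertex;
    exact ties break to the lowest vertex index.
    """
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise TypeError("labels must be integers")
    q = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    d, idx = mesh.kdtree().query(q, k=2)
    # Euclidean nearest == geodesic nearest on the sphere; break exact ties low
    tie = np.isclose(d[:, 0], d[:, 1], rtol=0, atol=1e-15)
    nearest = idx[:, 0].copy()
    nearest[tie] = np.minimum(idx[tie, 0], idx[tie, 1])
    out = labels[nearest]
    return out[0] if np.asarray(queries).ndim == 1 else out


def vertex_area(
    mesh: SphericalMesh, positions: Optional[np.ndarray] = None
) -> np.ndarray:
    """Per-vertex area: the summed flat area of all incident triangles.

    The total over vertices is three times the total mesh area (each
    triangle contributes to its three corners).  ``positions`` computes the
    same quantity for warped coordinates of the same topology.
    """
    fa = mesh.face_areas(positions=positions)
    if fa.min() <= 0:
        raise GeometryError("degenerate face encountered in vertex_area")
    out = np.zeros(mesh.n_vertices)
    for col in range(3):
        np.add.at(out, mesh.faces[:, col], fa)
    return out
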