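"""Low-level triangle-mesh operations on (vertices, faces) arrays.

Vertices are (n, 3) float arrays in mm; faces are (m, 3) int arrays of
0-based vertex indices.  Everything here is deliberately free of the domain
types so it can be unit-tested on bare arrays.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "face_areas",
    "face_normals",
    "vertex_adjacency",
    "edge_list",
    "boundary_edges",
    "connected_components",
    "vertex_curvatures",
    "plane_cross_sections",
    "project_points_to_mesh",
    "surface_graph_distances",
    "sample_points_on_mesh",
]


def face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)


def face_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    n = np.cross(v1 - v0, v2 - v0)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return n / norm


def edge_list(faces: np.ndarray) -> np.ndarray:
    """All directed edges (3 per face), shape (3m, 2)."""
    return np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])


def vertex_adjacency(n_vertices: int, faces: np.ndarray) -> csr_matrix:
    """Symmetric boolean vertex-adjacency matrix."""
    e = edge_list(faces)
    data = np.ones(len(e), dtype=bool)
    a = coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n_vertices, n_vertices))
    a = a.tocsr()
    return a + a.T


def boundary_edges(faces: np.ndarray) -> np.ndarray:
    """Undirected edges used by exactly one face, shape (k, 2)."""
    e = np.sort(edge_list(faces), axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return uniq[counts == 1]


def connected_components(n_vertices: int, faces: np.ndarray, mask: np.ndarray | None = None):
    """Edge-connected vertex components, optionally restricted to a vertex mask.

    Returns (n_components, labels) where labels is -1 outside the mask.
    """
    adj = vertex_adjacency(n_vertices, faces)
    if mask is None:
        return _cc(adj, directed=False)
    idx = np.flatnonzero(mask)
    sub = adj[idx][:, idx]
    n_comp, sub_labels = _cc(sub, directed=False)
    labels = np.full(n_vertices, -1, dtype=int)
    labels[idx] = sub_labels
    return n_comp, labels


def vertex_curvatures(vertices: np.ndarray, faces: np.ndarray):
    """Discrete principal curvatures (k1, k2) per vertex, k1 >= k2.

    Mean curvature from the cotangent Laplacian, Gaussian curvature from the
    angle defect, both normalized by one third of the incident triangle area.
    Boundary vertices get zero (their estimates are meaningless).
    """
    n = len(vertices)
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))

    def _angles(a, b, c):
        # angle at a between rays to b and c
        u, w = b - a, c - a
        cu = np.einsum("ij,ij->i", u, w)
        den = np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
        den[den == 0] = 1.0
        return np.arccos(np.clip(cu / den, -1.0, 1.0))

    ang0 = _angles(v0, v1, v2)
    ang1 = _angles(v1, v2, v0)
    ang2 = _angles(v2, v0, v1)

    areas = face_areas(vertices, faces)
    va = np.zeros(n)
    np.add.at(va, faces[:, 0], areas / 3)
    np.add.at(va, faces[:, 1], areas / 3)
    np.add.at(va, faces[:, 2], areas / 3)
    va[va == 0] = np.inf

    angle_sum = np.zeros(n)
    np.add.at(angle_sum, faces[:, 0], ang0)
    np.add.at(angle_sum, faces[:, 1], ang1)
    np.add.at(angle_sum, faces[:, 2], ang2)
    gaussian = (2 * np.pi - angle_sum) / va

    # Cotangent Laplacian: for each face, the angle opposite edge (i, j)
    # contributes cot(angle)/2 to weight w_ij.
    eps = 1e-12
    cot0 = 1.0 / np.tan(np.clip(ang0, eps, np.pi - eps))
    cot1 = 1.0 / np.tan(np.clip(ang1, eps, np.pi - eps))
    cot2 = 1.0 / np.tan(np.clip(ang2, eps, np.pi - eps))
    lap = np.zeros((n, 3))
    for (i, j), cot in (((1, 2), cot0), ((2, 0), cot1), ((0, 1), cot2)):
        fi, fj = faces[:, i], faces[:, j]
        d = vertices[fj] - vertices[fi]
        np.add.at(lap, fi, 0.5 * cot[:, None] * d)
        np.add.at(lap, fj, -0.5 * cot[:, None] * d)
    mean_curv = 0.5 * np.linalg.norm(lap, axis=1) / va

    disc = np.maximum(mean_curv**2 - gaussian, 0.0)
    root = np.sqrt(disc)
    k1 = mean_curv + root
    k2 = mean_curv - root

    be = boundary_edges(faces)
    if len(be):
        bset = np.unique(be)
        k1[bset] = 0.0
        k2[bset] = 0.0
    return k1, k2


def plane_cross_sections(
    vertices: np.ndarray,
    faces: np.ndarray,
    point: np.ndarray,
    normal: np.ndarray,
    face_mask: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Intersect the mesh with a plane; return closed polylines (loops).

    Each loop is an ordered (k, 3) array of points lying on the plane and on
    mesh edges.  Open chains (from crossing a mesh boundary) are discarded.
    """
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    d = (vertices - np.asarray(point, float)) @ normal
    # Nudge vertices exactly on the plane to avoid degenerate crossings.
    d = np.where(np.abs(d) < 1e-9, 1e-9, d)

    f = faces if face_mask is None else faces[face_mask]
    sd = d[f]
    crossing = ~(np.all(sd > 0, axis=1) | np.all(sd < 0, axis=1))
    f = f[crossing]
    if len(f) == 0:
        return []

    # For each crossing face, find its two crossed edges and the intersection
    # points; key each point by its sorted edge so the chaining is exact.
    loops: list[np.ndarray] = []
    seg_by_edge: dict[tuple[int, int], list[int]] = {}
    segments: list[tuple[tuple[int, int], tuple[int, int]]] = []
    pts: dict[tuple[int, int], np.ndarray] = {}

    for tri in f:
        keys = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            if d[a] * d[b] < 0:
                key = (min(a, b), max(a, b))
                if key not in pts:
                    t = d[key[0]] / (d[key[0]] - d[key[1]])
                    pts[key] = vertices[key[0]] + t * (vertices[key[1]] - vertices[key[0]])
                keys.append(key)
        if len(keys) == 2:
            si = len(segments)
            segments.append((keys[0], keys[1]))
            seg_by_edge.setdefault(keys[0], []).append(si)
            seg_by_edge.setdefault(keys[1], []).append(si)

    used = np.zeros(len(segments), dtype=bool)
    for start in range(len(segments)):
        if used[start]:
            continue
        chain = [segments[start][0], segments[start][1]]
        used[start] = True
        closed = False
        while True:
            tail = chain[-1]
            nxt = [s for s in seg_by_edge.get(tail, []) if not used[s]]
            if not nxt:
                break
            si = nxt[0]
            used[si] = True
            a, b = segments[si]
            nxt_key = b if a == tail else a
            if nxt_key == chain[0]:
                closed = True
                break
            chain.append(nxt_key)
        if closed and len(chain) >= 3:
            loops.append(np.array([pts[k] for k in chain]))
    return loops


class _MeshProjector:
    """Closest-point projection onto a triangle mesh (KD-tree shortlisted)."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k_candidates: int = 32):
        self.vertices = np.asarray(vertices, float)
        self.faces = np.asarray(faces, int)
        self.centroids = self.vertices[self.faces].mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.k = min(k_candidates, len(self.faces))

    def __call__(self, points: np.ndarray):
        points = np.atleast_2d(np.asarray(points, float))
        _, cand = self.tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        out_pts = np.empty_like(points)
        out_tri = np.empty(len(points), dtype=int)
        out_d = np.empty(len(points))
        for i, (p, cs) in enumerate(zip(points, cand)):
            tri = self.faces[cs]
            proj = _closest_point_on_triangles(p, self.vertices[tri])
            dd = np.linalg.norm(proj - p, axis=1)
            j = int(np.argmin(dd))
            out_pts[i] = proj[j]
            out_tri[i] = cs[j]
            out_d[i] = dd[j]
        return out_pts, out_d, out_tri


def _closest_point_on_triangles(p: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Closest point to p on each triangle (Ericson, vectorized over triangles)."""
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(tris), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m

    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d1 / (d1 - d3)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = d2 / (d2 - d6)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def project_points_to_mesh(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray):
    """Project points to their closest points on the mesh.

    Returns (projected_points, distances, triangle_indices).
    """
    return _MeshProjector(vertices, faces)(points)


def surface_graph_distances(
    vertices: np.ndarray, faces: np.ndarray, source_vertices: np.ndarray
) -> np.ndarray:
    """Graph-geodesic distances (Dijkstra over edge lengths) from sources.

    Returns an (n_sources, n_vertices) array; an upper bound on true geodesic
    distance, adequate for coarse locality checks.
    """
    e = np.unique(np.sort(edge_list(faces), axis=1), axis=0)
    w = np.linalg.norm(vertices[e[:, 0]] - vertices[e[:, 1]], axis=1)
    n = len(vertices)
    g = coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n)).tocsr()
    return dijkstra(g, directed=False, indices=np.asarray(source_vertices, int))


def sample_points_on_mesh(
    vertices: np.ndarray, faces: np.ndarray, n: int, rng: np.random.Generator
):
    """Area-weighted uniform random points on the surface.

    Returns (points, triangle_indices).
    """
    areas = face_areas(vertices, faces)
    probs = areas / areas.sum()
    tri = rng.choice(len(faces), size=n, p=probs)
    u = rng.random(n)
    v = rng.random(n)
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    a, b, c = (vertices[faces[tri, i]] for i in range(3))
    pts = a + u[:, None] * (b - a) + v[:, None] * (c - a)
    return pts, tri
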