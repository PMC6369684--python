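"""Labeled left-atrial surface meshes and pulmonary-vein junction landmarks.

The registration pipeline needs, per surface, one closed ring at each
PV-atrial junction (placed where the surface flares, i.e. at maximum
curvature along the vein axis) and ``n`` landmarks per ring separated by a
constant angle about the ring centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from gp_atlas import geometry
from gp_atlas.errors import MeshValidationError

__all__ = [
    "REGION_LABELS",
    "PV_LABELS",
    "AtrialSurface",
    "PVJunctionRing",
    "LandmarkRing",
    "find_junction_plane",
    "generate_landmark_ring",
]

REGION_LABELS = ("BODY", "LSPV", "RSPV", "LIPV", "RIPV", "MV_RIM")
PV_LABELS = ("LSPV", "RSPV", "LIPV", "RIPV")

#: Default number of landmarks per junction ring.
DEFAULT_LANDMARKS_PER_RING = 8

#: In-plane zero-angle reference: the global superior (+z) axis projected
#: into the ring plane.  Fixed so phases are comparable across patients.
DEFAULT_REFERENCE_AXIS = np.array([0.0, 0.0, 1.0])


@dataclass
class AtrialSurface:
    """Triangulated left-atrial surface with per-vertex region labels.

    Attributes
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of 0-based vertex indices
    labels : (n,) array of strings from :data:`REGION_LABELS`
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: np.ndarray
    surface_id: str = "surface"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.labels = np.asarray(self.labels, dtype="U8")

    # -- validation ---------------------------------------------------------

    def validate(self, require_pvs: bool = False) -> "AtrialSurface":
        """Check structural invariants; returns self for chaining.

        Raises :class:`MeshValidationError` on a hard violation; emits a
        warning (registration unavailable) when PV labels are missing and
        ``require_pvs`` is False.
        """
        v, f, lab = self.vertices, self.faces, self.labels
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshValidationError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshValidationError("faces must be (m, 3) triangles")
        if len(lab) != len(v):
            raise MeshValidationError("one label per vertex required")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshValidationError("face index out of range")

        unknown = set(np.unique(lab)) - set(REGION_LABELS)
        if unknown:
            raise MeshValidationError(f"unknown region labels: {sorted(unknown)}")

        referenced = np.zeros(len(v), dtype=bool)
        referenced[f.ravel()] = True
        if not referenced.all():
            orphans = np.flatnonzero(~referenced)
            raise MeshValidationError(
                f"{len(orphans)} unreferenced vertices (first: {orphans[:5].tolist()})"
            )

        areas = geometry.face_areas(v, f)
        bad = np.flatnonzero(areas < 1e-10)
        if len(bad):
            raise MeshValidationError(
                f"degenerate zero-area triangle(s) at face index {bad[:5].tolist()}"
            )

        missing = [pv for pv in PV_LABELS if pv not in lab]
        if missing:
            msg = f"missing PV labels {missing}; registration unavailable"
            if require_pvs:
                raise MeshValidationError(msg)
            warnings.warn(msg, stacklevel=2)

        for label in np.unique(lab):
            mask = lab == label
            n_comp, _ = geometry.connected_components(len(v), f, mask)
            if n_comp != 1:
                raise MeshValidationError(
                    f"region '{label}' is not edge-connected ({n_comp} components)"
                )
        return self

    # -- cached derived quantities -----------------------------------------

    def curvatures(self):
        if "curv" not in self._cache:
            self._cache["curv"] = geometry.vertex_curvatures(self.vertices, self.faces)
        return self._cache["curv"]

    def projector(self):
        if "proj" not in self._cache:
            self._cache["proj"] = geometry._MeshProjector(self.vertices, self.faces)
        return self._cache["proj"]

    def total_area(self) -> float:
        return float(geometry.face_areas(self.vertices, self.faces).sum())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray, scale: float = 1.0):
        """A copy with vertices mapped by x -> scale * R x + t."""
        new_v = scale * self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        return replace(self, vertices=new_v, _cache={})


@dataclass(frozen=True)
class PVJunctionRing:
    """Closed plane-mesh intersection curve at a PV-atrial junction."""

    pv: str
    plane_point: np.ndarray
    plane_normal: np.ndarray
    curve: np.ndarray  # ordered closed polyline, (k, 3)

    @property
    def centroid(self) -> np.ndarray:
        return self.curve.mean(axis=0)


@dataclass(frozen=True)
class LandmarkRing:
    """Equal-angle landmarks on a junction curve."""

    pv: str
    n: int
    phase: float
    points: np.ndarray  # (n, 3)


def _pv_axis(surface: AtrialSurface, pv: str) -> tuple[np.ndarray, np.ndarray]:
    """Axis of the PV region, oriented away from the atrial body.

    Runs from the centroid of the PV/body interface to the centroid of the
    distal third of the vein; robust for stubs too short for PCA.
    """
    mask = surface.labels == pv
    pts = surface.vertices[mask]
    centroid = pts.mean(axis=0)
    adj = geometry.vertex_adjacency(len(surface.vertices), surface.faces)
    touches_other = np.asarray(adj[:, ~mask].sum(axis=1)).ravel() > 0
    interface_c = surface.vertices[mask & touches_other].mean(axis=0)
    d_int = np.linalg.norm(pts - interface_c, axis=1)
    tip_c = pts[d_int >= np.quantile(d_int, 0.7)].mean(axis=0)
    axis = tip_c - interface_c
    axis = axis / np.linalg.norm(axis)
    return centroid, axis


def _check_tubular(surface: AtrialSurface, pv: str) -> None:
    mask = surface.labels == pv
    if not mask.any():
        raise MeshValidationError(f"PV label '{pv}' absent from surface")
    n_comp, _ = geometry.connected_components(len(surface.vertices), surface.faces, mask)
    if n_comp != 1:
        raise MeshValidationError(f"PV region '{pv}' is not a single component")
    # Interface with the rest of the surface must be one cycle-like component.
    adj = geometry.vertex_adjacency(len(surface.vertices), surface.faces)
    touches_other = np.asarray(adj[:, ~mask].sum(axis=1)).ravel() > 0
    interface = mask & touches_other
    if not interface.any():
        raise MeshValidationError(f"PV region '{pv}' has no boundary with the body")
    n_comp, _ = geometry.connected_components(len(surface.vertices), surface.faces, interface)
    if n_comp != 1:
        raise MeshValidationError(
            f"PV region '{pv}' boundary is not a single cycle ({n_comp} components)"
        )


def _ring_at(
    surface: AtrialSurface,
    origin: np.ndarray,
    axis: np.ndarray,
    s: float,
    max_radius: float,
) -> np.ndarray | None:
    """The plane-mesh loop around the PV axis at axial offset s, if any."""
    point = origin + s * axis
    loops = geometry.plane_cross_sections(surface.vertices, surface.faces, point, axis)
    best, best_r = None, np.inf
    for loop in loops:
        rel = loop - point
        radial = rel - np.outer(rel @ axis, axis)
        r = np.linalg.norm(radial, axis=1)
        if r.min() > max_radius:
            continue  # loop does not hug the axis (e.g. the atrial body outline)
        if r.mean() < best_r:
            best, best_r = loop, r.mean()
    return best


def find_junction_plane(
    surface: AtrialSurface, pv: str, n_sweep: int = 40
) -> PVJunctionRing:
    """Locate the PV-atrial junction ring at maximum surface curvature.

    Sweeps cutting planes orthogonal to the PV principal axis along the vein
    and scores each intersection loop by the mean absolute principal
    curvature of the surface sampled along the loop; returns the loop at the
    arg-max.  A flat sweep (uniform cylinder) falls back to the plane closest
    to the atrial body.
    """
    _check_tubular(surface, pv)
    centroid, axis = _pv_axis(surface, pv)
    pts = surface.vertices[surface.labels == pv]
    s_pv = (pts - centroid) @ axis
    span = float(np.ptp(s_pv))
    if span <= 0:
        raise MeshValidationError(f"PV region '{pv}' is degenerate along its axis")

    # Tube radius estimate from the distal half of the vein.
    distal = pts[s_pv > np.median(s_pv)]
    radial = distal - centroid - np.outer((distal - centroid) @ axis, axis)
    r_tube = float(np.linalg.norm(radial, axis=1).mean())

    k1, k2 = surface.curvatures()
    curv = 0.5 * (np.abs(k1) + np.abs(k2))
    from scipy.spatial import cKDTree

    vtree = surface._cache.setdefault("vtree", cKDTree(surface.vertices))

    s_lo = float(s_pv.min() - 0.45 * span)
    s_hi = float(s_pv.min() + 0.65 * span)
    sweep = np.linspace(s_lo, s_hi, n_sweep)

    candidates: list[tuple[float, float, np.ndarray]] = []
    for s in sweep:
        loop = _ring_at(surface, centroid, axis, s, max_radius=2.5 * r_tube)
        if loop is None:
            continue
        _, idx = vtree.query(loop)
        score = float(curv[idx].mean())
        candidates.append((s, score, loop))
    if not candidates:
        raise MeshValidationError(f"no junction ring found for PV '{pv}'")

    scores = np.array([c[1] for c in candidates])
    if np.ptp(scores) < 1e-9 * max(1.0, np.abs(scores).max()):
        # Flat sweep (uniform cylinder): take the plane closest to the
        # PV/body boundary of the label region.
        s_boundary = float(s_pv.min())
        pick = int(np.argmin([abs(c[0] - s_boundary) for c in candidates]))
    else:
        pick = int(np.argmax(scores))
    s_best, _, loop = candidates[pick]
    return PVJunctionRing(
        pv=pv,
        plane_point=centroid + s_best * axis,
        plane_normal=axis,
        curve=loop,
    )


def _inplane_basis(normal: np.ndarray, reference_axis: np.ndarray):
    normal = normal / np.linalg.norm(normal)
    e1 = reference_axis - np.dot(reference_axis, normal) * normal
    if np.linalg.norm(e1) < 1e-8:
        fallback = np.array([1.0, 0.0, 0.0])
        e1 = fallback - np.dot(fallback, normal) * normal
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def generate_landmark_ring(
    ring: PVJunctionRing,
    n: int = DEFAULT_LANDMARKS_PER_RING,
    phase: float = 0.0,
    reference_axis: np.ndarray = DEFAULT_REFERENCE_AXIS,
) -> LandmarkRing:
    """Place ``n`` landmarks on the junction curve at equal angular spacing.

    Landmark ``k`` sits at in-plane polar angle ``phase + k * 2*pi/n`` about
    the ring centroid, with angle zero along ``reference_axis`` projected
    into the ring plane.
    """
    if n < 3:
        raise ValueError("need at least 3 landmarks per ring")
    curve = ring.curve
    if len(curve) < 8:
        raise MeshValidationError("junction curve too coarse to interpolate landmarks")

    centroid = ring.centroid
    e1, e2 = _inplane_basis(ring.plane_normal, np.asarray(reference_axis, float))
    rel = curve - centroid
    theta = np.arctan2(rel @ e2, rel @ e1)

    # Orient the polyline counter-clockwise in the (e1, e2) frame.
    dtheta = np.angle(np.exp(1j * np.diff(np.append(theta, theta[0]))))
    if dtheta.sum() < 0:
        curve = curve[::-1]
        rel = rel[::-1]
        theta = theta[::-1]

    # Unwrapped angle along the (closed) polyline.
    steps = np.angle(np.exp(1j * np.diff(theta)))
    theta_u = np.concatenate([[theta[0]], theta[0] + np.cumsum(steps)])
    closing = float(np.angle(np.exp(1j * (theta[0] - theta[-1]))))
    theta_closed = np.append(theta_u, theta_u[-1] + closing)  # ends ~ theta_u[0] + 2*pi
    curve_closed = np.vstack([curve, curve[:1]])

    if not np.all(np.diff(theta_closed) > -1e-9):
        # Non-star-shaped wiggles: fall back to nearest-sample placement.
        theta_closed = np.maximum.accumulate(theta_closed)

    def angle_of(p: np.ndarray) -> float:
        q = p - centroid
        return float(np.arctan2(q @ e2, q @ e1))

    points = np.empty((n, 3))
    base = theta_closed[0]
    for k in range(n):
        target = phase + k * 2 * np.pi / n
        # Shift target into [base, base + 2*pi)
        t = base + float(np.mod(target - base, 2 * np.pi))
        i = int(np.searchsorted(theta_closed, t, side="right") - 1)
        i = min(max(i, 0), len(curve_closed) - 2)
        p0, p1 = curve_closed[i], curve_closed[i + 1]
        lo, hi = 0.0, 1.0
        for _ in range(60):  # bisection on the in-plane angle along the chord
            mid = 0.5 * (lo + hi)
            ang = angle_of(p0 + mid * (p1 - p0))
            if float(np.angle(np.exp(1j * (ang - target)))) < 0:
                lo = mid
            else:
                hi = mid
        lam = 0.5 * (lo + hi)
        points[k] = p0 + lam * (p1 - p0)
    return LandmarkRing(pv=ring.pv, n=n, phase=float(phase), points=points)
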