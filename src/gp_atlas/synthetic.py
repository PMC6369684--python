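"""Seeded synthetic cohort generator.

Produces everything the pipeline consumes: a labeled reference atrial shell
(ellipsoid body, four pulmonary-vein stubs with smooth fillets, mitral
opening), patient-specific smoothly deformed copies with known forward
correspondence, evenly spread HFS site layouts, hotspot-structured
ground-truth GP probability fields, and R-wave series realizing each site's
true label.  One master seed reproduces an entire cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from gp_atlas import geometry
from gp_atlas.beats import AFVariabilitySample, BeatSeries, SiteLabel
from gp_atlas.errors import SamplingError
from gp_atlas.surface import PV_LABELS, AtrialSurface

__all__ = [
    "ShellParams",
    "Hotspot",
    "RRParams",
    "CohortConfig",
    "GroundTruthField",
    "PatientShell",
    "PatientRecord",
    "Cohort",
    "make_reference_shell",
    "make_sphere_cylinder_shell",
    "make_patient_shell",
    "sample_sites",
    "assign_true_labels",
    "make_af_samples",
    "make_cohort",
]


# -- reference shell --------------------------------------------------------

_PV_DIRECTIONS = {
    # unit-ish directions from the body centre; +x left, +y posterior, +z superior
    "LSPV": (0.78, 0.38, 0.55),
    "RSPV": (-0.72, 0.38, 0.62),
    "LIPV": (0.82, 0.50, -0.35),
    "RIPV": (-0.80, 0.52, -0.38),
}


@dataclass(frozen=True)
class ShellParams:
    """Geometry of the synthetic left-atrial shell (mm)."""

    body_axes: tuple = (30.0, 27.0, 24.0)
    pv_radius: dict = field(
        default_factory=lambda: {"LSPV": 6.5, "RSPV": 7.0, "LIPV": 6.0, "RIPV": 6.5}
    )
    pv_length: float = 16.0
    pv_open_at: float = 12.0  # distal cut to open the vein ends
    fillet_mm: float = 3.0  # smooth-union blending radius
    mv_direction: tuple = (0.0, -0.55, -0.84)  # anterior-inferior mitral opening
    mv_depth: float = 8.0  # cap height removed for the mitral opening
    grid_mm: float = 1.6  # marching-cubes voxel pitch


def _pv_anchor(params: ShellParams, pv: str) -> tuple[np.ndarray, np.ndarray]:
    """(surface anchor point, outward unit axis) of a PV stub."""
    d = np.asarray(_PV_DIRECTIONS[pv], float)
    d = d / np.linalg.norm(d)
    axes = np.asarray(params.body_axes)
    t = 1.0 / np.linalg.norm(d / axes)  # ray-ellipsoid exit
    return t * d, d


def _shell_implicit(params: ShellParams):
    axes = np.asarray(params.body_axes)
    scale = 3.0 / np.sum(1.0 / axes)  # harmonic-mean length for pseudo-distance
    anchors = {pv: _pv_anchor(params, pv) for pv in PV_LABELS}

    def f(pts: np.ndarray) -> np.ndarray:
        vals = [(np.linalg.norm(pts / axes, axis=1) - 1.0) * scale]
        for pv in PV_LABELS:
            q, d = anchors[pv]
            u = pts - q
            s = u @ d
            rho = np.linalg.norm(u - np.outer(s, d), axis=1)
            caps = np.maximum(s - params.pv_length, -s - 10.0)
            vals.append(np.maximum(rho - params.pv_radius[pv], caps))
        stack = np.stack(vals)
        k = params.fillet_mm
        # smooth union (log-sum-exp soft min)
        m = stack.min(axis=0)
        return m - k * np.log(np.exp(-(stack - m) / k).sum(axis=0))

    return f, anchors


def make_reference_shell(params: ShellParams | None = None, seed: int = 0) -> AtrialSurface:
    """Build the labeled reference shell (deterministic; seed kept for API parity)."""
    params = params or ShellParams()
    f, anchors = _shell_implicit(params)
    axes = np.asarray(params.body_axes)

    pad = 5.0
    reach = [axes + pad]
    for pv in PV_LABELS:
        q, d = anchors[pv]
        reach.append(np.abs(q + params.pv_length * d) + params.pv_radius[pv] + pad)
    extent = np.max(np.stack(reach), axis=0)

    h = params.grid_mm
    grids = [np.arange(-e, e + h, h) for e in extent]
    gx, gy, gz = np.meshgrid(*grids, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    vol = f(pts).reshape(gx.shape)

    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(h, h, h))
    verts = verts + np.array([g[0] for g in grids])

    # Open the mitral annulus and the PV ends.
    m = np.asarray(params.mv_direction, float)
    m = m / np.linalg.norm(m)
    support = float(np.linalg.norm(m * axes))
    keep = (verts @ m) < (support - params.mv_depth)
    for pv in PV_LABELS:
        q, d = anchors[pv]
        keep &= (verts - q) @ d < params.pv_open_at

    verts, faces = _drop_vertices(verts, faces, keep)
    verts, faces = _largest_component(verts, faces)
    verts, faces = _remove_degenerate(verts, faces)

    labels = np.full(len(verts), "BODY", dtype="U8")
    for pv in PV_LABELS:
        q, d = anchors[pv]
        u = verts - q
        s = u @ d
        rho = np.linalg.norm(u - np.outer(s, d), axis=1)
        cand = (s > params.fillet_mm + 1.0) & (rho < params.pv_radius[pv] + 1.5 * params.fillet_mm)
        cand &= labels == "BODY"
        if not cand.any():
            continue
        n_comp, comp = geometry.connected_components(len(verts), faces, cand)
        tip = np.flatnonzero(cand)[np.argmax(s[cand])]
        labels[comp == comp[tip]] = pv

    # Mitral rim: the boundary cycle left by the mitral cut.
    be = geometry.boundary_edges(faces)
    if len(be):
        bverts = np.unique(be)
        on_mv = (verts[bverts] @ m) > (support - params.mv_depth - 2.5 * h)
        labels[bverts[on_mv]] = "MV_RIM"

    surf = AtrialSurface(vertices=verts, faces=faces, labels=labels, surface_id="reference")
    return surf.validate()


def _drop_vertices(verts, faces, keep_mask):
    idx = np.full(len(verts), -1, dtype=int)
    idx[keep_mask] = np.arange(int(keep_mask.sum()))
    fkeep = keep_mask[faces].all(axis=1)
    return verts[keep_mask], idx[faces[fkeep]]


def _largest_component(verts, faces):
    n_comp, labels = geometry.connected_components(len(verts), faces)
    if n_comp > 1:
        main = np.argmax(np.bincount(labels))
        keep = labels == main
        verts, faces = _drop_vertices(verts, faces, keep)
    # drop unreferenced vertices
    ref = np.zeros(len(verts), dtype=bool)
    ref[faces.ravel()] = True
    return _drop_vertices(verts, faces, ref)


def _remove_degenerate(verts, faces, min_area: float = 1e-9):
    areas = geometry.face_areas(verts, faces)
    faces = faces[areas >= min_area]
    return _largest_component(verts, faces)


# -- analytic revolution shell (oracle geometry) ---------------------------


def make_sphere_cylinder_shell(
    sphere_radius: float = 25.0,
    tube_radius: float = 8.0,
    fillet_radius: float = 4.0,
    tube_length: float = 20.0,
    pv: str = "RSPV",
    n_theta: int = 64,
    profile_step: float = 0.7,
):
    """Sphere + coaxial cylinder joined by an exact torus fillet.

    A surface of revolution about +z with piecewise-analytic principal
    curvatures; used as ground truth for junction-plane detection.  Returns
    ``(surface, analytic)`` where ``analytic`` holds the fillet geometry,
    including ``z_max_curvature``: the latitude maximizing the mean absolute
    principal curvature (the fillet-cylinder tangent line).
    """
    R, a, rf, L = sphere_radius, tube_radius, fillet_radius, tube_length
    if a + rf >= R + rf:
        raise ValueError("tube too wide for the sphere")
    z_c = float(np.sqrt((R + rf) ** 2 - (a + rf) ** 2))

    prof: list[tuple[float, float]] = []
    # sphere from near the south pole up to the fillet tangency
    rho_t = R * (a + rf) / (R + rf)
    z_t = R * z_c / (R + rf)
    phi_t = np.pi - np.arctan2(rho_t, z_t)  # polar angle from the south pole
    n_sph = max(8, int(R * phi_t / profile_step))
    for phi in np.linspace(0.06, phi_t, n_sph):
        prof.append((R * np.sin(phi), -R * np.cos(phi)))
    # torus fillet from the sphere tangency to the cylinder tangency
    psi0 = np.arctan2(z_c, a + rf) - np.pi
    n_fil = max(6, int(rf * abs(-np.pi - psi0) / (profile_step / 2)))
    for psi in np.linspace(psi0, -np.pi, n_fil + 1)[1:]:
        prof.append(((a + rf) + rf * np.cos(psi), z_c + rf * np.sin(psi)))
    # cylinder
    n_cyl = max(4, int(L / profile_step))
    for z in np.linspace(z_c, z_c + L, n_cyl + 1)[1:]:
        prof.append((a, z))

    prof_arr = np.array(prof)
    n_prof = len(prof_arr)
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    ring = np.column_stack([np.cos(theta), np.sin(theta)])

    verts = [np.array([0.0, 0.0, -R])]  # south pole
    for rho, z in prof_arr:
        verts.extend(np.column_stack([rho * ring, np.full(n_theta, z)]))
    verts = np.vstack(verts)

    faces = []
    for j in range(n_theta):  # pole fan
        faces.append([0, 1 + j, 1 + (j + 1) % n_theta])
    for i in range(n_prof - 1):
        base0, base1 = 1 + i * n_theta, 1 + (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([base0 + j, base1 + j, base1 + jn])
            faces.append([base0 + j, base1 + jn, base0 + jn])
    faces = np.array(faces, int)

    labels = np.full(len(verts), "BODY", dtype="U8")
    labels[verts[:, 2] > z_c + 0.75 * profile_step] = pv

    surf = AtrialSurface(
        vertices=verts, faces=faces, labels=labels, surface_id="revolution-shell"
    )
    analytic = {
        "z_fillet_center": z_c,
        "z_max_curvature": z_c,  # fillet-cylinder tangency maximizes (|k1|+|k2|)/2
        "fillet_radius": rf,
        "tube_radius": a,
        "sphere_radius": R,
        "mean_abs_curvature": _revolution_curvature_fn(R, a, rf, z_c),
    }
    return surf, analytic


def _revolution_curvature_fn(R, a, rf, z_c):
    """Piecewise-analytic (|k1| + |k2|)/2 as a function of latitude z."""

    def fn(z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, float)
        out = np.full(z.shape, 1.0 / R)
        z_t = R * z_c / (R + rf)
        on_fillet = (z >= z_t) & (z < z_c)
        if np.any(on_fillet):
            sinpsi = (z[on_fillet] - z_c) / rf
            cospsi = -np.sqrt(np.maximum(1 - sinpsi**2, 0.0))
            rho = (a + rf) + rf * cospsi
            out[on_fillet] = 0.5 * (1.0 / rf + np.abs(cospsi) / rho)
        out[z >= z_c] = 0.5 * (1.0 / rf + 1.0 / a)  # limit at tangency
        on_cyl = z > z_c + 1e-9
        out[on_cyl] = 0.5 / a
        return out

    return fn


# -- ground truth field -----------------------------------------------------


@dataclass(frozen=True)
class Hotspot:
    """A Gaussian bump of AVD-GP probability on the reference surface."""

    center: tuple  # (3,) mm
    amplitude: float  # in [0, 1]
    scale_mm: float

    def __post_init__(self) -> None:
        if not 0 <= self.amplitude <= 1:
            raise ValueError("hotspot amplitude must lie in [0, 1]")
        if self.scale_mm <= 0:
            raise ValueError("hotspot scale must be positive")


def default_hotspots(
    params: ShellParams | None = None, surface: AtrialSurface | None = None
) -> list[Hotspot]:
    """Three bumps in a stylized version of the classic peak geography
    (posterior wall near the septum, RSPV antrum, RIPV base), spread far
    enough apart to stay distinct after 5 mm kernel smoothing.

    When ``surface`` is given, centers are projected onto it so each bump
    peaks on the shell rather than in the open vein mouth.
    """
    params = params or ShellParams()
    axes = np.asarray(params.body_axes)

    def on_body(direction):
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        return tuple(d / np.linalg.norm(d / axes))

    q_rspv, d_rspv = _pv_anchor(params, "RSPV")
    q_ripv, d_ripv = _pv_anchor(params, "RIPV")
    centers = [
        on_body((0.30, 0.80, -0.55)),
        tuple(q_rspv + 2.0 * d_rspv),
        tuple(q_ripv - 1.0 * d_ripv),
    ]
    if surface is not None:
        projected, _, _ = surface.projector()(np.array(centers))
        centers = [tuple(p) for p in projected]
    amps = (0.68, 0.62, 0.62)
    return [
        Hotspot(center=c, amplitude=a, scale_mm=5.5) for c, a in zip(centers, amps)
    ]


@dataclass
class GroundTruthField:
    """True per-point AVD-GP probability: base rate plus Gaussian bumps."""

    hotspots: list
    base_rate: float = 0.02

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        val = np.full(len(pts), self.base_rate)
        for h in self.hotspots:
            d2 = np.sum((pts - np.asarray(h.center)) ** 2, axis=1)
            val = val + h.amplitude * np.exp(-d2 / (2 * h.scale_mm**2))
        return np.clip(val, 0.0, 1.0)

    def vertex_values(self, surface: AtrialSurface) -> np.ndarray:
        return self(surface.vertices)


# -- patient shells ---------------------------------------------------------


@dataclass
class PatientShell:
    """A deformed copy of the reference with its exact forward map."""

    surface: AtrialSurface
    rotation: np.ndarray
    translation: np.ndarray
    deform_centers: np.ndarray
    deform_coeffs: np.ndarray
    deform_width: float

    def forward(self, points: np.ndarray) -> np.ndarray:
        """Map reference-frame points into the patient frame."""
        pts = np.atleast_2d(np.asarray(points, float))
        return (pts + self._displacement(pts)) @ self.rotation.T + self.translation

    def _displacement(self, pts: np.ndarray) -> np.ndarray:
        if len(self.deform_centers) == 0:
            return np.zeros_like(pts)
        d2 = np.sum(
            (pts[:, None, :] - self.deform_centers[None, :, :]) ** 2, axis=-1
        )
        w = np.exp(-d2 / (2 * self.deform_width**2))
        return w @ self.deform_coeffs


def make_patient_shell(
    reference: AtrialSurface,
    deformation_scale_mm: float = 3.0,
    seed: int = 0,
    patient_id: str = "patient",
    max_rotation_deg: float = 20.0,
    max_translation_mm: float = 15.0,
    n_deform_centers: int = 6,
    deform_width_mm: float = 25.0,
) -> PatientShell:
    """Random rigid motion plus a smooth low-frequency deformation.

    The exact forward correspondence is returned for oracle use.  A
    deformation that degenerates the mesh is regenerated with damped
    amplitude.
    """
    rng = np.random.default_rng(seed)

    angle = np.deg2rad(rng.uniform(0, max_rotation_deg))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    trans = rng.uniform(-max_translation_mm, max_translation_mm, size=3)

    centroid = reference.vertices.mean(axis=0)
    body_scale = np.ptp(reference.vertices, axis=0).max() / 2

    amplitude = deformation_scale_mm
    for _attempt in range(5):
        if amplitude == 0:
            centers = np.zeros((0, 3))
            coeffs = np.zeros((0, 3))
        else:
            dirs = rng.normal(size=(n_deform_centers, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            centers = centroid + 0.8 * body_scale * dirs
            coeffs = rng.normal(size=(n_deform_centers, 3))

        shell = PatientShell(
            surface=reference,  # placeholder, replaced below
            rotation=rot,
            translation=trans,
            deform_centers=centers,
            deform_coeffs=coeffs,
            deform_width=deform_width_mm,
        )
        if amplitude > 0:
            disp = shell._displacement(reference.vertices)
            peak = np.linalg.norm(disp, axis=1).max()
            shell.deform_coeffs = coeffs * (amplitude / peak)

        new_v = shell.forward(reference.vertices)
        areas = geometry.face_areas(new_v, reference.faces)
        if np.all(np.isfinite(new_v)) and areas.min() > 1e-9:
            shell.surface = AtrialSurface(
                vertices=new_v,
                faces=reference.faces.copy(),
                labels=reference.labels.copy(),
                surface_id=patient_id,
            )
            return shell
        amplitude *= 0.7
        warnings.warn(
            f"{patient_id}: deformation degenerated the mesh; damping to {amplitude:.2f} mm"
        )
    raise RuntimeError(f"{patient_id}: could not generate a valid deformation")


# -- site sampling ----------------------------------------------------------


def sample_sites(
    surface: AtrialSurface,
    n_target: int = 75,
    min_spacing_mm: float = 6.0,
    seed: int = 0,
) -> np.ndarray:
    """Evenly spread HFS site positions on the surface (farthest-point rule).

    The spacing figure is a coverage target (dense, even mapping), not a
    hard minimum separation; sampling is infeasible when ``n_target`` sites
    pairwise ``min_spacing_mm`` apart cannot fit on the surface area.
    """
    if n_target < 1:
        raise SamplingError("n_target must be >= 1")
    area = surface.total_area()
    n_min = int(np.ceil(0.8 * n_target))
    disk = np.pi * (min_spacing_mm / 2.0) ** 2
    achievable = int(1.2 * area / disk) if disk > 0 else n_target
    if n_min * disk > 1.2 * area:
        raise SamplingError(
            f"cannot place {n_min} sites with ~{min_spacing_mm:g} mm spacing on "
            f"{area:.0f} mm^2; at most ~{achievable} sites are achievable",
            achievable=achievable,
        )

    rng = np.random.default_rng(seed)
    pool, _ = geometry.sample_points_on_mesh(
        surface.vertices, surface.faces, max(40 * n_target, 2000), rng
    )
    chosen = [int(rng.integers(len(pool)))]
    dist = np.linalg.norm(pool - pool[chosen[0]], axis=1)
    while len(chosen) < n_target:
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(pool - pool[nxt], axis=1))
    return pool[np.array(chosen)]


def coverage_radius(surface: AtrialSurface, sites: np.ndarray, n_probe: int = 4000, seed: int = 0):
    """Max distance from a random surface probe point to its nearest site."""
    rng = np.random.default_rng(seed)
    probes, _ = geometry.sample_points_on_mesh(surface.vertices, surface.faces, n_probe, rng)
    from scipy.spatial import cKDTree

    d, _ = cKDTree(np.atleast_2d(sites)).query(probes)
    return float(d.max())


# -- beat series synthesis --------------------------------------------------


@dataclass(frozen=True)
class RRParams:
    """Log-normal AF RR-interval model plus response-shape parameters."""

    log_mean: float = float(np.log(700.0))  # ms
    log_sd: float = 0.26
    brady_ratio_range: tuple = (1.6, 2.2)
    asystole_ratio_range: tuple = (3.2, 4.5)
    hfs_duration_ms: float = 10_000.0
    ab_split: float = 0.8  # fraction of AVD-GPs that are asystole (A) type


def _draw_rr(rng: np.random.Generator, params: RRParams, n: int) -> np.ndarray:
    return np.exp(rng.normal(params.log_mean, params.log_sd, size=n))


def synth_beat_series(
    label: SiteLabel, rng: np.random.Generator, params: RRParams
) -> BeatSeries:
    """An R-wave series realizing the requested response label."""
    pre = np.concatenate([[0.0], np.cumsum(_draw_rr(rng, params, 12))])
    hfs_start = pre[-1] + rng.uniform(50.0, 200.0)
    hfs_end = hfs_start + params.hfs_duration_ms
    baseline_mean = float(np.mean(np.diff(pre[-11:])))

    times = list(pre)
    t = hfs_start + rng.uniform(20.0, 80.0)

    if label == SiteLabel.A_AVD_GP:
        times.append(t)
        t += 0.8 * baseline_mean
        times.append(t)
        ratio = rng.uniform(*params.asystole_ratio_range)
        t += ratio * baseline_mean  # the asystolic pause
        times.append(t)
        while t < hfs_end:
            t += float(_draw_rr(rng, params, 1)[0])
            times.append(t)
    elif label == SiteLabel.B_AVD_GP:
        target = rng.uniform(*params.brady_ratio_range)
        times.append(t)
        while t < hfs_end:
            rr = target * baseline_mean * rng.uniform(0.97, 1.03)
            rr = min(rr, 2.25 * baseline_mean)
            t += rr
            times.append(t)
    else:
        while t < hfs_end:
            times.append(t)
            t += float(_draw_rr(rng, params, 1)[0])
        times.append(t)

    for _ in range(3):  # post-HFS recovery beats
        t += float(_draw_rr(rng, params, 1)[0])
        times.append(t)
    return BeatSeries(r_times=np.array(times), hfs_start=hfs_start, hfs_end=hfs_end)


def assign_true_labels(
    site_positions: np.ndarray,
    truth_field: GroundTruthField,
    rr_params: RRParams,
    seed: int = 0,
    field_scale: float = 1.0,
):
    """Draw each site's true label from the field and emit a realizing BeatSeries.

    ``field_scale`` multiplies the local probability (per-patient amplitude
    variation).  Returns (labels, beat_series_list, probabilities).
    """
    rng = np.random.default_rng(seed)
    probs = np.clip(truth_field(site_positions) * field_scale, 0.0, 1.0)
    labels: list[SiteLabel] = []
    series: list[BeatSeries] = []
    for p in probs:
        if rng.random() < p:
            label = (
                SiteLabel.A_AVD_GP
                if rng.random() < rr_params.ab_split
                else SiteLabel.B_AVD_GP
            )
        else:
            label = SiteLabel.NEGATIVE
        labels.append(label)
        series.append(synth_beat_series(label, rng, rr_params))
    return labels, series, probs


def make_af_samples(
    n: int, rr_params: RRParams | None = None, seed: int = 0
) -> list[AFVariabilitySample]:
    """Independent 20 s AF R-wave segments for threshold calibration."""
    rr_params = rr_params or RRParams()
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        n_beats = int(np.ceil(25_000.0 / np.exp(rr_params.log_mean - 2 * rr_params.log_sd)))
        times = np.concatenate([[0.0], np.cumsum(_draw_rr(rng, rr_params, n_beats))])
        samples.append(AFVariabilitySample(r_times=times))
    return samples


# -- cohort assembly --------------------------------------------------------


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort."""

    n_patients: int = 20
    sites_per_patient: int = 75
    sites_sd: float = 0.0  # per-patient spread around the target count
    min_site_spacing_mm: float = 6.0
    deformation_scale_mm: float = 3.0
    hotspots: list | None = None
    base_rate: float = 0.015
    field_scale_sd: float = 0.0  # per-patient amplitude variation (lognormal sd)
    rr_params: RRParams = field(default_factory=RRParams)
    shell_params: ShellParams = field(default_factory=ShellParams)
    seed: int = 0


@dataclass
class PatientRecord:
    patient_id: str
    shell: PatientShell
    sites_reference: np.ndarray  # true positions on the reference surface
    sites_patient: np.ndarray  # the same sites in the patient map frame
    true_labels: list
    beat_series: list
    true_probs: np.ndarray


@dataclass
class Cohort:
    config: CohortConfig
    reference: AtrialSurface
    truth_field: GroundTruthField
    patients: list


def make_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort from one master seed."""
    config = config or CohortConfig()
    reference = make_reference_shell(config.shell_params)
    hotspots = (
        config.hotspots
        if config.hotspots is not None
        else default_hotspots(config.shell_params, surface=reference)
    )
    truth = GroundTruthField(hotspots=hotspots, base_rate=config.base_rate)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_patients + 1)
    top_rng = np.random.default_rng(seeds[0])

    patients = []
    for i in range(config.n_patients):
        pid = f"p{i:03d}"
        child = np.random.default_rng(seeds[i + 1])
        sub = child.integers(0, 2**31 - 1, size=4)

        shell = make_patient_shell(
            reference,
            deformation_scale_mm=config.deformation_scale_mm,
            seed=int(sub[0]),
            patient_id=pid,
        )
        n_sites = config.sites_per_patient
        if config.sites_sd > 0:
            n_sites = int(
                np.clip(
                    round(child.normal(config.sites_per_patient, config.sites_sd)),
                    int(0.8 * config.sites_per_patient),
                    int(1.2 * config.sites_per_patient),
                )
            )
        sites_ref = sample_sites(
            reference, n_target=n_sites, min_spacing_mm=config.min_site_spacing_mm,
            seed=int(sub[1]),
        )
        field_scale = (
            float(np.exp(child.normal(0.0, config.field_scale_sd)))
            if config.field_scale_sd > 0
            else 1.0
        )
        labels, series, probs = assign_true_labels(
            sites_ref, truth, config.rr_params, seed=int(sub[2]), field_scale=field_scale
        )
        patients.append(
            PatientRecord(
                patient_id=pid,
                shell=shell,
                sites_reference=sites_ref,
                sites_patient=shell.forward(sites_ref),
                true_labels=labels,
                beat_series=series,
                true_probs=probs,
            )
        )
    return Cohort(config=config, reference=reference, truth_field=truth, patients=patients)
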