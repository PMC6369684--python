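"""Kernel probability fields of AVD-GP outcome on the reference surface.

Per patient, each mapped site carries a binary outcome (1 = AVD-GP, 0 =
negative HFS response).  The per-vertex probability is the Gaussian-kernel
weighted average of nearby outcomes (Nadaraya-Watson smoothing with a 3D
Euclidean metric), undefined where total kernel weight is negligible.
Patient fields are averaged vertex-wise across the cohort, peaks are
extracted as edge-connected super-threshold components, and the atlas is
summarized by the fraction of surface area needed to contain a given share
of the AVD-GP sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from gp_atlas import geometry
from gp_atlas.errors import ConfigurationError
from gp_atlas.surface import AtrialSurface

__all__ = [
    "DEFAULT_SIGMA_MM",
    "DEFAULT_PEAK_THRESHOLD",
    "MappedSite",
    "ProbabilityField",
    "AtlasPeak",
    "patient_field",
    "cohort_average",
    "find_peaks",
    "area_concentration",
]

#: Gaussian kernel scale (mm): the catheter-position uncertainty radius.
DEFAULT_SIGMA_MM = 5.0
#: Peaks are components with probability strictly above this value.
DEFAULT_PEAK_THRESHOLD = 0.20


@dataclass(frozen=True)
class MappedSite:
    """A stimulated site transformed onto the reference surface."""

    patient_id: str
    position: np.ndarray  # (3,) mm, on/near the reference surface
    p: int  # 1 = AVD-GP (either subtype), 0 = negative

    def __post_init__(self) -> None:
        if self.p not in (0, 1):
            raise ConfigurationError(f"site outcome must be binary, got {self.p}")


@dataclass
class ProbabilityField:
    """Per-vertex AVD-GP probability on a reference surface.

    ``values`` holds NaN where the field is undefined (insufficient kernel
    weight for a patient field; zero patient coverage for a cohort field).
    """

    surface: AtrialSurface
    sigma_mm: float
    values: np.ndarray
    coverage_count: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.coverage_count is None:
            self.coverage_count = np.where(np.isfinite(self.values), 1, 0)
        defined = self.defined_values
        if defined.size and (defined.min() < -1e-12 or defined.max() > 1 + 1e-12):
            raise ConfigurationError("defined probabilities must lie in [0, 1]")

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def defined_values(self) -> np.ndarray:
        return self.values[self.defined_mask]


def _default_weight_cutoff(sigma_mm: float) -> float:
    # Kernel value at 3 sigma; beyond this the field is masked as undefined.
    return float(np.exp(-9.0 / 2.0))


def patient_field(
    sites: list[MappedSite],
    surface: AtrialSurface,
    sigma_mm: float = DEFAULT_SIGMA_MM,
    weight_cutoff: float | None = None,
) -> ProbabilityField:
    """Kernel-weighted outcome probability at every reference vertex.

    value(x) = sum_i p_i w_i / sum_i w_i with w_i = exp(-d(x, x_i)^2 / (2 sigma^2)),
    d the 3D Euclidean distance; undefined where sum_i w_i < weight_cutoff
    (default: the kernel value at 3 sigma).
    """
    if not sites:
        raise ConfigurationError("patient_field requires at least one site")
    if sigma_mm <= 0:
        raise ConfigurationError("sigma_mm must be positive")
    cutoff = _default_weight_cutoff(sigma_mm) if weight_cutoff is None else weight_cutoff

    positions = np.vstack([s.position for s in sites])
    p = np.array([s.p for s in sites], dtype=float)
    d2 = cdist(surface.vertices, positions, metric="sqeuclidean")
    w = np.exp(-d2 / (2.0 * sigma_mm**2))
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (w @ p) / wsum
    values[wsum < cutoff] = np.nan
    return ProbabilityField(surface=surface, sigma_mm=sigma_mm, values=values)


def cohort_average(fields: list[ProbabilityField]) -> ProbabilityField:
    """Vertex-wise masked mean across patients.

    A vertex's average uses only the patients whose field is defined there
    (patients without local site coverage are excluded rather than imputed
    as zero); it stays undefined where no patient contributes.
    """
    if not fields:
        raise ConfigurationError("cohort_average requires at least one field")
    first = fields[0]
    for f in fields[1:]:
        if f.values.shape != first.values.shape or f.sigma_mm != first.sigma_mm:
            raise ConfigurationError("fields must share the reference surface and sigma")
        if not np.array_equal(f.surface.vertices.shape, first.surface.vertices.shape):
            raise ConfigurationError("fields must share the reference surface")

    stack = np.vstack([f.values for f in fields])
    count = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, np.nansum(np.nan_to_num(stack), axis=0), np.nan)
        mean = np.where(count > 0, mean / np.maximum(count, 1), np.nan)
    return ProbabilityField(
        surface=first.surface,
        sigma_mm=first.sigma_mm,
        values=mean,
        coverage_count=count,
    )


@dataclass
class AtlasPeak:
    """One edge-connected super-threshold component of the atlas."""

    component_id: int
    peak_vertex: int
    peak_probability: float
    member_vertices: np.ndarray
    annotation: str = ""

    def to_dict(self) -> dict:
        return {
            "component_id": self.component_id,
            "peak_vertex": int(self.peak_vertex),
            "peak_probability": float(self.peak_probability),
            "member_vertices": np.asarray(self.member_vertices).tolist(),
            "annotation": self.annotation,
        }


def find_peaks(
    field: ProbabilityField, threshold: float = DEFAULT_PEAK_THRESHOLD
) -> list[AtlasPeak]:
    """Edge-connected components of vertices with probability > threshold.

    Components are returned sorted by peak probability, descending; the
    inequality is strict, so a threshold of 1.0 never yields peaks.
    """
    mask = field.defined_mask & (np.nan_to_num(field.values, nan=-np.inf) > threshold)
    if not mask.any():
        return []
    n_comp, labels = geometry.connected_components(
        len(field.surface.vertices), field.surface.faces, mask
    )
    peaks = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        peak_vertex = members[np.argmax(field.values[members])]
        peaks.append(
            AtlasPeak(
                component_id=comp,
                peak_vertex=int(peak_vertex),
                peak_probability=float(field.values[peak_vertex]),
                member_vertices=members,
            )
        )
    peaks.sort(key=lambda pk: -pk.peak_probability)
    for i, pk in enumerate(peaks):
        pk.component_id = i
    return peaks


def area_concentration(
    field: ProbabilityField,
    gp_site_positions: np.ndarray,
    site_coverage: float = 0.90,
) -> float:
    """Fraction of total surface area covering ``site_coverage`` of the GP sites.

    Triangles are ranked by their mean vertex probability (undefined vertices
    count as 0; ties break by triangle index) and accumulated greedily until
    the covered triangles contain at least the requested share of AVD-GP
    sites, each site belonging to the triangle nearest to it.
    """
    positions = np.atleast_2d(np.asarray(gp_site_positions, float))
    if positions.size == 0:
        raise ConfigurationError("area_concentration requires at least one AVD-GP site")
    if not 0 < site_coverage <= 1:
        raise ConfigurationError("site_coverage must lie in (0, 1]")

    surf = field.surface
    tri_vals = np.nan_to_num(field.values, nan=0.0)[surf.faces].mean(axis=1)
    areas = geometry.face_areas(surf.vertices, surf.faces)
    _, _, site_tri = surf.projector()(positions)

    order = np.lexsort((np.arange(len(tri_vals)), -tri_vals))
    needed = site_coverage * len(positions)
    sites_per_tri = np.bincount(site_tri, minlength=len(tri_vals))

    got = 0.0
    acc_area = 0.0
    for t in order:
        acc_area += areas[t]
        got += sites_per_tri[t]
        if got >= needed - 1e-12:
            break
    return float(acc_area / areas.sum())


def save_peaks_json(peaks: list[AtlasPeak], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in peaks], fh, indent=1)
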