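"""End-to-end pipeline: simulate -> classify -> register -> atlas -> report.

Every stage is a pure function of (inputs, config, seed); the run writes a
report bundle (labels.csv, per-patient registration JSONs, atlas CSV/VTK,
peaks.json, summary.json) and aborts with the failing stage's name on error,
keeping partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from gp_atlas import io as gio
from gp_atlas import records
from gp_atlas import registration as greg
from gp_atlas import synthetic as syn
from gp_atlas.atlas import (
    MappedSite,
    area_concentration,
    cohort_average,
    find_peaks,
    patient_field,
    save_peaks_json,
)
from gp_atlas.beats import SiteLabel, derive_asystole_threshold
from gp_atlas.errors import PipelineStageError

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("gp_atlas.pipeline")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; every threshold is surfaced here."""

    seed: int = 0
    n_patients: int = 20
    sites_per_patient: int = 75
    sites_sd: float = 0.0
    min_site_spacing_mm: float = 6.0
    deformation_scale_mm: float = 3.0
    mean_increase_threshold: float = 1.5
    asystole_ratio_threshold: float = 2.5
    calibration_tail_mass: float = 0.01
    n_af_samples: int = 75
    sigma_mm: float = 5.0
    peak_threshold: float = 0.20
    site_coverage: float = 0.90
    landmarks_per_ring: int = 8
    phase_grid_steps: int = 16
    field_scale_sd: float = 0.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in (
            "mean_increase_threshold",
            "asystole_ratio_threshold",
            "peak_threshold",
            "sigma_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        pathlib.Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    cohort: syn.Cohort
    labels_table: "object"
    registrations: dict
    mapped_sites: list
    atlas_field: "object"
    peaks: list
    summary: dict


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s ...", name)
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - wrap with stage context
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig, outdir: pathlib.Path) -> syn.Cohort:
    cohort = syn.make_cohort(
        syn.CohortConfig(
            n_patients=config.n_patients,
            sites_per_patient=config.sites_per_patient,
            sites_sd=config.sites_sd,
            min_site_spacing_mm=config.min_site_spacing_mm,
            deformation_scale_mm=config.deformation_scale_mm,
            field_scale_sd=config.field_scale_sd,
            seed=config.seed,
        )
    )
    meshes = outdir / "meshes"
    meshes.mkdir(parents=True, exist_ok=True)
    gio.save_surface(cohort.reference, meshes / "reference.ply", labels_path=meshes / "reference_labels.csv")
    entries3, entries4 = [], []
    truth = {}
    for pat in cohort.patients:
        gio.save_surface(
            pat.shell.surface,
            meshes / f"{pat.patient_id}.ply",
            labels_path=meshes / f"{pat.patient_id}_labels.csv",
        )
        truth[pat.patient_id] = {
            "labels": [lab.value for lab in pat.true_labels],
            "probs": pat.true_probs.tolist(),
            "sites_reference": pat.sites_reference.tolist(),
        }
        for j, series in enumerate(pat.beat_series):
            sid = f"s{j:03d}"
            entries3.append((pat.patient_id, sid, series))
            entries4.append((pat.patient_id, sid, series, pat.sites_patient[j]))
    records.write_beats_csv(entries3, outdir / "beats.csv")
    records.write_sites_csv(entries4, outdir / "sites.csv")
    (outdir / "truth.json").write_text(json.dumps(truth))
    return cohort


@_stage("calibrate")
def _calibrate(config: PipelineConfig):
    samples = syn.make_af_samples(config.n_af_samples, seed=config.seed + 90_001)
    return derive_asystole_threshold(samples, tail_mass=config.calibration_tail_mass)


@_stage("classify")
def _classify(config: PipelineConfig, cohort: syn.Cohort, outdir: pathlib.Path):
    entries = []
    for pat in cohort.patients:
        for j, series in enumerate(pat.beat_series):
            entries.append((pat.patient_id, f"s{j:03d}", series))
    table = records.classify_table(
        entries,
        mean_increase_threshold=config.mean_increase_threshold,
        asystole_ratio_threshold=config.asystole_ratio_threshold,
    )
    records.write_labels_csv(table, outdir / "labels.csv")
    return table


@_stage("register")
def _register(config: PipelineConfig, cohort: syn.Cohort, outdir: pathlib.Path):
    regdir = outdir / "registrations"
    regdir.mkdir(parents=True, exist_ok=True)
    registrations = {}
    for pat in cohort.patients:
        reg = greg.register_surfaces(
            pat.shell.surface,
            cohort.reference,
            n_per_ring=config.landmarks_per_ring,
            grid_steps=config.phase_grid_steps,
        )
        reg.save(regdir / f"{pat.patient_id}.json")
        registrations[pat.patient_id] = reg
        log.info("registered %s: TRE %.2f mm", pat.patient_id, reg.tre_mm)
    return registrations


@_stage("atlas")
def _atlas(config: PipelineConfig, cohort: syn.Cohort, labels_table, registrations, outdir):
    by_patient = {p.patient_id: p for p in cohort.patients}
    mapped = []
    fields = []
    for pid, group in labels_table.groupby("patient_id", sort=True):
        pat = by_patient[pid]
        reg = registrations[pid]
        positions, _ = greg.transform_to_reference(
            reg, pat.sites_patient, cohort.reference
        )
        p_outcomes = (group.sort_values("site_id")["label"] != SiteLabel.NEGATIVE.value).to_numpy()
        sites = [
            MappedSite(patient_id=pid, position=pos, p=int(out))
            for pos, out in zip(positions, p_outcomes)
        ]
        mapped.extend(sites)
        fields.append(patient_field(sites, cohort.reference, sigma_mm=config.sigma_mm))
    atlas_field = cohort_average(fields)
    peaks = find_peaks(atlas_field, threshold=config.peak_threshold)

    # exports
    import pandas as pd

    pd.DataFrame(
        {
            "vertex_id": np.arange(len(atlas_field.values)),
            "probability": atlas_field.values,
            "coverage_count": atlas_field.coverage_count,
        }
    ).to_csv(outdir / "atlas.csv", index=False)
    gio.write_vtk_with_scalars(
        cohort.reference,
        outdir / "atlas.vtk",
        {"avd_gp_probability": np.nan_to_num(atlas_field.values, nan=-1.0)},
    )
    save_peaks_json(peaks, outdir / "peaks.json")
    return mapped, atlas_field, peaks


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Run all stages and write the report bundle into ``outdir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    cohort = _simulate(config, outdir)
    calibration = _calibrate(config)
    labels_table = _classify(config, cohort, outdir)
    registrations = _register(config, cohort, outdir)
    mapped, atlas_field, peaks = _atlas(
        config, cohort, labels_table, registrations, outdir
    )

    try:
        gp_positions = np.vstack(
            [s.position for s in mapped if s.p == 1]
        ) if any(s.p == 1 for s in mapped) else None
        area_frac = (
            area_concentration(atlas_field, gp_positions, config.site_coverage)
            if gp_positions is not None
            else float("nan")
        )

        n_sites = len(labels_table)
        n_a = int((labels_table["label"] == SiteLabel.A_AVD_GP.value).sum())
        n_b = int((labels_table["label"] == SiteLabel.B_AVD_GP.value).sum())
        n_gp = n_a + n_b
        tres = np.array([r.tre_mm for r in registrations.values()])
        summary = {
            "seed": config.seed,
            "n_patients": config.n_patients,
            "hfs_sites_tested": n_sites,
            "avd_gp_identified": n_gp,
            "avd_gp_fraction": n_gp / n_sites if n_sites else float("nan"),
            "a_avd_gp": n_a,
            "a_fraction_of_gp": n_a / n_gp if n_gp else float("nan"),
            "b_avd_gp": n_b,
            "b_fraction_of_gp": n_b / n_gp if n_gp else float("nan"),
            "tre_mean_mm": float(tres.mean()),
            "tre_sd_mm": float(tres.std(ddof=1)) if len(tres) > 1 else 0.0,
            "area_fraction_for_site_coverage": area_frac,
            "site_coverage": config.site_coverage,
            "peaks": [
                {"peak_probability": p.peak_probability, "peak_vertex": p.peak_vertex}
                for p in peaks
            ],
            "calibration": {
                "derived_ratio_threshold": calibration.derived_ratio_threshold,
                "z": calibration.z,
                "normality_p": calibration.normality_p,
                "operational_threshold": config.asystole_ratio_threshold,
            },
            "thresholds": {
                "mean_increase": config.mean_increase_threshold,
                "asystole_ratio": config.asystole_ratio_threshold,
                "peak": config.peak_threshold,
                "sigma_mm": config.sigma_mm,
                "landmarks_per_ring": config.landmarks_per_ring,
                "phase_grid_steps": config.phase_grid_steps,
            },
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("report", exc) from exc

    return PipelineResult(
        cohort=cohort,
        labels_table=labels_table,
        registrations=registrations,
        mapped_sites=mapped,
        atlas_field=atlas_field,
        peaks=peaks,
        summary=summary,
    )
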