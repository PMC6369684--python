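# gp-atlas

Toolkit for mapping atrioventricular-dissociating ganglionated plexus
(AVD-GP) sites in the left atrium:

1. **Response classification** (`gp_atlas.beats`) — turns R-wave time series
   around an endocardial high-frequency-stimulation (HFS) window into RR
   statistics and a site label (`A_AVD_GP` asystole / `B_AVD_GP` bradycardia
   / `NEGATIVE`), and calibrates the asystole ratio threshold from baseline
   AF RR-variability samples (log-normal one-tailed 1 % quantile; the
   operational default is 2.5× the baseline mean RR, i.e. a 150 % single-RR
   increase).
2. **Surface geometry** (`gp_atlas.surface`, `gp_atlas.io`) — labeled
   triangulated left-atrial meshes (body, 4 PVs, mitral rim), read/written as
   ASCII PLY / OBJ / legacy VTK / a CSV dialect, with circumferential
   equal-angle landmark rings generated at the PV-atrial junction planes of
   maximum surface curvature.
3. **Registration** (`gp_atlas.registration`) — per-patient coregistration
   onto a reference shell: angle-based fiducial phase selection, Procrustes
   similarity, thin-plate-spline warp, closest-point surface projection, and
   held-out target registration error (TRE).
4. **Probability atlas** (`gp_atlas.atlas`) — per-patient Gaussian-kernel
   (σ = 5 mm) weighted outcome fields on the reference surface, masked
   cohort averaging, peak components above 20 % probability, and the
   area-fraction statistic covering a given share of GP sites.
5. **Synthetic cohort** (`gp_atlas.synthetic`) — seeded generator for the
   reference shell, deformed patient shells with exact forward
   correspondence, evenly spread HFS site layouts, hotspot-structured ground
   truth fields, and R-wave series realizing each site's true label.
6. **Pipeline / CLI** (`gp_atlas.pipeline`, `gp_atlas.cli`) — one-command
   orchestration with a YAML config.

## CLI

```bash
# full synthetic run: simulate -> classify -> register -> atlas -> report
gp-atlas run --config pipeline.yaml --out out/

# individual stages
gp-atlas simulate  --out cohort/ --seed 1 --n-patients 20
gp-atlas classify  --beats cohort/beats.csv --sites cohort/sites.csv \
                   --mean-threshold 1.5 --asystole-threshold 2.5 --out labels.csv
gp-atlas calibrate --af-samples af.csv --tail 0.01
gp-atlas register  --source patient.ply --reference ref.ply \
                   --landmarks-per-ring 8 --grid 16 --out reg.json
gp-atlas atlas     --reference ref.ply --registrations reg/p000.json \
                   --labels labels.csv --sites cohort/sites.csv \
                   --sigma 5 --peak-threshold 0.2 --out atlas_out/
```

`pipeline.yaml` holds every constant with its default (mean-increase ratio
1.5, asystole ratio 2.5, kernel σ 5 mm, peak threshold 0.20, calibration
tail 0.01, 8 landmarks per ring, 16 phase grid steps, seed); write one with
`python -c "from gp_atlas.pipeline import PipelineConfig; PipelineConfig().to_yaml('pipeline.yaml')"`.

The run directory contains `labels.csv`, `registrations/*.json`,
`atlas.csv` / `atlas.vtk`, `peaks.json`, `summary.json` (site counts, AVD-GP
fraction, A/B split, per-patient TRE mean ± SD, area-concentration value),
plus the simulated inputs (`meshes/`, `beats.csv`, `sites.csv`,
`truth.json`).

## Data formats

* `beats.csv`: `patient_id, site_id, r_time_ms` (one row per beat)
* `sites.csv`: `patient_id, site_id, hfs_start_ms, hfs_end_ms, x_mm, y_mm, z_mm`
* mesh CSV dialect: `vertices.csv` (`vertex_id, x_mm, y_mm, z_mm, label`) +
  `faces.csv` (`v0, v1, v2`), 0-based indices; labels from
  `{BODY, LSPV, RSPV, LIPV, RIPV, MV_RIM}`
* other mesh formats carry labels in a sidecar CSV (`vertex_id, label`)

All coordinates are millimetres; all times are milliseconds.
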