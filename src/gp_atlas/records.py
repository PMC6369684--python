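"""Tabular record I/O: R-peak series, HFS site tables, classification reports.

CSV layouts
-----------
beats.csv : patient_id, site_id, r_time_ms           (one row per beat)
sites.csv : patient_id, site_id, hfs_start_ms, hfs_end_ms[, x_mm, y_mm, z_mm]
labels.csv: patient_id, site_id, baseline_mean_rr, hfs_mean_rr, hfs_max_rr,
            mean_ratio, max_ratio, label
af.csv    : sample_id, r_time_ms                     (one row per beat)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gp_atlas.beats import (
    AFVariabilitySample,
    BeatSeries,
    RRStats,
    SiteLabel,
    classify_series,
)

__all__ = [
    "write_beats_csv",
    "write_sites_csv",
    "read_beat_series",
    "classify_table",
    "write_labels_csv",
    "read_labels_csv",
    "write_af_csv",
    "read_af_samples",
]


def write_beats_csv(entries, path) -> None:
    """entries: iterable of (patient_id, site_id, BeatSeries)."""
    rows = []
    for pid, sid, series in entries:
        for t in series.r_times:
            rows.append((pid, sid, t))
    pd.DataFrame(rows, columns=["patient_id", "site_id", "r_time_ms"]).to_csv(
        path, index=False
    )


def write_sites_csv(entries, path) -> None:
    """entries: iterable of (patient_id, site_id, BeatSeries, position or None)."""
    rows = []
    for pid, sid, series, pos in entries:
        x, y, z = (np.nan, np.nan, np.nan) if pos is None else tuple(pos)
        rows.append((pid, sid, series.hfs_start, series.hfs_end, x, y, z))
    pd.DataFrame(
        rows,
        columns=["patient_id", "site_id", "hfs_start_ms", "hfs_end_ms", "x_mm", "y_mm", "z_mm"],
    ).to_csv(path, index=False)


def read_beat_series(beats_path, sites_path):
    """Join beats.csv and sites.csv into per-site BeatSeries.

    Returns a list of (patient_id, site_id, BeatSeries, position-or-None).
    """
    beats = pd.read_csv(beats_path)
    sites = pd.read_csv(sites_path)
    grouped = beats.groupby(["patient_id", "site_id"])["r_time_ms"]
    out = []
    for row in sites.itertuples(index=False):
        r = grouped.get_group((row.patient_id, row.site_id)).to_numpy(float)
        series = BeatSeries(
            r_times=np.sort(r), hfs_start=row.hfs_start_ms, hfs_end=row.hfs_end_ms
        )
        pos = None
        if hasattr(row, "x_mm") and np.isfinite(row.x_mm):
            pos = np.array([row.x_mm, row.y_mm, row.z_mm])
        out.append((row.patient_id, row.site_id, series, pos))
    return out


def classify_table(
    entries, mean_increase_threshold: float = 1.5, asystole_ratio_threshold: float = 2.5
) -> pd.DataFrame:
    """Classification report for (patient_id, site_id, BeatSeries[, pos]) entries."""
    rows = []
    for entry in entries:
        pid, sid, series = entry[0], entry[1], entry[2]
        stats, label = classify_series(
            series, mean_increase_threshold, asystole_ratio_threshold
        )
        rows.append(
            {
                "patient_id": pid,
                "site_id": sid,
                "baseline_mean_rr": stats.baseline_mean_rr,
                "hfs_mean_rr": stats.hfs_mean_rr,
                "hfs_max_rr": stats.hfs_max_rr,
                "mean_ratio": stats.mean_ratio,
                "max_ratio": stats.max_ratio,
                "label": label.value,
            }
        )
    return pd.DataFrame(rows)


def write_labels_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["label"] = df["label"].map(SiteLabel)
    return df


def write_af_csv(samples, path) -> None:
    rows = []
    for i, s in enumerate(samples):
        for t in s.r_times:
            rows.append((i, t))
    pd.DataFrame(rows, columns=["sample_id", "r_time_ms"]).to_csv(path, index=False)


def read_af_samples(path) -> list[AFVariabilitySample]:
    df = pd.read_csv(path)
    return [
        AFVariabilitySample(r_times=np.sort(g.to_numpy(float)))
        for _, g in df.groupby("sample_id")["r_time_ms"]
    ]
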