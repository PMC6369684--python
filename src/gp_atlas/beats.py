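"""RR-interval analysis of high-frequency stimulation (HFS) responses.

An HFS application at an endocardial site either leaves ventricular rhythm
unchanged, produces a sustained bradycardic slowing, or provokes transient
ventricular asystole.  This module turns an R-wave time series around an HFS
window into summary RR statistics, labels the site, and calibrates the
asystole ratio threshold from baseline AF RR-variability samples.

All times are milliseconds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from gp_atlas.errors import ConfigurationError, SeriesRejected

__all__ = [
    "BeatSeries",
    "RRStats",
    "SiteLabel",
    "AFVariabilitySample",
    "ThresholdDerivation",
    "baseline_mean_rr",
    "hfs_rr_stats",
    "classify_site",
    "classify_series",
    "derive_asystole_threshold",
    "one_tailed_z",
    "DEFAULT_MEAN_INCREASE_THRESHOLD",
    "DEFAULT_ASYSTOLE_RATIO_THRESHOLD",
]

#: Mean-RR increase defining an AVD response (ratio >= 1.5, i.e. >= 50 %).
DEFAULT_MEAN_INCREASE_THRESHOLD = 1.5
#: Single-RR prolongation defining asystole (ratio strictly > 2.5).
DEFAULT_ASYSTOLE_RATIO_THRESHOLD = 2.5

#: Number of pre-HFS RR intervals averaged for the baseline.
N_BASELINE_INTERVALS = 10


class SiteLabel(str, enum.Enum):
    """Outcome label for a stimulated site."""

    A_AVD_GP = "A_AVD_GP"  # asystole response
    B_AVD_GP = "B_AVD_GP"  # bradycardia response
    NEGATIVE = "NEGATIVE"  # no AV-dissociating effect


@dataclass(frozen=True)
class BeatSeries:
    """R-wave timestamps around one HFS application.

    Parameters
    ----------
    r_times:
        Strictly increasing R-wave times in ms.
    hfs_start, hfs_end:
        Stimulation window in ms, ``hfs_start < hfs_end``.
    source:
        Channel the R-peaks were extracted from ("arterial" pressure peaks
        or "ventricular" electrogram); metadata only.
    """

    r_times: np.ndarray
    hfs_start: float
    hfs_end: float
    source: str = "arterial"

    def __post_init__(self) -> None:
        r = np.asarray(self.r_times, dtype=float)
        object.__setattr__(self, "r_times", r)
        if r.ndim != 1 or r.size < 2:
            raise SeriesRejected("need at least two R-wave times")
        if not np.all(np.diff(r) > 0):
            raise SeriesRejected("R-wave times must be strictly increasing")
        if not self.hfs_start < self.hfs_end:
            raise SeriesRejected("hfs_start must precede hfs_end")
        n_pre = int(np.sum(r < self.hfs_start))
        if n_pre < N_BASELINE_INTERVALS + 1:
            raise SeriesRejected(
                f"only {n_pre} R-waves precede HFS; "
                f"{N_BASELINE_INTERVALS + 1} required for a 10-interval baseline"
            )

    @property
    def pre_hfs_times(self) -> np.ndarray:
        return self.r_times[self.r_times < self.hfs_start]


@dataclass(frozen=True)
class RRStats:
    """Summary RR statistics of one HFS application."""

    baseline_mean_rr: float
    hfs_mean_rr: float
    hfs_max_rr: float

    def __post_init__(self) -> None:
        for name in ("baseline_mean_rr", "hfs_mean_rr", "hfs_max_rr"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")

    @property
    def mean_ratio(self) -> float:
        return self.hfs_mean_rr / self.baseline_mean_rr

    @property
    def max_ratio(self) -> float:
        return self.hfs_max_rr / self.baseline_mean_rr


def baseline_mean_rr(series: BeatSeries) -> float:
    """Mean of the 10 RR intervals immediately preceding HFS, in ms."""
    pre = series.pre_hfs_times
    intervals = np.diff(pre[-(N_BASELINE_INTERVALS + 1):])
    return float(np.mean(intervals))


def hfs_rr_stats(series: BeatSeries, horizon_ms: float = 30_000.0) -> RRStats:
    """RR statistics over the HFS window.

    The mean HFS RR spans from the first R-wave at/after ``hfs_start`` to the
    first R-wave at/after ``hfs_end``, divided by the number of RR intervals
    in that span.  The max HFS RR is the longest single interval whose right
    endpoint falls in ``(hfs_start, t_last]``.  If no R-wave occurs during
    stimulation, the bridging interval from the last pre-HFS R to the first
    post-HFS R is used for both statistics.

    Raises
    ------
    SeriesRejected
        If no R-wave follows ``hfs_end`` within ``horizon_ms`` (the recording
        is considered truncated).
    """
    r = series.r_times
    base = baseline_mean_rr(series)

    after_end = np.flatnonzero(r >= series.hfs_end)
    if after_end.size == 0 or r[after_end[0]] > series.hfs_end + horizon_ms:
        raise SeriesRejected(
            f"no R-wave within {horizon_ms:g} ms after HFS cessation; recording truncated"
        )
    i_last = int(after_end[0])
    t_last = r[i_last]

    at_or_after_start = np.flatnonzero(r >= series.hfs_start)
    i_first = int(at_or_after_start[0])
    k = i_last - i_first

    if k == 0:
        # Complete asystole: no beat inside the window.  Bridge from the last
        # pre-HFS R to the first post-HFS R.
        i_pre = i_first - 1
        bridge = float(t_last - r[i_pre])
        return RRStats(baseline_mean_rr=base, hfs_mean_rr=bridge, hfs_max_rr=bridge)

    t_first = r[i_first]
    hfs_mean = float((t_last - t_first) / k)

    # Intervals whose right endpoint lies in (hfs_start, t_last].
    right = r[1 : i_last + 1]
    mask = right > series.hfs_start
    intervals = np.diff(r)[: i_last][mask]
    hfs_max = float(np.max(intervals))

    return RRStats(baseline_mean_rr=base, hfs_mean_rr=hfs_mean, hfs_max_rr=hfs_max)


def classify_site(
    stats: RRStats,
    mean_increase_threshold: float = DEFAULT_MEAN_INCREASE_THRESHOLD,
    asystole_ratio_threshold: float = DEFAULT_ASYSTOLE_RATIO_THRESHOLD,
) -> SiteLabel:
    """Label a site from its RR statistics.

    Asystole (``A_AVD_GP``) when the max single-RR ratio strictly exceeds the
    asystole threshold; else bradycardia (``B_AVD_GP``) when the mean-RR ratio
    meets the inclusive mean-increase threshold; else ``NEGATIVE``.
    """
    if mean_increase_threshold <= 0 or asystole_ratio_threshold <= 0:
        raise ConfigurationError("classification thresholds must be positive")
    if stats.max_ratio > asystole_ratio_threshold:
        return SiteLabel.A_AVD_GP
    if stats.mean_ratio >= mean_increase_threshold:
        return SiteLabel.B_AVD_GP
    return SiteLabel.NEGATIVE


def classify_series(
    series: BeatSeries,
    mean_increase_threshold: float = DEFAULT_MEAN_INCREASE_THRESHOLD,
    asystole_ratio_threshold: float = DEFAULT_ASYSTOLE_RATIO_THRESHOLD,
) -> tuple[RRStats, SiteLabel]:
    """Convenience wrapper: series -> (stats, label)."""
    stats = hfs_rr_stats(series)
    return stats, classify_site(stats, mean_increase_threshold, asystole_ratio_threshold)


@dataclass(frozen=True)
class AFVariabilitySample:
    """A 20 s AF R-wave segment used to calibrate the asystole threshold.

    The derived ratio is (longest RR interval in the last 10 s) divided by
    (mean RR interval of the first 10 s).
    """

    r_times: np.ndarray
    window_ms: float = 20_000.0

    def __post_init__(self) -> None:
        r = np.asarray(self.r_times, dtype=float)
        object.__setattr__(self, "r_times", r)
        if r.ndim != 1 or r.size < 3:
            raise SeriesRejected("AF sample needs at least three beats")
        if not np.all(np.diff(r) > 0):
            raise SeriesRejected("R-wave times must be strictly increasing")
        if r[-1] - r[0] < self.window_ms:
            raise SeriesRejected(
                f"AF sample spans {r[-1] - r[0]:.0f} ms; {self.window_ms:.0f} ms required"
            )

    @property
    def ratio(self) -> float:
        r = self.r_times
        t0 = r[0]
        mid = t0 + self.window_ms / 2
        end = t0 + self.window_ms
        intervals = np.diff(r)
        right = r[1:]
        first_half = intervals[right <= mid]
        second_half = intervals[(right > mid) & (right <= end)]
        if first_half.size == 0 or second_half.size == 0:
            raise SeriesRejected("AF sample has an empty half-window")
        return float(np.max(second_half) / np.mean(first_half))


@dataclass(frozen=True)
class ThresholdDerivation:
    """Result of calibrating the asystole ratio threshold from AF variability."""

    log_ratios: np.ndarray
    normality_p: float
    mu_log: float
    sd_log: float
    z: float
    derived_ratio_threshold: float
    operational_threshold: float = DEFAULT_ASYSTOLE_RATIO_THRESHOLD
    tail_mass: float = field(default=0.01)


def one_tailed_z(tail_mass: float) -> float:
    """Standard-normal upper quantile at a one-tailed tail mass."""
    if not 0 < tail_mass < 1:
        raise ConfigurationError("tail_mass must lie in (0, 1)")
    return float(sps.norm.ppf(1.0 - tail_mass))


def derive_asystole_threshold(
    samples,
    tail_mass: float = 0.01,
    operational_threshold: float = DEFAULT_ASYSTOLE_RATIO_THRESHOLD,
) -> ThresholdDerivation:
    """Calibrate the single-RR asystole ratio threshold from AF variability.

    Each sample's ratio is log-transformed; a Shapiro-Wilk normality p-value
    is reported (not enforced); the threshold is the log-normal upper
    quantile ``exp(mu + z * sd)`` with ``z`` the one-tailed standard-normal
    quantile at ``tail_mass``.

    Parameters
    ----------
    samples:
        Iterable of :class:`AFVariabilitySample` or of bare positive ratios.
    """
    ratios = np.asarray(
        [s.ratio if isinstance(s, AFVariabilitySample) else float(s) for s in samples],
        dtype=float,
    )
    if ratios.size < 3:
        raise SeriesRejected(f"need at least 3 AF samples, got {ratios.size}")
    if np.any(ratios <= 0) or not np.all(np.isfinite(ratios)):
        raise SeriesRejected("all AF-variability ratios must be positive and finite")

    log_ratios = np.log(ratios)
    # Shapiro-Wilk is defined up to n = 5000; subsample deterministically beyond.
    sw_input = log_ratios if log_ratios.size <= 5000 else log_ratios[:5000]
    if np.ptp(sw_input) == 0:
        normality_p = float("nan")  # Shapiro-Wilk undefined for constant data
    else:
        normality_p = float(sps.shapiro(sw_input).pvalue)

    mu = float(np.mean(log_ratios))
    sd = float(np.std(log_ratios, ddof=1))
    z = one_tailed_z(tail_mass)
    return ThresholdDerivation(
        log_ratios=log_ratios,
        normality_p=normality_p,
        mu_log=mu,
        sd_log=sd,
        z=z,
        derived_ratio_threshold=float(np.exp(mu + z * sd)),
        operational_threshold=operational_threshold,
        tail_mass=tail_mass,
    )
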