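"""Whole-chromosomal-arm mosaicism screening from BAF dispersion.

A germline diploid arm shows heterozygote BAF tightly clustered at 0.5;
an arm that is mosaic for a loss or gain in a fraction ``f`` of cells
splits the heterozygote band into two bands symmetric about 0.5 — at
(1-f)/(2-f) and 1/(2-f) for a loss, 1/(2+f) and (1+f)/(2+f) for a gain.
The screen therefore takes, per sample-arm, all BAF values in the
mid-band (0.15, 0.85), summarises their standard deviation and
interquartile range, and flags arms whose robust z-score on either
statistic is extreme across the cohort.  For a flagged arm the band
separation ``d`` (difference of the upper- and lower-band means)
inverts to the mosaic fraction: f = 2d/(1+d) for a loss and 2d/(1-d)
for a gain, with the direction read from mean LRR.

Flagged arms whose length is mostly covered by an HMM CNV call are
classed ``mosaic_called_cnv`` and excluded from association (their
calls dropped, the arm masked for that sample); flagged arms without a
call are retained as ``mosaic_uncalled``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import IntensityPanel

__all__ = [
    "ArmMosaicStat",
    "arm_baf_stats",
    "scan_arms",
    "flag_outlier_arms",
    "estimate_mosaic_fraction",
    "classify_and_exclude",
    "apply_arm_exclusions",
]

MID_LO, MID_HI = 0.15, 0.85
# band means for fraction estimation use a wider window: at high
# fractions the split heterozygote bands leave the screening mid-band
EST_LO, EST_HI = 0.05, 0.95
MIN_MID_BAND = 30


@dataclass
class ArmMosaicStat:
    sample_id: str
    chrom: str
    arm: str
    n_mid: int
    baf_sd: float
    baf_iqr: float
    mean_lrr: float
    lrr_sd: float
    outlier: bool = False
    arm_class: str = "unknown"
    est_fraction: float = float("nan")
    excluded: bool = False


def arm_baf_stats(baf_values: np.ndarray) -> tuple[int, float, float]:
    """Mid-band count, standard deviation and IQR of one arm's BAF.

    Only values strictly inside (0.15, 0.85) enter; fewer than 30 such
    values yields NaN statistics (class stays ``unknown``).
    """
    v = np.asarray(baf_values, dtype=float)
    v = v[np.isfinite(v)]
    mid = v[(v > MID_LO) & (v < MID_HI)]
    n = len(mid)
    if n < MIN_MID_BAND:
        return n, float("nan"), float("nan")
    sd = float(np.std(mid))           # population sd: two-point closed forms
    q75, q25 = np.percentile(mid, [75, 25])
    return n, sd, float(q75 - q25)


def scan_arms(panel: IntensityPanel) -> list[ArmMosaicStat]:
    """Compute mid-band BAF statistics for every sample-arm."""
    markers = panel.markers
    key = markers["chrom"].astype(str) + ":" + markers["arm"].astype(str)
    stats: list[ArmMosaicStat] = []
    for k in pd.unique(key):
        chrom, arm = k.split(":")
        cols = np.flatnonzero((key == k).to_numpy())
        for si, sample_id in enumerate(panel.samples):
            n, sd, iqr = arm_baf_stats(panel.baf[si, cols])
            lrr = panel.lrr[si, cols]
            stats.append(ArmMosaicStat(
                sample_id=sample_id, chrom=chrom, arm=arm,
                n_mid=n, baf_sd=sd, baf_iqr=iqr,
                mean_lrr=float(np.nanmean(lrr)),
                lrr_sd=float(np.nanstd(lrr))))
    return stats


def _robust_z(values: np.ndarray, mad_floor: float) -> np.ndarray:
    med = np.nanmedian(values)
    mad = np.nanmedian(np.abs(values - med))
    scale = max(1.4826 * mad, mad_floor)
    return (values - med) / scale


def flag_outlier_arms(stats: list[ArmMosaicStat], z_threshold: float = 6.0,
                      mad_floor: float = 0.005) -> list[ArmMosaicStat]:
    """Flag arms whose BAF sd or IQR is a robust outlier across the cohort.

    Scaling uses median/MAD over all arms with defined statistics; a
    degenerate MAD falls back to ``mad_floor`` before scaling.  Needs
    at least 50 arm records for a stable reference distribution.
    """
    if len(stats) < 50:
        raise ValueError("need >= 50 arm records for robust scaling")
    sd = np.array([s.baf_sd for s in stats])
    iqr = np.array([s.baf_iqr for s in stats])
    z_sd = _robust_z(sd, mad_floor)
    z_iqr = _robust_z(iqr, mad_floor)
    for i, s in enumerate(stats):
        defined = np.isfinite(sd[i]) and np.isfinite(iqr[i])
        s.outlier = bool(defined and (z_sd[i] > z_threshold
                                      or z_iqr[i] > z_threshold))
        if defined and not s.outlier:
            s.arm_class = "normal"
    return stats


def estimate_mosaic_fraction(mid_baf: np.ndarray,
                             mean_lrr: float) -> tuple[str, float]:
    """Invert the band geometry of a flagged arm to (direction, fraction).

    Mid-band values are split at 0.5; ``d`` is the difference of the
    upper and lower band means.  When the screening mid-band holds too
    few values — at high fractions the split bands migrate past 0.15 /
    0.85 — a wider (0.05, 0.95) window is used instead; the narrow
    window is preferred because homozygote cluster tails contaminate
    the wide one at low fractions.  Direction comes from mean LRR (loss
    if negative).  Returns ('unknown', NaN) when the band is one-sided.
    """
    vv = np.asarray(mid_baf, dtype=float)
    vv = vv[np.isfinite(vv)]
    v = vv[(vv > MID_LO) & (vv < MID_HI)]
    if len(v) < MIN_MID_BAND:
        v = vv[(vv > EST_LO) & (vv < EST_HI)]
    lo = v[v < 0.5]
    hi = v[v >= 0.5]
    if len(lo) == 0 or len(hi) == 0 or len(v) < MIN_MID_BAND:
        return "unknown", float("nan")
    d = float(np.mean(hi) - np.mean(lo))
    if mean_lrr < 0:
        direction = "loss"
        f = 2.0 * d / (1.0 + d)
    else:
        direction = "gain"
        f = 2.0 * d / (1.0 - d) if d < 1.0 else 1.0
    return direction, float(np.clip(f, 0.0, 1.0))


def _arm_call_coverage(calls: pd.DataFrame, chrom: str,
                       arm_start: int, arm_end: int,
                       sample_id: str) -> tuple[float, int]:
    """Fraction of the arm covered by the sample's calls, and how many
    disjoint calls overlap it."""
    if calls.empty:
        return 0.0, 0
    sub = calls[(calls["sample_id"] == sample_id)
                & (calls["chrom"] == chrom)
                & (calls["end_pos"] >= arm_start)
                & (calls["start_pos"] <= arm_end)]
    if sub.empty:
        return 0.0, 0
    covered = 0
    for _, r in sub.iterrows():
        covered += (min(r["end_pos"], arm_end)
                    - max(r["start_pos"], arm_start) + 1)
    return covered / (arm_end - arm_start + 1), len(sub)


def classify_and_exclude(
    stats: list[ArmMosaicStat], panel: IntensityPanel,
    calls: pd.DataFrame, coverage_threshold: float = 0.5,
    noisy_lrr_sd: float = 0.35,
) -> list[ArmMosaicStat]:
    """Classify flagged arms and decide exclusions.

    A flagged arm mostly covered (>= ``coverage_threshold`` of its
    marker span) by the sample's CNV calls is ``mosaic_called_cnv`` and
    excluded; with two or more disjoint overlapping calls it is
    ``multi_event`` and excluded; flagged arms with no such call are
    ``mosaic_uncalled`` and retained; flagged arms with LRR noise above
    ``noisy_lrr_sd`` are ``noisy``.  Fractions are estimated for mosaic
    classes only.
    """
    markers = panel.markers
    arm_bounds: dict[tuple[str, str], tuple[int, int]] = {}
    for (chrom, arm), grp in markers.groupby(["chrom", "arm"], sort=False):
        arm_bounds[(str(chrom), str(arm))] = (int(grp["pos"].min()),
                                              int(grp["pos"].max()))
    key = markers["chrom"].astype(str) + ":" + markers["arm"].astype(str)
    for s in stats:
        if not s.outlier:
            continue
        a0, a1 = arm_bounds[(s.chrom, s.arm)]
        cov, n_ev = _arm_call_coverage(calls, s.chrom, a0, a1, s.sample_id)
        if s.lrr_sd > noisy_lrr_sd:
            s.arm_class = "noisy"
            s.excluded = False
            continue
        cols = np.flatnonzero((key == f"{s.chrom}:{s.arm}").to_numpy())
        si = panel.sample_index(s.sample_id)
        direction, f = estimate_mosaic_fraction(panel.baf[si, cols],
                                                s.mean_lrr)
        if n_ev >= 2 and cov >= coverage_threshold:
            s.arm_class = "multi_event"
            s.excluded = True
            s.est_fraction = f
        elif cov >= coverage_threshold:
            s.arm_class = "mosaic_called_cnv"
            s.excluded = True
            s.est_fraction = f
        elif direction == "unknown":
            s.arm_class = "unknown"
        elif f < 0.15:
            s.arm_class = "faint"
            s.est_fraction = f
        else:
            s.arm_class = "mosaic_uncalled"
            s.est_fraction = f
    return stats


def apply_arm_exclusions(calls: pd.DataFrame, panel: IntensityPanel,
                         stats: list[ArmMosaicStat]) -> pd.DataFrame:
    """Drop calls on excluded sample-arms from a callset."""
    if calls.empty:
        return calls
    markers = panel.markers
    keep = np.ones(len(calls), dtype=bool)
    for s in stats:
        if not s.excluded:
            continue
        grp = markers[(markers["chrom"] == s.chrom)
                      & (markers["arm"] == s.arm)]
        a0, a1 = int(grp["pos"].min()), int(grp["pos"].max())
        hit = ((calls["sample_id"] == s.sample_id)
               & (calls["chrom"] == s.chrom)
               & (calls["end_pos"] >= a0)
               & (calls["start_pos"] <= a1))
        keep &= ~hit.to_numpy()
    return calls.loc[keep].reset_index(drop=True)


def stats_frame(stats: list[ArmMosaicStat]) -> pd.DataFrame:
    """Flatten arm statistics to a DataFrame for reporting."""
    return pd.DataFrame([vars(s) for s in stats])
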