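"""Replichore symmetry and region statistics.

The two chromosome arms (replichores) run from *oriC* to the terminus and
are replicated by the left and right forks. Large-scale supercoiling on the
two arms can be compared by reading the smoothed landscape outward from an
axis point in both directions and correlating the two series; scanning the
axis over angular offsets from *oriC* locates the axis of maximal mirror
symmetry. Skew is measured in degrees of the circular map, counterclockwise
positive (1 degree = genome_length/360 bp toward decreasing coordinates on
the conventional clockwise map).

Region statistics compare mean supercoiling between macrodomains,
hemi-genomes, or signal-defined regions across replicate experiments with
an equal-variance F test followed by a paired two-tailed t test
(df = n_replicates − 1), reported without multiple-testing correction by
default. Signal-defined regions (psoralen-enriched / depleted) are maximal
runs of smoothed z-scores beyond a threshold, against which any external
binned z-score track (nucleoid proteins, topoisomerases) can be scored.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import GenomeConfig
from .tracks import (
    BinnedTrack,
    circular_moving_average,
    window_kb_to_bins,
    zscore_track,
)

__all__ = [
    "AxisSpec",
    "Region",
    "RegionStats",
    "SkewScanResult",
    "arm_series",
    "symmetry_correlation",
    "skew_scan",
    "region_means_and_tests",
    "classify_supercoiled_regions",
    "track_association",
    "significance_stars",
]

logger = logging.getLogger("psorakit")


@dataclass(frozen=True)
class AxisSpec:
    """Symmetry axis through oriC displaced by ``skew_deg`` (CCW positive)."""

    oric_bp: int
    skew_deg: float = 0.0

    def axis_bp(self, config: GenomeConfig) -> int:
        L = config.genome_length_bp
        return int(round(self.oric_bp - self.skew_deg * L / 360.0)) % L

    def antipode_bp(self, config: GenomeConfig) -> int:
        L = config.genome_length_bp
        return (self.axis_bp(config) + L // 2) % L


@dataclass(frozen=True)
class Region:
    """Named circular interval with a classification."""

    name: str
    start_bp: int
    end_bp: int
    region_class: str = "macrodomain"  # macrodomain | hemi_genome | signal_defined

    def __post_init__(self) -> None:
        if self.start_bp == self.end_bp:
            raise ValueError(f"region {self.name} is degenerate")


@dataclass
class RegionStats:
    region: Region
    replicate_means: np.ndarray
    mean: float
    sem: float
    n_bins: int


@dataclass
class SkewScanResult:
    skews_deg: np.ndarray
    r: np.ndarray
    optimal_skew_deg: float
    r_at_optimum: float


# -- arm extraction and symmetry ----------------------------------------


def _arms(values: np.ndarray, mask: np.ndarray, axis_bin: int, length: int):
    n = values.size
    k = np.arange(1, length + 1)
    left_idx = (axis_bin - k) % n   # counterclockwise
    right_idx = (axis_bin + k) % n  # clockwise
    return (values[left_idx], mask[left_idx]), (values[right_idx], mask[right_idx])


def _arm_length(config: GenomeConfig, smoothing_kb: float) -> int:
    half = config.n_bins // 2
    w = window_kb_to_bins(smoothing_kb, config) if smoothing_kb else 1
    return max(3, half - w // 2)


def arm_series(
    track: BinnedTrack, axis: AxisSpec, smoothing_kb: float = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Left (counterclockwise) and right (clockwise) arm series from the
    skewed axis point, each out to half the genome minus the smoothing
    half-window; returned as equal-length arrays (invalid bins are NaN)."""
    sm = circular_moving_average(track, smoothing_kb) if smoothing_kb else track
    b = track.config.bin_of(axis.axis_bp(track.config))
    (lv, lm), (rv, rm) = _arms(sm.values, sm.mask, b, _arm_length(track.config, smoothing_kb))
    left = np.where(lm, np.nan, lv)
    right = np.where(rm, np.nan, rv)
    return left, right


def _pairwise_r(left: np.ndarray, right: np.ndarray) -> float:
    ok = np.isfinite(left) & np.isfinite(right)
    x, y = left[ok], right[ok]
    if x.size < 3:
        raise ValueError("fewer than 3 valid arm pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate arm variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def symmetry_correlation(
    track: BinnedTrack, axis: AxisSpec, smoothing_kb: float = 100
) -> float:
    """Pearson r between the left- and right-arm series about ``axis``."""
    left, right = arm_series(track, axis, smoothing_kb)
    return _pairwise_r(left, right)


def skew_scan(
    track: BinnedTrack,
    skew_range_deg: tuple[float, float] = (-90.0, 90.0),
    step_deg: float = 1.0,
    smoothing_kb: float = 100,
    oric_bp: int | None = None,
) -> SkewScanResult:
    """Arm symmetry r over a grid of axis skews; ties broken toward the
    smallest |skew|."""
    config = track.config
    oric = config.oric_bp if oric_bp is None else oric_bp
    lo, hi = skew_range_deg
    if hi < lo or step_deg <= 0:
        raise ValueError("invalid skew grid")
    skews = np.arange(lo, hi + step_deg / 2, step_deg)
    sm = circular_moving_average(track, smoothing_kb) if smoothing_kb else track
    length = _arm_length(config, smoothing_kb)
    rs = np.empty(skews.size)
    for i, s in enumerate(skews):
        b = config.bin_of(AxisSpec(oric, float(s)).axis_bp(config))
        (lv, lm), (rv, rm) = _arms(sm.values, sm.mask, b, length)
        rs[i] = _pairwise_r(np.where(lm, np.nan, lv), np.where(rm, np.nan, rv))
    best_r = rs.max()
    candidates = np.flatnonzero(rs >= best_r - 1e-12)
    best = candidates[np.lexsort((skews[candidates], np.abs(skews[candidates])))][0]
    return SkewScanResult(
        skews_deg=skews, r=rs,
        optimal_skew_deg=float(skews[best]), r_at_optimum=float(rs[best]),
    )


# -- region statistics ---------------------------------------------------


def significance_stars(p: float) -> str:
    for thr, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thr:
            return stars
    return "NS"


def _region_replicate_means(
    replicates: list[BinnedTrack], region: Region
) -> tuple[np.ndarray, int]:
    cfg = replicates[0].config
    bins = cfg.bins_overlapping(region.start_bp, region.end_bp)
    means = []
    for rep in replicates:
        ok = rep.valid[bins]
        if not ok.any():
            raise ValueError(f"region {region.name} has no valid bins")
        means.append(float(rep.values[bins][ok].mean()))
    return np.array(means), int(bins.size)


def region_means_and_tests(
    replicates: list[BinnedTrack],
    regions: list[Region],
    correct_multiple_testing: bool = False,
) -> tuple[list[RegionStats], pd.DataFrame]:
    """Per-region replicate means plus all pairwise region comparisons.

    Each comparison reports an F test for equality of variances of the two
    sets of replicate means followed by a paired two-tailed t test across
    replicates (df = n_replicates − 1) with significance stars at the
    0.05/0.01/0.001/0.0001 thresholds. No multiple-testing correction is
    applied unless requested (Bonferroni when it is).
    """
    if len(replicates) < 2:
        raise ValueError("region tests need at least 2 replicates")
    stats_list = []
    for reg in regions:
        means, n_bins = _region_replicate_means(replicates, reg)
        stats_list.append(
            RegionStats(
                region=reg, replicate_means=means, mean=float(means.mean()),
                sem=float(means.std(ddof=1) / math.sqrt(means.size)),
                n_bins=n_bins,
            )
        )
    nrep = len(replicates)
    rows = []
    pairs = list(itertools.combinations(range(len(regions)), 2))
    for i, j in pairs:
        a, b = stats_list[i], stats_list[j]
        va, vb = a.replicate_means.var(ddof=1), b.replicate_means.var(ddof=1)
        if va > 0 and vb > 0:
            F = max(va, vb) / min(va, vb)
            f_p = 2 * stats.f.sf(F, nrep - 1, nrep - 1)
            f_p = min(1.0, f_p)
        else:
            F, f_p = math.nan, math.nan
        diff = a.replicate_means - b.replicate_means
        if np.allclose(diff, diff[0]) and diff.std() == 0:
            t_p = 1.0 if diff[0] == 0 else 0.0
            t_stat = math.inf if diff[0] else 0.0
        else:
            t_stat, t_p = stats.ttest_rel(a.replicate_means, b.replicate_means)
        rows.append(
            {
                "region_a": a.region.name,
                "region_b": b.region.name,
                "mean_a": a.mean,
                "mean_b": b.mean,
                "mean_difference": a.mean - b.mean,
                "f_statistic": float(F) if np.isfinite(F) else F,
                "f_p": f_p,
                "t_statistic": float(t_stat),
                "t_p": float(t_p),
                "df": nrep - 1,
            }
        )
    table = pd.DataFrame(rows)
    if correct_multiple_testing and len(table):
        table["t_p_adjusted"] = np.minimum(1.0, table["t_p"] * len(table))
        table["stars"] = table["t_p_adjusted"].map(significance_stars)
    elif len(table):
        table["stars"] = table["t_p"].map(significance_stars)
    return stats_list, table


def classify_supercoiled_regions(
    track: BinnedTrack,
    smoothing_kb: float = 100,
    threshold_sd: float = 0.5,
    min_length_kb: float = 20,
) -> list[Region]:
    """Psoralen-enriched / depleted regions from a smoothed z-scored track.

    Maximal circular runs of bins above +threshold_sd are labeled
    ``enriched`` (relatively negatively supercoiled) and runs below
    −threshold_sd ``depleted``; runs shorter than ``min_length_kb`` are
    dropped. The defaults are a documented analysis choice, not a published
    prescription; with ``threshold_sd=0`` on a zero-mean track the two
    classes tile the genome.
    """
    sm = circular_moving_average(track, smoothing_kb) if smoothing_kb else track
    z = zscore_track(sm)
    cfg = track.config
    min_bins = max(1, round(min_length_kb * 1000 / cfg.bin_size_bp))
    regions: list[Region] = []
    from .tracks import _circular_runs

    for label, flags in (
        ("enriched", z.valid & (z.values >= threshold_sd) & (z.values > -threshold_sd)),
        ("depleted", z.valid & (z.values < -threshold_sd)),
    ):
        runs = [r for r in _circular_runs(flags) if r.size >= min_bins]
        # order regions by genomic start for stable naming
        runs.sort(key=lambda r: r[0])
        for idx, run in enumerate(runs, start=1):
            start = int(run[0]) * cfg.bin_size_bp
            end = (int(run[-1]) + 1) * cfg.bin_size_bp % cfg.genome_length_bp
            regions.append(
                Region(
                    name=f"{label}_{idx}", start_bp=start,
                    end_bp=end if end != start else cfg.genome_length_bp,
                    region_class="signal_defined",
                )
            )
    return regions


def track_association(
    protein_track_z: BinnedTrack,
    regions: list[Region],
    two_sample: bool = False,
) -> dict:
    """Mean binding of an external z-scored track within region classes.

    Per-region mean z is computed, then per class the mean ± SEM and a
    one-sample two-tailed t test of the region means against zero with
    df = n_regions − 1. With ``two_sample=True`` a two-sample t between the
    two classes is reported instead of the one-sample tests.
    """
    if protein_track_z.kind != "zscore":
        raise ValueError("association expects a z-scored track")
    by_class: dict[str, list] = {}
    for reg in regions:
        key = reg.name.rsplit("_", 1)[0] if reg.region_class == "signal_defined" else reg.region_class
        bins = protein_track_z.config.bins_overlapping(reg.start_bp, reg.end_bp)
        ok = protein_track_z.valid[bins]
        if not ok.any():
            raise ValueError(f"region {reg.name} has no valid bins")
        by_class.setdefault(key, []).append(
            {"region": reg.name, "mean_z": float(protein_track_z.values[bins][ok].mean())}
        )
    out: dict = {"per_region": by_class, "per_class": {}}
    for key, entries in by_class.items():
        if not entries:
            raise ValueError(f"empty region class {key}")
        means = np.array([e["mean_z"] for e in entries])
        entry = {
            "n_regions": means.size,
            "mean_z": float(means.mean()),
            "sem_z": float(means.std(ddof=1) / math.sqrt(means.size))
            if means.size > 1 else 0.0,
        }
        if not two_sample and means.size > 1:
            t, p = stats.ttest_1samp(means, 0.0)
            entry.update(t=float(t), p=float(p), df=means.size - 1,
                         stars=significance_stars(float(p)))
        out["per_class"][key] = entry
    if two_sample:
        keys = sorted(by_class)
        if len(keys) == 2:
            m1 = np.array([e["mean_z"] for e in by_class[keys[0]]])
            m2 = np.array([e["mean_z"] for e in by_class[keys[1]]])
            t, p = stats.ttest_ind(m1, m2)
            out["two_sample"] = {
                "classes": keys, "t": float(t), "p": float(p),
                "df": m1.size + m2.size - 2, "stars": significance_stars(float(p)),
            }
    return out
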