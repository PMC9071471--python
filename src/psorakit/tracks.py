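"""Binned circular genome tracks and the psoralen-enrichment operations.

The measurement chain mirrors a psoralen-pulldown sequencing
experiment: aligned fragments are binned at 1 kb, unmappable intervals
(rRNA operons) are imputed from flanking bins, counts are normalized to the
genome average, and the pulldown/input ratio is log2-transformed into a
relative supercoiling track. Because psoralen intercalation increases with
helical under-winding, bins above the genome average are relatively
negatively supercoiled and bins below it relatively positively supercoiled.

Masking semantics: each track carries two boolean vectors.  ``mask`` marks
bins with no usable value (for example zero-count bins in a log ratio);
these are excluded from every statistic.  ``imputed`` marks bins whose
value was replaced from flanking signal; those values are usable and are
included in means and regressions, but stay flagged for provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .config import GenomeConfig

__all__ = [
    "BinnedTrack",
    "FragmentSet",
    "bin_fragments",
    "mask_and_impute",
    "normalize_relative",
    "log2_enrichment",
    "zscore_track",
    "circular_moving_average",
    "track_diagnostics",
    "window_kb_to_bins",
]

logger = logging.getLogger("psorakit")

TRACK_KINDS = ("count", "relative", "log2_enrichment", "zscore", "modeled")


@dataclass
class BinnedTrack:
    """One value per bin on a circular genome.

    ``kind`` states the unit of the values: raw fragment counts, relative
    coverage (mean 1), log2 pulldown/input enrichment, z-scores, or a
    modeled supercoiling signal.
    """

    config: GenomeConfig
    values: np.ndarray
    kind: str = "count"
    mask: np.ndarray = None  # True = invalid, excluded from statistics
    imputed: np.ndarray = None  # True = value imputed from flanks, usable

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.config.n_bins
        if self.values.shape != (n,):
            raise ValueError(
                f"track length {self.values.shape} != n_bins {n}"
            )
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        self.mask = (
            np.zeros(n, dtype=bool) if self.mask is None
            else np.asarray(self.mask, dtype=bool).copy()
        )
        self.imputed = (
            np.zeros(n, dtype=bool) if self.imputed is None
            else np.asarray(self.imputed, dtype=bool).copy()
        )
        if self.kind == "count" and np.any(self.values[~self.mask] < 0):
            raise ValueError("count tracks must be non-negative")

    @property
    def valid(self) -> np.ndarray:
        """Bins with a usable value (imputed bins count as valid)."""
        return ~self.mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def with_values(self, values, kind=None, mask=None) -> "BinnedTrack":
        return BinnedTrack(
            config=self.config,
            values=np.asarray(values, dtype=float),
            kind=kind or self.kind,
            mask=self.mask if mask is None else mask,
            imputed=self.imputed,
        )

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.config.genome_length_bp == other.config.genome_length_bp
            and self.config.bin_size_bp == other.config.bin_size_bp
        )


@dataclass
class FragmentSet:
    """Aligned fragment intervals on the circular genome.

    ``end_bp < start_bp`` denotes a fragment wrapping through coordinate 0.
    """

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.starts.shape != self.ends.shape:
            raise ValueError("starts and ends must have equal length")

    def __len__(self) -> int:
        return self.starts.size

    def midpoints(self, config: GenomeConfig) -> np.ndarray:
        """Circular fragment midpoints in bp."""
        L = config.genome_length_bp
        if np.any(self.starts < 0) or np.any(self.starts >= L):
            raise ValueError("fragment start outside [0, genome_length)")
        if np.any(self.ends < 0) or np.any(self.ends > L):
            raise ValueError("fragment end outside [0, genome_length]")
        length = (self.ends - self.starts) % L
        if np.any(length == 0):
            raise ValueError("zero-length fragment")
        return (self.starts + length // 2) % L


def bin_fragments(fragments: FragmentSet, config: GenomeConfig) -> BinnedTrack:
    """Count fragments per bin by circular midpoint assignment.

    Each fragment contributes exactly one count to the bin containing its
    midpoint (computed on the circle, so origin-spanning fragments land in
    the correct bin); the total count is conserved.
    """
    mids = fragments.midpoints(config)
    counts = np.bincount(config.bin_of(mids), minlength=config.n_bins).astype(float)
    return BinnedTrack(config=config, values=counts, kind="count")


def _masked_bins(config: GenomeConfig) -> np.ndarray:
    out = np.zeros(config.n_bins, dtype=bool)
    for s, e, _ in config.masked_intervals:
        out[config.bins_overlapping(s, e)] = True
    return out


def _circular_runs(flags: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of True, merged across the origin."""
    n = flags.size
    if flags.all():
        return [np.arange(n)]
    if not flags.any():
        return []
    # rotate so position 0 is False, then find contiguous runs
    start0 = int(np.argmin(flags))
    rot = np.roll(flags, -start0)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], rot.view(np.int8), [0]])))
    runs = []
    for a, b in zip(edges[::2], edges[1::2]):
        runs.append((np.arange(a, b) + start0) % n)
    return runs


def mask_and_impute(
    track: BinnedTrack, config: GenomeConfig | None = None, flank_kb: int = 3
) -> BinnedTrack:
    """Replace bins overlapping masked intervals with the flanking mean.

    Every bin of a masked run is set to the mean of the nearest ``flank_kb``
    un-masked bins on each side (6 kb total by default, matching the rRNA
    imputation used on real data). If a flank runs into another masked
    interval the search extends outward past it, with a logged warning.
    """
    config = config or track.config
    if track.kind not in ("count", "relative"):
        raise ValueError("impute operates on count or relative tracks")
    bad = _masked_bins(config)
    if not bad.any():
        return replace(
            track, values=track.values.copy(), mask=track.mask.copy(),
            imputed=track.imputed.copy(),
        )
    n = config.n_bins
    flank_bins = max(1, round(flank_kb * 1000 / config.bin_size_bp))
    if bad.sum() + 2 * flank_bins >= n:
        raise ValueError("masked intervals leave too few bins to impute from")
    values = track.values.copy()
    imputed = track.imputed.copy()
    for run in _circular_runs(bad):
        flank_idx, skipped = [], 0
        for direction, anchor in ((-1, run[0]), (+1, run[-1])):
            got, step = [], 1
            while len(got) < flank_bins:
                i = (anchor + direction * step) % n
                if bad[i] or track.mask[i]:
                    skipped += 1
                else:
                    got.append(i)
                step += 1
            flank_idx.extend(got)
        if skipped:
            logger.warning(
                "imputation flank for bins %d-%d extended past %d masked/invalid "
                "bin(s)", run[0], run[-1], skipped,
            )
        values[run] = track.values[flank_idx].mean()
        imputed[run] = True
    out = replace(track, values=values, imputed=imputed, mask=track.mask.copy())
    return out


def normalize_relative(track: BinnedTrack) -> BinnedTrack:
    """Divide counts by their mean over valid bins (genome-average = 1)."""
    if track.kind != "count":
        raise ValueError("normalize_relative expects a count track")
    vals = track.valid_values()
    if vals.size == 0 or vals.sum() <= 0:
        raise ValueError("empty library: no counts to normalize")
    return track.with_values(track.values / vals.mean(), kind="relative")


def log2_enrichment(pulldown: BinnedTrack, input_: BinnedTrack) -> BinnedTrack:
    """Per-bin log2(pulldown / input) of two relative-coverage tracks.

    Bins where either side is zero (or already invalid) are masked rather
    than pseudocounted; downstream statistics skip them.
    """
    if pulldown.kind != "relative" or input_.kind != "relative":
        raise ValueError("log2_enrichment expects relative tracks")
    if not pulldown.same_grid(input_):
        raise ValueError("pulldown and input are on different genome grids")
    mask = pulldown.mask | input_.mask | (pulldown.values <= 0) | (input_.values <= 0)
    values = np.zeros_like(pulldown.values)
    ok = ~mask
    values[ok] = np.log2(pulldown.values[ok] / input_.values[ok])
    return BinnedTrack(
        config=pulldown.config, values=values, kind="log2_enrichment",
        mask=mask, imputed=pulldown.imputed | input_.imputed,
    )


def zscore_track(track: BinnedTrack) -> BinnedTrack:
    """Standardize to mean 0, population SD 1 over valid bins."""
    vals = track.valid_values()
    if vals.size < 2:
        raise ValueError("need at least 2 valid bins to standardize")
    sd = vals.std()  # population SD
    if sd == 0:
        raise ValueError("zero variance: cannot standardize")
    return track.with_values((track.values - vals.mean()) / sd, kind="zscore")


def window_kb_to_bins(window_kb: float, config: GenomeConfig) -> int:
    """Convert a window in kb to the nearest odd number of bins (>= 1)."""
    w = max(1, round(window_kb * 1000 / config.bin_size_bp))
    return w if w % 2 == 1 else w + 1


def circular_moving_average(track: BinnedTrack, window_kb: float) -> BinnedTrack:
    """Centered circular moving average; invalid bins excluded from means."""
    w = window_kb_to_bins(window_kb, track.config)
    if w >= track.config.n_bins:
        raise ValueError("smoothing window must be smaller than the genome")
    if w == 1:
        return replace(track, values=track.values.copy(), mask=track.mask.copy(),
                       imputed=track.imputed.copy())
    ok = track.valid.astype(float)
    sv = uniform_filter1d(track.values * ok, size=w, mode="wrap")
    sw = uniform_filter1d(ok, size=w, mode="wrap")
    out = np.zeros_like(track.values)
    nz = sw > 1e-12
    out[nz] = sv[nz] / sw[nz]
    return replace(track, values=out, mask=~nz, imputed=track.imputed.copy())


def track_diagnostics(track: BinnedTrack, gc_per_bin=None) -> dict:
    """Distributional diagnostics of a log2-enrichment track.

    Returns sample skewness, the correlation coefficient of a normal q-q
    plot, and (when per-bin GC content is supplied) the Pearson correlation
    of enrichment with GC — provided so users can verify that composition
    correction is unnecessary, as is typical for psoralen data.
    """
    if track.kind != "log2_enrichment":
        raise ValueError("diagnostics are defined for log2_enrichment tracks")
    vals = track.valid_values()
    (_, _), (_, _, qq_r) = stats.probplot(vals, dist="norm")
    out = {
        "n_bins": int(vals.size),
        "skewness": float(stats.skew(vals)),
        "qq_r": float(qq_r),
    }
    if gc_per_bin is not None:
        gc = np.asarray(gc_per_bin, dtype=float)[track.valid]
        r, p = stats.pearsonr(vals, gc)
        out["gc_r"] = float(r)
        out["gc_p"] = float(p)
    return out
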