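"""Transcription twin-domain quantification.

A translocating RNA polymerase behaves as a moving topological barrier,
under-winding the DNA behind it and over-winding the DNA ahead of it (the
Liu–Wang twin-domain). On a psoralen-enrichment track this appears as
elevated binding upstream of a transcription unit and depressed binding
downstream, each decaying roughly linearly with distance.

This module builds strand-oriented windows around transcription units,
averages them into a consensus profile, and quantifies each side of the
twin-domain with an expanding-window linear regression: starting from the
first ``start_kb`` kb from the unit midpoint, the fit is extended 1 kb at a
time and the extent maximizing |Pearson r| is kept. The regression's
y-intercept is the domain *amplitude* (log2 fold-change at the midpoint)
and its x-intercept the domain *magnitude* (kb of detectable supercoiling
diffusion); 95% ranges come from the intercepts of the pointwise 95%
confidence band of the fitted line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import GenomeConfig
from .tracks import BinnedTrack

__all__ = [
    "TranscriptionUnit",
    "OrientedWindow",
    "ConsensusProfile",
    "DomainFit",
    "extract_oriented_window",
    "consensus_profile",
    "fit_domain_regression",
    "per_tu_amplitude",
    "amplitude_expression_correlation",
    "amplitude_change_percent",
]

logger = logging.getLogger("psorakit")


@dataclass(frozen=True)
class TranscriptionUnit:
    """Oriented genomic interval with a relative expression level.

    ``end_bp`` may exceed the genome length for units spanning the
    coordinate origin (circularly unwrapped); ``start_bp < end_bp`` always.
    """

    name: str
    start_bp: int
    end_bp: int
    strand: str
    expression: float
    ribosomal: bool = False

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError(f"{self.name}: start must precede end (unwrap circular TUs)")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be '+' or '-'")
        if self.expression < 0:
            raise ValueError(f"{self.name}: expression must be non-negative")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def midpoint_bp(self, config: GenomeConfig) -> int:
        return (self.start_bp + self.length_bp // 2) % config.genome_length_bp

    def five_prime_bp(self, config: GenomeConfig) -> int:
        p = self.start_bp if self.strand == "+" else self.end_bp
        return p % config.genome_length_bp

    def three_prime_bp(self, config: GenomeConfig) -> int:
        p = self.end_bp if self.strand == "+" else self.start_bp
        return p % config.genome_length_bp


@dataclass
class OrientedWindow:
    """Per-kb signal around a TU midpoint, flipped so transcription runs
    left to right; position 0 is the midpoint bin."""

    tu: TranscriptionUnit
    half_width_kb: int
    values: np.ndarray  # length 2*half_width_kb + 1
    mask: np.ndarray

    @property
    def positions_kb(self) -> np.ndarray:
        return np.arange(-self.half_width_kb, self.half_width_kb + 1)


@dataclass
class ConsensusProfile:
    """Mean of per-window mean-centered oriented windows."""

    values: np.ndarray
    sem: np.ndarray
    n_windows: int
    half_width_kb: int
    n_per_position: np.ndarray = None

    @property
    def positions_kb(self) -> np.ndarray:
        return np.arange(-self.half_width_kb, self.half_width_kb + 1)


@dataclass
class DomainFit:
    """One fitted side of a twin-domain."""

    side: str  # "upstream" or "downstream"
    slope: float  # log2-units per kb
    intercept: float  # log2-units at the midpoint
    window_kb: int  # regression extent actually used
    pearson_r: float
    amplitude: float  # y-intercept (signed)
    magnitude_kb: float  # x-intercept distance (NaN when no domain)
    amplitude_range: tuple[float, float] = (math.nan, math.nan)
    magnitude_range: tuple[float, float] = (math.nan, math.nan)
    detected: bool = True
    n_points: int = 0


def extract_oriented_window(
    track: BinnedTrack, tu: TranscriptionUnit, half_width_kb: int = 40
) -> OrientedWindow:
    """Signal over ±half_width kb of the TU midpoint, in transcription
    orientation (minus-strand windows are reversed genomic values)."""
    config = track.config
    m = config.bin_of(tu.midpoint_bp(config))
    offsets = np.arange(-half_width_kb, half_width_kb + 1)
    idx = (m + offsets) % config.n_bins
    values = track.values[idx]
    mask = track.mask[idx]
    if tu.strand == "-":
        values = values[::-1].copy()
        mask = mask[::-1].copy()
    return OrientedWindow(tu=tu, half_width_kb=half_width_kb, values=values, mask=mask)


def consensus_profile(
    windows: list[OrientedWindow], groups: list | None = None
) -> ConsensusProfile:
    """Average mean-centered windows position-wise, skipping invalid entries.

    Each window is first centered so its mean over the full range is zero
    (the consensus therefore measures relative change around the unit), then
    positions are averaged across windows with the per-position SEM kept.

    By default all windows carry equal weight. Passing ``groups`` (one
    hashable label per window, e.g. the experiment each window came from)
    averages within each group first and then across groups, weighting
    experiments rather than windows equally.
    """
    if not windows:
        raise ValueError("consensus of zero windows")
    h = windows[0].half_width_kb
    if any(w.half_width_kb != h for w in windows):
        raise ValueError("windows have unequal half-widths")
    if groups is not None:
        if len(groups) != len(windows):
            raise ValueError("need one group label per window")
        subs = []
        for g in dict.fromkeys(groups):  # preserve first-seen order
            sub = [w for w, gi in zip(windows, groups) if gi == g]
            subs.append(consensus_profile(sub))
        vals = np.array([p.values for p in subs])
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1) if len(subs) > 1 else np.zeros_like(mean)
        return ConsensusProfile(
            values=mean, sem=sd / np.sqrt(len(subs)), n_windows=len(windows),
            half_width_kb=h, n_per_position=np.full(mean.size, len(subs)),
        )
    vals = np.array([w.values for w in windows], dtype=float)
    ok = ~np.array([w.mask for w in windows])
    centered = np.where(ok, vals, np.nan)
    centered = centered - np.nanmean(centered, axis=1, keepdims=True)
    n = ok.sum(axis=0)
    if np.any(n == 0):
        raise ValueError("some positions have no valid data in any window")
    mean = np.nanmean(centered, axis=0)
    if len(windows) > 1:
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(centered, axis=0, ddof=1)
        sd = np.nan_to_num(sd)
    else:
        sd = np.zeros_like(mean)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return ConsensusProfile(
        values=mean, sem=sem, n_windows=len(windows), half_width_kb=h,
        n_per_position=n,
    )


def _side_series(profile: ConsensusProfile, side: str):
    h = profile.half_width_kb
    d = np.arange(1, h + 1, dtype=float)
    if side in ("upstream", "up", "negative"):
        y = profile.values[h - 1 :: -1][:h]
        side_name = "upstream"
    elif side in ("downstream", "down", "positive"):
        y = profile.values[h + 1 :]
        side_name = "downstream"
    else:
        raise ValueError(f"unknown side {side!r}")
    return side_name, d, np.asarray(y, dtype=float)


def _scan_best_k(d: np.ndarray, y: np.ndarray, start_kb: int, rule: str) -> int:
    """Extent k maximizing |Pearson r| of the fit over distances 1..k.

    ``rule='max'`` scans every k (global maximum, smallest k on ties);
    ``rule='greedy'`` extends while |r| strictly increases and stops at the
    first decline.
    """
    ks = np.arange(start_kb, d.size + 1)
    # incremental sums make the scan O(n)
    cx = np.cumsum(d)
    cy = np.cumsum(y)
    cxx = np.cumsum(d * d)
    cyy = np.cumsum(y * y)
    cxy = np.cumsum(d * y)
    rs = np.full(ks.size, -np.inf)
    for j, k in enumerate(ks):
        n = float(k)
        sxx = cxx[k - 1] - cx[k - 1] ** 2 / n
        syy = cyy[k - 1] - cy[k - 1] ** 2 / n
        sxy = cxy[k - 1] - cx[k - 1] * cy[k - 1] / n
        if syy <= 0:
            continue
        rs[j] = abs(sxy) / math.sqrt(sxx * syy)
    if rule == "max":
        return int(ks[int(np.argmax(rs))])
    if rule == "greedy":
        best = 0
        for j in range(1, ks.size):
            if rs[j] > rs[best]:
                best = j
            else:
                break
        return int(ks[best])
    raise ValueError(f"unknown stopping rule {rule!r}")


def fit_domain_regression(
    profile: ConsensusProfile,
    side: str,
    start_kb: int = 10,
    stop_rule: str = "max",
    confidence: float = 0.95,
) -> DomainFit:
    """Expanding-window least-squares fit of one twin-domain side.

    The fit uses distances 1..k kb from the TU midpoint; ``k`` starts at
    ``start_kb`` and the extent maximizing |Pearson r| is retained.
    Amplitude is the y-intercept, magnitude the x-intercept (−intercept /
    slope). A side whose slope and intercept share a sign has no zero
    crossing at positive distance: it is flagged as not detected.
    """
    side_name, d_all, y_all = _side_series(profile, side)
    if d_all.size < start_kb:
        raise ValueError(
            f"profile extends only {d_all.size} kb on the {side_name} side; "
            f"need at least start_kb={start_kb}"
        )
    if not np.all(np.isfinite(y_all)):
        raise ValueError("consensus profile contains non-finite values")
    k = _scan_best_k(d_all, y_all, start_kb, stop_rule)
    d, y = d_all[:k], y_all[:k]
    res = stats.linregress(d, y)
    slope, intercept, r = float(res.slope), float(res.intercept), float(res.rvalue)
    fit = DomainFit(
        side=side_name, slope=slope, intercept=intercept, window_kb=k,
        pearson_r=r, amplitude=intercept, magnitude_kb=math.nan, n_points=k,
    )
    if slope == 0 or intercept == 0 or np.sign(slope) == np.sign(intercept):
        fit.detected = False
        logger.warning("%s side: no decaying domain detected", side_name)
        return fit
    fit.magnitude_kb = -intercept / slope

    # pointwise confidence band of the fitted mean line
    n = float(k)
    resid = y - (intercept + slope * d)
    dof = k - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    xbar = d.mean()
    sxx = float(((d - xbar) ** 2).sum())
    tcrit = stats.t.ppf(0.5 + confidence / 2, dof) if dof > 0 else math.inf

    def band_halfwidth(x):
        return tcrit * math.sqrt(s2 * (1 / n + (x - xbar) ** 2 / sxx))

    if s2 == 0.0:
        fit.amplitude_range = (intercept, intercept)
        fit.magnitude_range = (fit.magnitude_kb, fit.magnitude_kb)
        return fit
    h0 = band_halfwidth(0.0)
    fit.amplitude_range = (intercept - h0, intercept + h0)
    # x where (a + b x)^2 = tcrit^2 s2 (1/n + (x - xbar)^2 / sxx):
    # the two roots bracketing the x-intercept are the band-line crossings.
    c2 = tcrit**2 * s2 / sxx
    c1 = -2 * tcrit**2 * s2 * xbar / sxx
    c0 = tcrit**2 * s2 * (1 / n + xbar**2 / sxx)
    A = slope**2 - c2
    B = 2 * slope * intercept - c1
    C = intercept**2 - c0
    disc = B * B - 4 * A * C
    if A != 0 and disc >= 0:
        roots = np.sort(np.array([(-B - math.sqrt(disc)) / (2 * A),
                                  (-B + math.sqrt(disc)) / (2 * A)]))
        lo, hi = float(roots[0]), float(roots[1])
        if lo <= fit.magnitude_kb <= hi:
            fit.magnitude_range = (lo, hi)
    return fit


def per_tu_amplitude(
    track: BinnedTrack, tus: list[TranscriptionUnit], offset_kb: int = 5
) -> pd.DataFrame:
    """Genome-wide per-TU twin-domain amplitudes.

    Amplitude is the enrichment ``offset_kb`` upstream of the 5' boundary
    minus the enrichment ``offset_kb`` downstream of the 3' boundary, in
    transcription orientation — positive for a canonical twin-domain
    (negative supercoiling behind the polymerase, positive ahead).
    Reversing a TU's strand flips the sign. Rows with an invalid bin on
    either side get a NaN amplitude and ``masked=True``.
    """
    config = track.config
    off = offset_kb * 1000
    rows = []
    for tu in tus:
        sign = 1 if tu.strand == "+" else -1
        up_bp = (tu.five_prime_bp(config) - sign * off) % config.genome_length_bp
        dn_bp = (tu.three_prime_bp(config) + sign * off) % config.genome_length_bp
        iu, id_ = config.bin_of(up_bp), config.bin_of(dn_bp)
        bad = bool(track.mask[iu] or track.mask[id_])
        amp = math.nan if bad else float(track.values[iu] - track.values[id_])
        rows.append(
            {
                "name": tu.name,
                "start_bp": tu.start_bp,
                "end_bp": tu.end_bp,
                "strand": tu.strand,
                "expression": tu.expression,
                "ribosomal": tu.ribosomal,
                "upstream_value": float(track.values[iu]),
                "downstream_value": float(track.values[id_]),
                "amplitude": amp,
                "masked": bad,
            }
        )
    return pd.DataFrame(rows)


def amplitude_expression_correlation(
    amplitudes, expressions, top_fractions=(1.0, 0.1, 0.01)
) -> pd.DataFrame:
    """Pearson correlation of twin-domain amplitude with expression.

    Expression is converted to z-scores; one row per requested top-expression
    fraction (membership by expression rank). Fractions with fewer than 3
    usable TUs are skipped with a warning.
    """
    amp = np.asarray(amplitudes, dtype=float)
    expr = np.asarray(expressions, dtype=float)
    if amp.shape != expr.shape:
        raise ValueError("amplitudes and expressions must be matched per TU")
    ok = np.isfinite(amp) & np.isfinite(expr)
    amp, expr = amp[ok], expr[ok]
    z = (expr - expr.mean()) / expr.std()
    order = np.argsort(z)[::-1]
    rows = []
    for frac in top_fractions:
        m = max(0, math.ceil(frac * z.size))
        if m < 3:
            logger.warning("top fraction %.3g has %d TUs (<3); skipped", frac, m)
            continue
        sel = order[:m]
        r, p = stats.pearsonr(z[sel], amp[sel])
        rows.append({"top_fraction": frac, "n_tus": m, "r": float(r), "p": float(p),
                     "mean_amplitude": float(amp[sel].mean())})
    return pd.DataFrame(rows)


def amplitude_change_percent(fit_treated: DomainFit, fit_control: DomainFit) -> float:
    """Percent reduction in domain amplitude after a treatment.

    ``100 * (1 - amp_treated / amp_control)``: positive for a reduction,
    negative when treatment increases the amplitude. Both fits must be for
    the same side.
    """
    if fit_treated.side != fit_control.side:
        raise ValueError("fits are for different sides")
    if fit_control.amplitude == 0:
        raise ValueError("control amplitude is zero: change undefined")
    return 100.0 * (1.0 - fit_treated.amplitude / fit_control.amplitude)
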