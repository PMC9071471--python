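"""Additive twin-domain model of the genome supercoiling landscape.

Every transcription unit is assigned a triangular twin-domain: the signal
rises to +A just upstream of the unit midpoint and decays linearly to zero
``neg_magnitude_kb`` upstream, falls to −A just downstream and decays to
zero ``pos_magnitude_kb`` downstream, crossing zero at the midpoint. The
per-unit amplitude A scales with the unit's transcription rate relative to
the mean ribosomal-operon rate, at ``amp_per_unit_expression`` log2 units
per ribosomal-equivalent. Summing every unit's triangle over the circular
genome yields a phenomenological supercoiling landscape predicted from the
transcriptome alone, which can then be rescaled to and correlated against a
measured psoralen-enrichment track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .config import GenomeConfig
from .tracks import BinnedTrack, circular_moving_average, window_kb_to_bins
from .twin_domain import TranscriptionUnit

__all__ = [
    "TwinDomainModelParams",
    "ModeledProfile",
    "tu_twin_domain_profile",
    "compose_genome_model",
    "scale_to_reference",
    "sliding_window_correlation",
    "genome_wide_correlation",
    "model_fitness_summary",
]


@dataclass(frozen=True)
class TwinDomainModelParams:
    """Generative triangle parameters.

    ``amp_per_unit_expression`` is the log2 fold-change assigned to a unit
    transcribed at the mean ribosomal-operon rate (default 0.38);
    ``neg_magnitude_kb``/``pos_magnitude_kb`` are the upstream (negative,
    under-wound) and downstream (positive, over-wound) domain extents
    (defaults 23 and 25 kb). ``reference_expression`` is the mean ribosomal
    expression in the transcriptome's own units; when None it is derived
    from TUs flagged ribosomal at composition time.
    """

    amp_per_unit_expression: float = 0.38
    neg_magnitude_kb: float = 23.0
    pos_magnitude_kb: float = 25.0
    reference_expression: float | None = None

    def __post_init__(self) -> None:
        if self.amp_per_unit_expression <= 0:
            raise ValueError("amp_per_unit_expression must be positive")
        if self.neg_magnitude_kb <= 0 or self.pos_magnitude_kb <= 0:
            raise ValueError("magnitudes must be positive")


@dataclass
class ModeledProfile:
    """Per-bin modeled supercoiling signal with its provenance."""

    config: GenomeConfig
    values: np.ndarray
    params: TwinDomainModelParams
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.config.n_bins,):
            raise ValueError("model length does not match the genome binning")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("model values must be finite")

    def as_track(self) -> BinnedTrack:
        return BinnedTrack(config=self.config, values=self.values.copy(), kind="modeled")


def _resolve_reference(tus: list[TranscriptionUnit], params: TwinDomainModelParams) -> float:
    if params.reference_expression is not None:
        if params.reference_expression <= 0:
            raise ValueError("reference_expression must be positive")
        return params.reference_expression
    ribo = [tu.expression for tu in tus if tu.ribosomal]
    if not ribo:
        raise ValueError(
            "no TUs flagged ribosomal and no reference_expression supplied; "
            "the amplitude scale is anchored to ribosomal rates"
        )
    return float(np.mean(ribo))


def tu_twin_domain_profile(
    tu: TranscriptionUnit,
    params: TwinDomainModelParams,
    config: GenomeConfig,
    reference_expression: float | None = None,
    shape: str = "ramp",
) -> np.ndarray:
    """Dense per-bin triangular contribution of a single TU.

    Oriented by strand, wrapping circularly: +A·(1−|d|/neg_mag) at d kb
    upstream of the midpoint, −A·(1−d/pos_mag) downstream. With the
    default ``shape="ramp"`` the signal crosses zero linearly at the
    midpoint (midpoint bin = 0); ``shape="step"`` instead places the full
    +A on the midpoint bin, jumping to the negative limb one bin later.
    """
    if shape not in ("ramp", "step"):
        raise ValueError(f"unknown shape {shape!r}")
    ref = reference_expression
    if ref is None:
        ref = _resolve_reference([tu], params)
    A = params.amp_per_unit_expression * (tu.expression / ref)
    out = np.zeros(config.n_bins)
    if A == 0:
        return out
    kb = config.bin_size_bp / 1000.0
    m = config.bin_of(tu.midpoint_bp(config))
    sign = 1 if tu.strand == "+" else -1
    n_neg = int(math.ceil(params.neg_magnitude_kb / kb)) - 1
    n_pos = int(math.ceil(params.pos_magnitude_kb / kb)) - 1
    # upstream (behind the polymerase): under-wound, positive signal
    j0 = 1 if shape == "ramp" else 0
    j = np.arange(j0, n_neg + 1)
    idx = (m - sign * j) % config.n_bins
    out[idx] += A * (1.0 - j * kb / params.neg_magnitude_kb)
    # downstream (ahead): over-wound, negative signal
    j = np.arange(1, n_pos + 1)
    idx = (m + sign * j) % config.n_bins
    out[idx] += -A * (1.0 - j * kb / params.pos_magnitude_kb)
    return out


def compose_genome_model(
    tus: list[TranscriptionUnit],
    params: TwinDomainModelParams,
    config: GenomeConfig,
    source: str = "",
    shape: str = "ramp",
) -> ModeledProfile:
    """Sum every TU's twin-domain triangle into one circular landscape."""
    if not tus:
        raise ValueError("cannot compose a model from zero TUs")
    ref = _resolve_reference(tus, params)
    total = np.zeros(config.n_bins)
    for tu in tus:
        total += tu_twin_domain_profile(tu, params, config,
                                        reference_expression=ref, shape=shape)
    resolved = replace(params, reference_expression=ref)
    return ModeledProfile(config=config, values=total, params=resolved, source=source)


def scale_to_reference(
    model: ModeledProfile, reference: BinnedTrack, smoothing_kb: float | None = 50
) -> ModeledProfile:
    """Affine-rescale the model so its extrema match the measured track.

    Extrema are taken on ``smoothing_kb``-smoothed copies of both signals
    (the scale at which model/measurement comparisons are made); pass
    ``smoothing_kb=None`` for raw extrema. Affine rescaling leaves every
    Pearson correlation with other tracks unchanged.
    """
    mt = model.as_track()
    if smoothing_kb:
        mt = circular_moving_average(mt, smoothing_kb)
        ref = circular_moving_average(reference, smoothing_kb)
    else:
        ref = reference
    mmin, mmax = mt.values.min(), mt.values.max()
    if mmax == mmin:
        raise ValueError("constant model cannot be rescaled to a range")
    rvals = ref.valid_values()
    rmin, rmax = rvals.min(), rvals.max()
    scaled = (model.values - mmin) / (mmax - mmin) * (rmax - rmin) + rmin
    return ModeledProfile(config=model.config, values=scaled, params=model.params,
                          source=model.source)


def sliding_window_correlation(
    a: BinnedTrack, b: BinnedTrack, window_kb: float = 300, step_kb: int = 1
) -> BinnedTrack:
    """Per-bin Pearson r of two tracks in a centered circular window.

    Invalid bins in either track are pairwise-excluded; windows with fewer
    than 3 valid pairs, or degenerate variance, are masked in the output.
    """
    if not a.same_grid(b):
        raise ValueError("tracks are on different genome grids")
    w = window_kb_to_bins(window_kb, a.config)
    if w < 3:
        raise ValueError("window must span at least 3 bins")
    ok = (a.valid & b.valid).astype(float)
    av = np.where(ok > 0, a.values, 0.0)
    bv = np.where(ok > 0, b.values, 0.0)

    def wsum(x):
        return uniform_filter1d(x, size=w, mode="wrap") * w

    n = wsum(ok)
    sa, sb = wsum(av), wsum(bv)
    saa, sbb, sab = wsum(av * av), wsum(bv * bv), wsum(av * bv)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sab - sa * sb / n
        va = saa - sa * sa / n
        vb = sbb - sb * sb / n
        r = cov / np.sqrt(va * vb)
    bad = (n < 3) | ~np.isfinite(r)
    r = np.where(bad, 0.0, np.clip(r, -1.0, 1.0))
    out = BinnedTrack(config=a.config, values=r, kind="modeled", mask=bad)
    if step_kb > 1:
        step = max(1, round(step_kb * 1000 / a.config.bin_size_bp))
        keep = np.zeros(a.config.n_bins, dtype=bool)
        keep[::step] = True
        out.mask |= ~keep
    return out


def genome_wide_correlation(a: BinnedTrack, b: BinnedTrack) -> float:
    """Single Pearson r over all pairwise-valid bins."""
    ok = a.valid & b.valid
    x, y = a.values[ok], b.values[ok]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate tracks: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def model_fitness_summary(
    model: ModeledProfile,
    replicates: list[BinnedTrack],
    regions: list | None = None,
) -> dict:
    """Genome-wide model fitness against replicate measured tracks.

    Returns the per-replicate Pearson r, their mean and SEM, and (when
    ``regions`` is given) per-region mean r of the replicates.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    mt = model.as_track()
    rs = np.array([genome_wide_correlation(mt, rep) for rep in replicates])
    out = {
        "r_per_replicate": [float(r) for r in rs],
        "mean_r": float(rs.mean()),
        "sem_r": float(rs.std(ddof=1) / math.sqrt(rs.size)) if rs.size > 1 else 0.0,
        "n_replicates": int(rs.size),
    }
    if regions:
        per_region = {}
        cfg = model.config
        for reg in regions:
            bins = cfg.bins_overlapping(reg.start_bp, reg.end_bp)
            reg_rs = []
            for rep in replicates:
                ok = rep.valid[bins]
                x, y = mt.values[bins][ok], rep.values[bins][ok]
                if x.size >= 3 and x.std() > 0 and y.std() > 0:
                    reg_rs.append(float(np.corrcoef(x, y)[0, 1]))
            if reg_rs:
                per_region[reg.name] = {
                    "mean_r": float(np.mean(reg_rs)),
                    "sem_r": float(np.std(reg_rs, ddof=1) / math.sqrt(len(reg_rs)))
                    if len(reg_rs) > 1 else 0.0,
                }
        out["per_region"] = per_region
    return out
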