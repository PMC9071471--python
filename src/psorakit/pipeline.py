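"""High-level chains over the track operations.

These helpers wire the standard measurement chain — impute unmappable
bins, normalize to the genome average, take the log2 pulldown/input ratio,
average replicates — exactly as the command-line stages do, so library and
CLI users run the same code.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .config import GenomeConfig
from .tracks import (
    BinnedTrack,
    log2_enrichment,
    mask_and_impute,
    normalize_relative,
)

__all__ = [
    "enrichment_from_counts",
    "average_tracks",
    "replicate_correlation",
]


def enrichment_from_counts(
    pulldown_counts: BinnedTrack,
    input_counts: BinnedTrack,
    flank_kb: int = 3,
) -> BinnedTrack:
    """Counts → imputed → relative → log2(pulldown/input) enrichment."""
    pull = normalize_relative(mask_and_impute(pulldown_counts, flank_kb=flank_kb))
    inp = normalize_relative(mask_and_impute(input_counts, flank_kb=flank_kb))
    return log2_enrichment(pull, inp)


def average_tracks(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Per-bin mean over replicate tracks, skipping invalid bins.

    A bin is masked in the output only when invalid in every replicate.
    """
    if not tracks:
        raise ValueError("no tracks to average")
    kinds = {t.kind for t in tracks}
    if len(kinds) > 1:
        raise ValueError(f"mixed track kinds {sorted(kinds)}")
    vals = np.array([t.values for t in tracks])
    ok = np.array([t.valid for t in tracks])
    n = ok.sum(axis=0)
    summed = np.where(ok, vals, 0.0).sum(axis=0)
    mean = np.divide(summed, n, out=np.zeros_like(summed, dtype=float), where=n > 0)
    imputed = np.logical_or.reduce([t.imputed for t in tracks])
    return BinnedTrack(
        config=tracks[0].config, values=mean, kind=tracks[0].kind,
        mask=n == 0, imputed=imputed,
    )


def replicate_correlation(tracks: list[BinnedTrack]) -> dict:
    """Mean pairwise Pearson r between replicate tracks (reproducibility)."""
    if len(tracks) < 2:
        raise ValueError("need at least 2 replicates")
    rs = []
    for a, b in itertools.combinations(tracks, 2):
        ok = a.valid & b.valid
        x, y = a.values[ok], b.values[ok]
        rs.append(float(np.corrcoef(x, y)[0, 1]))
    rs = np.array(rs)
    return {
        "pairwise_r": [float(r) for r in rs],
        "mean_r": float(rs.mean()),
        "sd_r": float(rs.std(ddof=1)) if rs.size > 1 else 0.0,
        "sem_r": float(rs.std(ddof=1) / math.sqrt(rs.size)) if rs.size > 1 else 0.0,
        "n_pairs": int(rs.size),
    }
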