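"""Plain-text I/O: bedGraph and TSV tracks, BED fragments/TUs/regions,
YAML genome configs.

Tracks round-trip bit-stably at 6 decimal places. Text outputs report bins
1-based (genomic convention); in-memory coordinates are 0-based half-open.
TSV outputs carry a header line beginning ``#``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GenomeConfig
from .symmetry import Region
from .tracks import BinnedTrack, FragmentSet
from .twin_domain import ConsensusProfile, DomainFit, TranscriptionUnit

__all__ = [
    "read_bedgraph", "write_bedgraph",
    "read_tsv_track", "write_tsv_track",
    "read_fragments_bed",
    "read_tus_bed", "write_tus_bed",
    "read_regions_bed", "write_regions_bed",
    "write_consensus_tsv", "read_consensus_tsv",
    "write_fit_json", "read_fit_json",
]

_FMT = "%.6f"


def write_bedgraph(track: BinnedTrack, path, chrom: str = "genome") -> None:
    """4-column bedGraph; masked bins written as ``nan``."""
    cfg = track.config
    starts = np.arange(cfg.n_bins) * cfg.bin_size_bp
    ends = np.minimum(starts + cfg.bin_size_bp, cfg.genome_length_bp)
    with open(path, "w") as fh:
        for s, e, v, m in zip(starts, ends, track.values, track.mask):
            val = "nan" if m else _FMT % v
            fh.write(f"{chrom}\t{s}\t{e}\t{val}\n")


def read_bedgraph(path, config: GenomeConfig, kind: str = "log2_enrichment") -> BinnedTrack:
    values = np.full(config.n_bins, np.nan)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            _, s, _e, v = line.split("\t")
            values[int(s) // config.bin_size_bp] = float(v)
    mask = ~np.isfinite(values)
    values[mask] = 0.0
    return BinnedTrack(config=config, values=values, kind=kind, mask=mask)


def write_tsv_track(track: BinnedTrack, path) -> None:
    """2-column TSV (1-based bin index, value); masked bins as ``nan``."""
    with open(path, "w") as fh:
        fh.write("# bin_index\tvalue\n")
        for i, (v, m) in enumerate(zip(track.values, track.mask), start=1):
            fh.write(f"{i}\t{'nan' if m else _FMT % v}\n")


def read_tsv_track(path, config: GenomeConfig, kind: str = "count") -> BinnedTrack:
    values = np.full(config.n_bins, np.nan)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            i, v = line.split("\t")
            values[int(i) - 1] = float(v)
    mask = ~np.isfinite(values)
    values[mask] = 0.0
    return BinnedTrack(config=config, values=values, kind=kind, mask=mask)


def read_fragments_bed(path) -> FragmentSet:
    """BED3 fragment intervals (chrom column ignored)."""
    starts, ends = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            starts.append(int(parts[1]))
            ends.append(int(parts[2]))
    return FragmentSet(starts=np.array(starts), ends=np.array(ends))


def read_tus_bed(path, ribosomal_prefix: str = "rrn") -> list[TranscriptionUnit]:
    """6-column BED: chrom, start, end, name, expression, strand.

    TUs whose name starts with ``ribosomal_prefix`` are flagged ribosomal.
    """
    tus = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            _, s, e, name, expr, strand = line.rstrip("\n").split("\t")[:6]
            tus.append(
                TranscriptionUnit(
                    name=name, start_bp=int(s), end_bp=int(e), strand=strand,
                    expression=float(expr),
                    ribosomal=name.startswith(ribosomal_prefix),
                )
            )
    return tus


def write_tus_bed(tus: list[TranscriptionUnit], path, chrom: str = "genome") -> None:
    with open(path, "w") as fh:
        for tu in tus:
            fh.write(
                f"{chrom}\t{tu.start_bp}\t{tu.end_bp}\t{tu.name}\t"
                f"{_FMT % tu.expression}\t{tu.strand}\n"
            )


def read_regions_bed(path) -> list[Region]:
    """BED with name and class in columns 4-5."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            _, s, e, name, cls = line.rstrip("\n").split("\t")[:5]
            regions.append(Region(name=name, start_bp=int(s), end_bp=int(e),
                                  region_class=cls))
    return regions


def write_regions_bed(regions: list[Region], path, chrom: str = "genome") -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{chrom}\t{r.start_bp}\t{r.end_bp}\t{r.name}\t{r.region_class}\n")


def write_consensus_tsv(profile: ConsensusProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("# position_kb\tmean_log2\tsem\tn_windows\n")
        for p, v, s, n in zip(profile.positions_kb, profile.values, profile.sem,
                              profile.n_per_position):
            fh.write(f"{p}\t{_FMT % v}\t{_FMT % s}\t{n}\n")


def read_consensus_tsv(path) -> ConsensusProfile:
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["position_kb", "mean_log2", "sem", "n_windows"])
    h = int(df["position_kb"].abs().max())
    return ConsensusProfile(
        values=df["mean_log2"].to_numpy(),
        sem=df["sem"].to_numpy(),
        n_windows=int(df["n_windows"].max()),
        half_width_kb=h,
        n_per_position=df["n_windows"].to_numpy(),
    )


def write_fit_json(fits: dict[str, DomainFit], path) -> None:
    payload = {}
    for key, fit in fits.items():
        payload[key] = {
            "side": fit.side,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "window_kb": fit.window_kb,
            "pearson_r": fit.pearson_r,
            "amplitude": fit.amplitude,
            "magnitude_kb": fit.magnitude_kb,
            "amplitude_range": list(fit.amplitude_range),
            "magnitude_range": list(fit.magnitude_range),
            "detected": fit.detected,
            "n_points": fit.n_points,
        }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_json(path) -> dict[str, DomainFit]:
    raw = json.loads(Path(path).read_text())
    out = {}
    for key, d in raw.items():
        d = dict(d)
        d["amplitude_range"] = tuple(d["amplitude_range"])
        d["magnitude_range"] = tuple(d["magnitude_range"])
        out[key] = DomainFit(**d)
    return out
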