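"""Circular genome geometry.

A :class:`GenomeConfig` carries everything the track operations need to know
about the chromosome: its length, the bin size used for all per-kb tracks,
the positions of the replication origin (*oriC*) and the dimer-resolution
site (*dif*) that anchor the ori–ter axis, intervals that cannot be mapped
by short reads (the seven near-identical rRNA operons) and therefore get
imputed, and the macrodomain partition used for region statistics.

All coordinates are 0-based, half-open, in bp, and are reduced modulo the
genome length; intervals with ``end < start`` wrap through the origin of the
coordinate system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = ["GenomeConfig", "mg1655_config"]


@dataclass(frozen=True)
class GenomeConfig:
    """Geometry of one circular chromosome binned at fixed width.

    Parameters
    ----------
    genome_length_bp
        Total chromosome length in bp (> 0).
    bin_size_bp
        Bin width in bp; 1000 throughout the analyses. A trailing partial
        bin is allowed (``last_bin_partial``).
    oric_bp, dif_bp
        Replication origin and terminus-region *dif* site, bp.
    masked_intervals
        ``(start_bp, end_bp, label)`` triples of unmappable sequence whose
        bins are imputed from flanking signal.
    macrodomains
        ``(name, start_bp, end_bp)`` triples. When provided they must tile
        the circle without overlap.
    """

    genome_length_bp: int
    bin_size_bp: int = 1000
    oric_bp: int = 0
    dif_bp: int = 0
    masked_intervals: tuple[tuple[int, int, str], ...] = field(default_factory=tuple)
    macrodomains: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.genome_length_bp <= 0:
            raise ValueError("genome_length_bp must be positive")
        if self.bin_size_bp <= 0:
            raise ValueError("bin_size_bp must be positive")
        L = self.genome_length_bp
        object.__setattr__(self, "oric_bp", int(self.oric_bp) % L)
        object.__setattr__(self, "dif_bp", int(self.dif_bp) % L)
        object.__setattr__(
            self,
            "masked_intervals",
            tuple((int(s) % L, int(e) % L if int(e) % L else (L if e else 0), str(lab))
                  for s, e, lab in self.masked_intervals),
        )
        object.__setattr__(
            self,
            "macrodomains",
            tuple((str(n), int(s) % L, int(e) % L) for n, s, e in self.macrodomains),
        )
        if self.macrodomains:
            self._check_macrodomain_tiling()

    def _check_macrodomain_tiling(self) -> None:
        doms = sorted(self.macrodomains, key=lambda d: d[1])
        L = self.genome_length_bp
        total = sum(self.interval_length(s, e) for _, s, e in doms)
        if total != L:
            raise ValueError(
                f"macrodomains must tile the genome: cover {total} of {L} bp"
            )
        for (_, s1, e1), (_, s2, _) in zip(doms, doms[1:] + doms[:1]):
            if e1 % L != s2 % L:
                raise ValueError("macrodomains overlap or leave gaps")

    # -- geometry helpers ------------------------------------------------

    @property
    def n_bins(self) -> int:
        return math.ceil(self.genome_length_bp / self.bin_size_bp)

    @property
    def last_bin_partial(self) -> bool:
        """True when the final bin covers less than a full bin width."""
        return self.genome_length_bp % self.bin_size_bp != 0

    def wrap(self, pos_bp) -> int | np.ndarray:
        return np.asarray(pos_bp) % self.genome_length_bp if np.ndim(pos_bp) else int(pos_bp) % self.genome_length_bp

    def bin_of(self, pos_bp):
        """Bin index containing a bp position (vectorised)."""
        p = np.asarray(pos_bp) % self.genome_length_bp
        b = (p // self.bin_size_bp).astype(int)
        return b if b.ndim else int(b)

    def interval_length(self, start_bp: int, end_bp: int) -> int:
        """Length of a circular ``[start, end)`` interval (0 means empty)."""
        return (end_bp - start_bp) % self.genome_length_bp

    def bins_overlapping(self, start_bp: int, end_bp: int) -> np.ndarray:
        """Indices of every bin overlapping the circular interval [start, end)."""
        L, B = self.genome_length_bp, self.bin_size_bp
        s, e = start_bp % L, end_bp % L
        if self.interval_length(s, e) == 0:
            return np.empty(0, dtype=int)
        if s < e:
            return np.arange(s // B, (e - 1) // B + 1)
        head = np.arange(s // B, self.n_bins)
        tail = np.arange(0, (e - 1) // B + 1)
        return np.unique(np.concatenate([head, tail]))

    def circular_distance_bp(self, a_bp, b_bp):
        """Shortest arc distance between two bp positions."""
        L = self.genome_length_bp
        d = np.abs(np.asarray(a_bp) - np.asarray(b_bp)) % L
        return np.minimum(d, L - d)

    # -- I/O -------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "genome_length_bp": self.genome_length_bp,
            "bin_size_bp": self.bin_size_bp,
            "oric_bp": self.oric_bp,
            "dif_bp": self.dif_bp,
            "masked_intervals": [list(iv) for iv in self.masked_intervals],
            "macrodomains": [list(md) for md in self.macrodomains],
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeConfig":
        known = {
            "genome_length_bp", "bin_size_bp", "oric_bp", "dif_bp",
            "masked_intervals", "macrodomains",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown genome config keys: {sorted(unknown)}")
        kwargs = dict(d)
        kwargs["masked_intervals"] = tuple(
            tuple(iv) for iv in kwargs.get("masked_intervals") or ()
        )
        kwargs["macrodomains"] = tuple(
            tuple(md) for md in kwargs.get("macrodomains") or ()
        )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenomeConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def mg1655_config() -> GenomeConfig:
    """Default *E. coli* MG1655 (NC_000913) geometry.

    oriC/dif positions, the macrodomain partition (Ori, NS-R, Right, Ter,
    Left, NS-L) and the seven rRNA-operon mask intervals are external
    annotation shipped for convenience; coordinates are approximate and
    fully overridable by a user YAML. The mask intervals cover 35 one-kb
    bins in total, five per operon.
    """
    with resources.files("psorakit.data").joinpath("mg1655.yaml").open() as fh:
        return GenomeConfig.from_dict(yaml.safe_load(fh))
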