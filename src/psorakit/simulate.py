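"""Ground-truthed synthetic psoralen-pulldown datasets.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be tested end to end without deposited data:

* a transcriptome of non-overlapping oriented transcription units with
  log-normal expression and a handful of ribosomal-like units pinned at the
  reference rate (so their generative twin-domain amplitude equals
  ``amp_per_unit_expression`` exactly);
* a true supercoiling landscape: the additive twin-domain composite of the
  transcriptome plus a smooth non-transcriptional background field (real
  landscapes carry broad 50–100 kb variance far exceeding what the
  transcription model alone predicts); for symmetry studies the background
  is partially mirrored about a skewed ori–ter axis;
* an input library whose expected coverage follows the exponential
  ori→ter replication copy-number gradient, and a pulldown library whose
  expected coverage is the input expectation times ``2**(s + eps)`` with
  ``s`` the true per-bin log2 signal and ``eps`` log-scale replicate noise;
  both are Poisson-sampled at the requested read depth.

With this construction the pipeline's log2(pulldown/input) estimates
``s + eps`` directly (up to an additive constant), the copy-number gradient
cancels, and recovery of amplitudes, magnitudes and symmetry axes can be
scored against stored ground truth. Every output is a pure function of the
spec and its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import GenomeConfig
from .model import TwinDomainModelParams, compose_genome_model
from .tracks import BinnedTrack
from .twin_domain import TranscriptionUnit

__all__ = [
    "SyntheticGenomeSpec",
    "GroundTruth",
    "SyntheticDataset",
    "sample_transcriptome",
    "true_supercoiling_profile",
    "symmetric_landscape",
    "simulate_input_counts",
    "simulate_pulldown_counts",
    "generate_dataset",
]


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Study conditions for one synthetic dataset.

    Defaults emulate a rapidly growing *E. coli* culture measured by a
    psoralen-pulldown experiment: a 4.64-Mb circular genome binned at 1 kb,
    2,598 transcription units of which 7 are ribosomal-like and together
    carry ~70% of transcription, a 4:1 ori:ter copy-number gradient, one
    million reads per sample, and six replicate experiments. The true
    landscape is the twin-domain composite plus a smooth 50-kb-scale
    non-transcriptional background (log2 sd 0.25); with log-scale replicate
    bin noise of sd 0.05 on top of Poisson counting noise this reproduces
    the replicate-to-replicate track correlation (~0.75) typical of such
    data while the transcription component alone explains only a modest
    share of landscape variance, as observed in vivo.
    """

    genome_length_bp: int = 4_641_652
    bin_size_bp: int = 1000
    n_tus: int = 2598
    n_ribosomal: int = 7
    expression_sigma: float = 1.5  # log-normal shape of non-ribosomal rates
    ribosomal_fraction: float = 0.70  # share of total transcription on rrn-like TUs
    twin_params: TwinDomainModelParams = field(default_factory=TwinDomainModelParams)
    ori_ter_copy_ratio: float = 4.0
    reads_per_sample: int = 1_000_000
    bin_noise_sd: float = 0.05
    n_replicates: int = 6
    background_sd: float = 0.25  # log2 sd of the non-transcriptional field
    background_scale_kb: float = 50.0  # smoothness of that field
    symmetry_skew_deg: float | None = None
    symmetry_fraction: float = 0.66  # mirrored share of background variance
    rifampicin_factor: float = 1.0  # scales the whole true landscape
    oric_bp: int = 3_925_744
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_tus < self.n_ribosomal or self.n_ribosomal < 0:
            raise ValueError("need 0 <= n_ribosomal <= n_tus")
        if self.ori_ter_copy_ratio < 1:
            raise ValueError("copy ratio must be >= 1")
        if self.reads_per_sample <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.symmetry_fraction <= 1:
            raise ValueError("symmetry_fraction must lie in [0, 1]")

    def genome_config(self) -> GenomeConfig:
        return GenomeConfig(
            genome_length_bp=self.genome_length_bp,
            bin_size_bp=self.bin_size_bp,
            oric_bp=self.oric_bp,
            dif_bp=(self.oric_bp + self.genome_length_bp // 2) % self.genome_length_bp,
        )

    def require_rng(self, rng=None) -> np.random.Generator:
        if rng is not None:
            return rng
        if self.rng_seed is None:
            raise ValueError("stochastic generation requires an explicit rng_seed")
        return np.random.default_rng(self.rng_seed)


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the generative conditions."""

    profile: np.ndarray  # true per-bin log2 supercoiling signal
    per_tu_amplitude: dict[str, float]
    twin_params: TwinDomainModelParams
    copy_profile: np.ndarray  # relative copy-number expectation, mean 1
    skew_deg: float | None = None
    transcription_profile: np.ndarray | None = None  # twin-domain component
    background_profile: np.ndarray | None = None  # non-transcriptional component


@dataclass
class SyntheticDataset:
    spec: SyntheticGenomeSpec
    config: GenomeConfig
    tus: list[TranscriptionUnit]
    replicates: list[tuple[BinnedTrack, BinnedTrack]]  # (pulldown, input) counts
    truth: GroundTruth


RRN_LENGTH_BP = 5500
MIN_TU_LENGTH_BP = 1000
MAX_TU_LENGTH_BP = 6000
TU_LENGTH_EXP_SCALE_BP = 500


def sample_transcriptome(
    spec: SyntheticGenomeSpec, rng: np.random.Generator | None = None
) -> list[TranscriptionUnit]:
    """Place oriented TUs without overlap; pin ribosomal-like expression.

    Non-ribosomal lengths are 1 kb + Exp(0.5 kb) clipped at 6 kb
    (gene-dense bacterial scale); ribosomal-like TUs are 5.5 kb. Strands
    are random. Non-ribosomal expression is log-normal; each ribosomal TU
    gets the common rate making the ribosomal class carry
    ``ribosomal_fraction`` of total transcription, and that rate is the
    model's natural ``reference_expression``.
    """
    rng = spec.require_rng(rng)
    n, n_ribo = spec.n_tus, spec.n_ribosomal
    lengths = np.minimum(
        MIN_TU_LENGTH_BP
        + rng.exponential(TU_LENGTH_EXP_SCALE_BP, size=n - n_ribo),
        MAX_TU_LENGTH_BP,
    ).astype(int)
    lengths = np.concatenate([np.full(n_ribo, RRN_LENGTH_BP, dtype=int), lengths])
    order = rng.permutation(n)
    lengths = lengths[order]
    is_ribo = np.zeros(n, dtype=bool)
    is_ribo[np.flatnonzero(order < n_ribo)] = True
    total = int(lengths.sum())
    free = spec.genome_length_bp - total
    if free < n:  # need at least 1 bp gap per TU
        raise ValueError(
            f"genome too small: {spec.n_tus} TUs of total {total} bp on "
            f"{spec.genome_length_bp} bp"
        )
    gaps = rng.multinomial(free - n, np.full(n, 1.0 / n)) + 1
    start = int(rng.integers(spec.genome_length_bp))
    strands = rng.choice(["+", "-"], size=n)
    expr = np.empty(n)
    expr[~is_ribo] = rng.lognormal(mean=0.0, sigma=spec.expression_sigma,
                                   size=n - is_ribo.sum())
    if n_ribo:
        others = expr[~is_ribo].sum()
        f = spec.ribosomal_fraction
        expr[is_ribo] = (f / (1 - f)) * others / n_ribo if others > 0 else 1.0
    tus = []
    pos = start
    ribo_i = other_i = 0
    for i in range(n):
        s = pos
        e = pos + int(lengths[i])
        if is_ribo[i]:
            ribo_i += 1
            name = f"rrn_{ribo_i}"
        else:
            other_i += 1
            name = f"tu_{other_i:04d}"
        tus.append(
            TranscriptionUnit(
                name=name, start_bp=int(s), end_bp=int(e),
                strand=str(strands[i]), expression=float(expr[i]),
                ribosomal=bool(is_ribo[i]),
            )
        )
        pos = e + int(gaps[i])
    if pos - start > spec.genome_length_bp:
        raise ValueError("TU placement overran the genome")  # defensive
    # unwrap into canonical [0, L) starts with end possibly > L
    L = spec.genome_length_bp
    out = []
    for tu in tus:
        s = tu.start_bp % L
        out.append(replace_tu(tu, start_bp=s, end_bp=s + tu.length_bp))
    out.sort(key=lambda t: t.start_bp)
    return out


def replace_tu(tu: TranscriptionUnit, **kw) -> TranscriptionUnit:
    d = dict(
        name=tu.name, start_bp=tu.start_bp, end_bp=tu.end_bp, strand=tu.strand,
        expression=tu.expression, ribosomal=tu.ribosomal,
    )
    d.update(kw)
    return TranscriptionUnit(**d)


def true_supercoiling_profile(
    tus: list[TranscriptionUnit],
    twin_params: TwinDomainModelParams,
    config: GenomeConfig,
) -> BinnedTrack:
    """Deterministic composite twin-domain field (the generative truth)."""
    model = compose_genome_model(tus, twin_params, config, source="ground_truth")
    return BinnedTrack(config=config, values=model.values, kind="modeled")


def symmetric_landscape(
    spec: SyntheticGenomeSpec,
    config: GenomeConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth non-transcriptional background field, unit variance × sd.

    A Gaussian random field with ``background_scale_kb`` smoothness. When
    ``symmetry_skew_deg`` is set, ``symmetry_fraction`` of its variance is
    mirror-symmetric about the axis through oriC skewed counterclockwise by
    that many degrees (the remainder is an independent asymmetric field),
    emulating the partial replichore symmetry of measured landscapes.
    """
    n = config.n_bins
    L = config.genome_length_bp
    sigma_bins = max(1.0, spec.background_scale_kb * 1000 / config.bin_size_bp / 2.355)

    def smooth_noise() -> np.ndarray:
        x = gaussian_filter1d(rng.standard_normal(n), sigma_bins, mode="wrap")
        sd = x.std()
        return x / sd if sd > 0 else x

    if spec.symmetry_skew_deg is None:
        return spec.background_sd * smooth_noise()
    skew = spec.symmetry_skew_deg
    axis_bp = int(round(config.oric_bp - skew * L / 360.0)) % L
    b = config.bin_of(axis_bp)
    arm = smooth_noise()
    sym = np.empty(n)
    k = np.arange(n)
    sym[(b + k) % n] = arm[k]
    half = n // 2
    k = np.arange(1, half + (0 if n % 2 == 0 else 1))
    sym[(b - k) % n] = sym[(b + k) % n]
    asym = smooth_noise()
    f = spec.symmetry_fraction
    landscape = math.sqrt(f) * sym + math.sqrt(1 - f) * asym
    return spec.background_sd * landscape


def _copy_number_weights(spec: SyntheticGenomeSpec, config: GenomeConfig) -> np.ndarray:
    """Relative copy number per bin: exponential decay with distance from
    oriC, reaching 1/ori_ter_copy_ratio at the antipode; normalized mean 1."""
    centers = (np.arange(config.n_bins) + 0.5) * config.bin_size_bp
    d = config.circular_distance_bp(centers, config.oric_bp)
    half = config.genome_length_bp / 2
    w = np.power(2.0, -(d / half) * math.log2(spec.ori_ter_copy_ratio))
    return w / w.mean()


def simulate_input_counts(
    spec: SyntheticGenomeSpec,
    config: GenomeConfig | None = None,
    rng: np.random.Generator | None = None,
) -> BinnedTrack:
    """Poisson input library following the replication copy-number gradient."""
    config = config or spec.genome_config()
    rng = spec.require_rng(rng)
    w = _copy_number_weights(spec, config)
    lam = spec.reads_per_sample * w / w.sum()
    counts = rng.poisson(lam).astype(float)
    return BinnedTrack(config=config, values=counts, kind="count")


def simulate_pulldown_counts(
    spec: SyntheticGenomeSpec,
    true_profile: np.ndarray,
    input_expectation: np.ndarray,
    rng: np.random.Generator | None = None,
    config: GenomeConfig | None = None,
) -> BinnedTrack:
    """Poisson pulldown library: expectation ∝ input × 2**(s + eps)."""
    config = config or spec.genome_config()
    rng = spec.require_rng(rng)
    s = np.asarray(true_profile, dtype=float)
    eps = rng.normal(0.0, spec.bin_noise_sd, size=config.n_bins) if spec.bin_noise_sd else 0.0
    w = np.asarray(input_expectation, dtype=float) * np.power(2.0, s + eps)
    lam = spec.reads_per_sample * w / w.sum()
    counts = rng.poisson(lam).astype(float)
    return BinnedTrack(config=config, values=counts, kind="count")


def generate_dataset(
    spec: SyntheticGenomeSpec, rng: np.random.Generator | None = None
) -> SyntheticDataset:
    """End-to-end bundle: transcriptome, truth, replicate count tracks.

    The true landscape is the additive twin-domain composite of the sampled
    transcriptome plus the smooth background field (partially mirrored
    about the skewed axis when ``symmetry_skew_deg`` is set), all scaled by
    ``rifampicin_factor`` (0 emulates full shutdown: a flat truth).
    Deterministic under the spec's seed.
    """
    rng = spec.require_rng(rng)
    config = spec.genome_config()
    tus = sample_transcriptome(spec, rng)
    ribo = [tu.expression for tu in tus if tu.ribosomal]
    params = spec.twin_params
    if params.reference_expression is None and ribo:
        params = replace(params, reference_expression=float(np.mean(ribo)))
    transcription = true_supercoiling_profile(tus, params, config).values
    background = (
        symmetric_landscape(spec, config, rng)
        if spec.background_sd > 0
        else np.zeros(config.n_bins)
    )
    profile = (transcription + background) * spec.rifampicin_factor
    ref = params.reference_expression or 1.0
    per_tu_amp = {
        tu.name: spec.rifampicin_factor
        * params.amp_per_unit_expression * tu.expression / ref
        for tu in tus
    }
    truth = GroundTruth(
        profile=profile,
        per_tu_amplitude=per_tu_amp,
        twin_params=params,
        copy_profile=_copy_number_weights(spec, config),
        skew_deg=spec.symmetry_skew_deg,
        transcription_profile=transcription * spec.rifampicin_factor,
        background_profile=background * spec.rifampicin_factor,
    )
    w_input = truth.copy_profile
    replicates = []
    for _ in range(spec.n_replicates):
        inp = simulate_input_counts(spec, config, rng)
        pull = simulate_pulldown_counts(spec, profile, w_input, rng, config)
        replicates.append((pull, inp))
    return SyntheticDataset(spec=spec, config=config, tus=tus,
                            replicates=replicates, truth=truth)
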