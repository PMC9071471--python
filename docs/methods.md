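# Methods

This note documents the statistical models, parameter choices and
numerical conventions behind `psorakit`, and what the synthetic-data
validation does and does not establish.

## Measurement model

Psoralen intercalation increases with helical under-winding, so the ratio
of psoralen-pulldown to input sequencing coverage is a monotone readout of
*relative* supercoiling; the absolute supercoiling density σ is not
identifiable from pulldown data and is never reported. The measurement
chain is:

1. **Binning.** Aligned fragments are assigned to fixed-width bins
   (default 1 kb) by their circular midpoint. Midpoint assignment is
   robust to fragment-length variation (~500 bp sonication) and conserves
   the total fragment count exactly. Coordinates are 0-based, half-open,
   reduced modulo the genome length; text outputs report bins 1-based.
2. **Imputation.** Bins overlapping annotated unmappable intervals (the
   seven near-identical rRNA operons; 35 one-kb bins in the bundled
   MG1655 annotation) are replaced by the mean of the nearest 3 unmapped-
   free bins on each side (6 kb total). If a flank runs into another
   masked interval the search extends outward past it with a logged
   warning. Imputed bins are flagged but remain usable; they carry
   plausible values and participate in means and regressions.
3. **Normalization.** Counts are divided by their mean over valid bins, so
   a value of 1 is the genome average. Forming log2(pulldown/input) then
   cancels the replication copy-number gradient and shared sequencing
   bias. Bins with a zero count on either side are masked rather than
   pseudocounted — at typical depths (≈100–650 reads per kb) zeros are
   rare, and masking avoids distorting log ratios; masked bins are
   excluded from every downstream statistic.
4. **Smoothing / standardization.** Circular centered moving averages
   (window given in kb, converted to the nearest odd bin count) and
   population-SD z-scores over valid bins.

Two per-bin flags are carried through the chain: `mask` (no usable value;
excluded everywhere) and `imputed` (value replaced from flanks; usable but
flagged). Conflating the two would force a choice between dropping the
rRNA-proximal bins from twin-domain regressions and treating zero-count
bins as data; keeping them separate supports both behaviors.

## Twin-domain quantification

Around each transcription unit an 81-position window (±40 kb of the unit
midpoint, 1 position per kb) is extracted in transcription orientation
(minus-strand windows are reversed). Each window is centered to zero mean
over its full range, and windows are averaged position-wise into a
consensus profile with per-position SEM, skipping masked entries.

Each side of the consensus is fit by an **expanding-window least-squares
regression**: distances d = 1..k kb from the midpoint, k starting at 10
and extended 1 kb at a time; the retained k maximizes |Pearson r|. The
default implementation scans every k in [10, 40] and takes the global
maximum (ties to the smallest k); a greedy variant that stops at the first
decline of |r| is available (`stop_rule="greedy"`). |r| rather than signed
r is maximized because the upstream and downstream limbs slope in opposite
directions. The regression starts at d = 1 kb — the midpoint bin itself is
excluded, since the modeled signal crosses zero there.

The y-intercept is the **amplitude** (log2 fold-change at the midpoint,
signed: positive upstream, negative downstream) and the x-intercept
(−intercept/slope) the **magnitude** in kb. A fitted line whose slope and
intercept share a sign never crosses zero at positive distance; such sides
are flagged "no domain detected". 95% ranges for both quantities come from
the pointwise 95% confidence band of the fitted mean line,
ŷ(x) ± t₀.₉₇₅,ₖ₋₂·s·√(1/k + (x−x̄)²/Sxx): the amplitude range is the band
at x = 0 and the magnitude range the two roots of band(x) = 0, obtained in
closed form from the quadratic (a+bx)² = t²s²(1/k + (x−x̄)²/Sxx).

Genome-wide per-unit amplitudes are measured non-parametrically as the
enrichment 5 kb upstream of the 5′ boundary minus the enrichment 5 kb
downstream of the 3′ boundary, in transcription orientation — positive for
a canonical twin-domain, sign-flipping under strand inversion.

## Additive transcription model

Each transcription unit contributes a triangle: +A adjacent to the
midpoint decaying linearly to zero at `neg_magnitude_kb` upstream, −A
decaying to zero at `pos_magnitude_kb` downstream, with the sign crossing
at the midpoint (the midpoint bin itself is zero). The per-unit amplitude
is A = `amp_per_unit_expression` × (expression / reference_expression),
where the reference is the mean expression of units flagged ribosomal
(an explicit `reference_expression` must be supplied when none are
flagged, because the amplitude scale is anchored to ribosomal rates). No
cap is applied to units expressed above the reference. Defaults:
`amp_per_unit_expression` = 0.38 log2 units, magnitudes 23 kb (upstream,
negative/under-wound) and 25 kb (downstream, positive/over-wound).

Contributions are summed over the circular genome; the composite is linear
in the TU list and equivariant under genome rotation. For comparison with
measured tracks the model can be affinely rescaled so its extrema match
the measured extrema, with both extrema taken on 50-kb-smoothed copies
(the scale at which such comparisons are made; raw extrema optional).
Affine rescaling leaves every Pearson correlation unchanged. Model fitness
is the genome-wide Pearson r against each replicate track (mean ± SEM),
optionally per region, plus a 300-kb circular sliding-window r profile
with pairwise exclusion of masked bins.

## Replichore symmetry and region statistics

Skew is measured in degrees of the circular map, 1° = genome_length/360 bp,
counterclockwise positive; with coordinates drawn clockwise, the axis
point is oriC − skew·L/360 (mod L). Arm series read the smoothed track
(default 100-kb window) outward from the axis point in both directions, to
half the genome minus the smoothing half-window (the axis antipode, not
*dif*, terminates the arms). Symmetry is the Pearson r between the two arm
series; the skew scan evaluates a grid (default −90°..90° in 1° steps) and
reports the maximum, ties broken toward the smallest |skew|. The scan is
equivariant under genome rotation and invariant under affine transforms of
the track.

Region statistics compute per-region means over valid bins for each
replicate, then compare regions pairwise: an F test for equality of the
two variance estimates, followed by a paired two-tailed t test across
replicates (df = n_replicates − 1), starred at 0.05/0.01/0.001/0.0001.
No multiple-testing correction is applied by default, matching common
reporting practice for these region panels; a Bonferroni flag exists.

Signal-defined regions ("psoralen enriched"/"depleted") are maximal
circular runs of smoothed z-scores beyond ±`threshold_sd`, dropping runs
shorter than `min_length_kb`. The defaults — 100-kb smoothing, 0.5 SD,
20 kb minimum — are this package's own analysis choice; published region
panels of this kind do not state their construction, so counts of such
regions are parameter-dependent. External binned tracks (nucleoid
proteins, topoisomerases), standardized to z-scores, are scored within
region classes by the class mean ± SEM and a one-sample two-tailed t test
of region means against zero (df = n_regions − 1); a two-sample variant
between classes is available.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated. Defaults: a 4,641,652-bp circular genome at 1-kb bins; 2,598
transcription units, 7 of them ribosomal-like (5.5 kb, pinned to the
common expression making the class carry 70% of total transcription — so
the generative ribosomal amplitude is exactly `amp_per_unit_expression`);
other lengths 1 kb + Exp(0.5 kb) clipped at 6 kb, placed without overlap
with multinomial gaps (mean gap < 1 kb); strands random; non-ribosomal
expression log-normal (σ = 1.5 in ln units, spanning ~4 orders of
magnitude).

The true landscape is the additive twin-domain composite **plus a smooth
non-transcriptional background**: a Gaussian random field with 50-kb
correlation scale and log2 SD 0.25. The background is essential realism —
measured landscapes vary several-fold at 50–100-kb scale while the
transcription component alone has log2 SD ≈ 0.06, which is precisely why
additive transcription models explain only part of the variance in vivo.
For symmetry studies a stated fraction of the background variance
(default 0.66) is mirror-symmetric about an axis skewed by
`symmetry_skew_deg`; the default fraction makes the measured arm
correlation of synthetic landscapes match the partial symmetry reported
for real chromosomes. A `rifampicin_factor` scales the whole landscape
(0.12 emulates the near-complete loss of transcription-dependent
supercoiling after RNA-polymerase arrest; 0 gives a flat truth).

Counts: the input expectation follows an exponential ori→ter copy-number
gradient reaching 1/`ori_ter_copy_ratio` (default 4) at the antipode — a
single-gradient approximation without a multi-fork cell-cycle model. The
pulldown expectation is input × 2^(s + ε), with s the true log2 landscape
and ε per-bin Normal(0, `bin_noise_sd` = 0.05) replicate noise on the log
scale (multiplicative, keeping counts non-negative and matching the
pipeline's log-ratio estimand). Both libraries are Poisson-sampled at
`reads_per_sample` (default 10⁶). With this construction the enrichment
pipeline estimates s + ε up to an additive constant, so recovery is
scored directly against stored ground truth. Every output is a pure
function of the spec and its mandatory seed.

With these defaults the mean pairwise replicate correlation of enrichment
tracks is ≈ 0.72 and the transcription-model fitness ≈ 0.15–0.2 — both
recomputed, not asserted, by `scripts/acceptance.py`. The combination of
high replicate reproducibility (≈ 0.75) with modest model fitness
(≈ 0.3) reported for real data is not reachable at 10⁶ reads, where
Poisson noise alone (log2 variance ≈ 0.02 per bin) bounds the replicate
correlation given the landscape variance; at several-fold higher depth
the two are compatible. The defaults keep the 10⁶-read condition and
accept a slightly lower fitness.

## Validation: what passing tests show

The acceptance suite establishes, end to end through the count-level
pipeline: exact recovery of amplitude and magnitudes (≤ 10⁻⁶) on
noiseless piecewise-linear profiles, for any retained window; equality of
the expanding-window rule with an exhaustive max-|r| scan on random
profiles; recovery of generative amplitude (within 15%) and magnitudes
(within 3 kb) in ≥ 90% of 100 simulated ribosomal-recovery experiments at
amplitudes 0.38 and 0.6; symmetry-axis recovery within ±2° at skews of
−20°, 0° and 14° in ≥ 90% of 100 repeats; and monotone convergence of the
recovered track to the generative landscape with sequencing depth
(r > 0.9 at 10⁷ reads).

These are statements about the estimators under the generator's
assumptions (additive triangles, log-scale noise, Poisson counting, a
single smooth background). They do not establish accuracy on real data,
where psoralen chemistry, crosslinking efficiency, mappability and
topoisomerase dynamics contribute structure the generator does not
emulate; headline quantities from deposited sequencing data can be
reproduced by running the same stages on those data.

## Known limitations

* **Weak domains.** At generative amplitude 0.2 (half the ribosomal
  scale) the amplitude estimate stays within 15% in ≥ 90% of repeats, but
  the magnitude x-intercept has ≈ 2-kb SD at that signal-to-noise — its
  estimates are unbiased, yet a 3-kb tolerance holds in only ~85% of
  repeats. Magnitudes of weak domains should be read with their 95%
  ranges, not as point values.
* The triangle shape between the two signed peaks is a modeling choice
  (a step-at-midpoint variant would differ only inside the unit body);
  the measured consensus constrains the limbs, not the interior.
* Enriched/depleted region counts depend on smoothing, threshold and
  minimum-length parameters that have no canonical published values.
* The copy-number gradient is a steady-state exponential; replication
  checkpointing, multi-fork replication and growth-phase shifts are out
  of scope, as are read alignment, GC correction (a diagnostic is
  provided, a correction is not) and absolute supercoiling density.
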