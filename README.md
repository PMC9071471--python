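# psorakit

Psoralen-pulldown supercoiling landscapes for circular bacterial genomes.

DNA supercoiling regulates replication, transcription and recombination,
but it is hard to measure genome-wide. Psoralen intercalates into duplex
DNA at a rate proportional to helical tension — strongest in under-wound
(negatively supercoiled) DNA — so sequencing psoralen-enriched fragments
against an input library turns relative psoralen binding into a relative
supercoiling map. `psorakit` implements the computational side of such an
experiment for a circular bacterial chromosome (*E. coli* by default):

* **Enrichment tracks** — bin aligned fragments at 1 kb, impute unmappable
  rRNA-operon bins from flanking signal, normalize pulldown and input to
  the genome average and form log2(pulldown/input). The input library
  cancels the replication copy-number gradient and sequencing bias.
* **Transcription twin-domains** — a translocating RNA polymerase
  under-winds the DNA behind it and over-winds the DNA ahead of it
  (Liu–Wang twin-domain). The package builds strand-oriented consensus
  profiles around transcription units and quantifies each side with an
  expanding-window linear regression: over distances 1..k kb from the unit
  midpoint the fit is extended 1 kb at a time and the extent maximizing
  |Pearson r| is kept. The regression **y-intercept is the domain
  amplitude** (log2 fold-change at the midpoint) and the **x-intercept the
  domain magnitude** (kb of supercoil diffusion); 95% ranges come from the
  intercepts of the pointwise 95% confidence band.
* **Additive supercoiling model** — every transcription unit contributes a
  triangular twin-domain, +A·(1−d/m₋) upstream and −A·(1−d/m₊) downstream
  (defaults A = 0.38 per ribosomal-equivalent expression, m₋ = 23 kb,
  m₊ = 25 kb), summed over the circular genome and compared with measured
  tracks genome-wide and in 300-kb sliding windows.
* **Replichore symmetry and regions** — correlate the left and right
  chromosome arms about an ori–ter axis swept over angular skews,
  and compare mean supercoiling across macrodomains, hemi-genomes and
  signal-defined regions with an equal-variance F test followed by a
  paired two-tailed t test across replicate experiments.
* **Synthetic data** — a ground-truthed generator (transcriptome with
  log-normal expression and ribosomal-like operons, exponential ori→ter
  copy-number gradient, Poisson-sampled pulldown/input counts whose
  expectation follows 2^(signal)) makes every stage testable end to end
  without any external data.

## Worked example

Simulate a six-replicate experiment under the default study conditions and
measure the ribosomal twin-domain it contains:

```python
import psorakit as pk

spec = pk.SyntheticGenomeSpec(rng_seed=7)          # 4.64 Mb, 2598 TUs, 1M reads
ds = pk.generate_dataset(spec)
enr = [pk.enrichment_from_counts(pull, inp) for pull, inp in ds.replicates]

rrn = [tu for tu in ds.tus if tu.ribosomal]
windows = [pk.extract_oriented_window(t, tu, half_width_kb=40)
           for t in enr for tu in rrn]
profile = pk.consensus_profile(windows)            # 7 operons x 6 replicates
up = pk.fit_domain_regression(profile, "upstream")
dn = pk.fit_domain_regression(profile, "downstream")
print(f"upstream domain:   amplitude {up.amplitude:+.2f}, "
      f"magnitude {up.magnitude_kb:.1f} kb, r = {up.pearson_r:.2f}")
print(f"downstream domain: amplitude {dn.amplitude:+.2f}, "
      f"magnitude {dn.magnitude_kb:.1f} kb, r = {dn.pearson_r:.2f}")

rep = pk.replicate_correlation(enr)
print(f"replicate reproducibility: mean pairwise r = {rep['mean_r']:.2f}")
```

This prints:

```
upstream domain:   amplitude +0.41, magnitude 23.0 kb, r = -0.98
downstream domain: amplitude -0.43, magnitude 22.4 kb, r = 0.93
replicate reproducibility: mean pairwise r = 0.72
```

The generative truth in this dataset places ±0.38 twin-domains of 23/25 kb
at the seven ribosomal-like operons; the fitted amplitudes and magnitudes
recover them through the full count-level pipeline, and the replicate
correlation reflects the generator's counting plus per-bin noise on top of
the landscape. The negative upstream r is expected: psoralen binding
*decays* with distance from the operon on that side.

The same stages are available from the shell via the `psorakit` command
(`simulate`, `bin`, `enrich`, `consensus`, `fit`, `model`, `slide-corr`,
`symmetry`, `regions`, `run`); every command writes a JSON run manifest
with resolved parameters, input checksums and the seed.

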