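# E. coli K-12 MG1655 (NC_000913) circular genome geometry.
# External annotation, approximate coordinates; override with your own YAML
# as needed. Masked intervals are the seven rRNA operons, unmappable by
# short reads; they cover exactly 35 one-kb bins (5 per operon).
genome_length_bp: 4641652
bin_size_bp: 1000
oric_bp: 3925744
dif_bp: 1588774
masked_intervals:
  - [223500, 228000, rrnH]
  - [2729500, 2734000, rrnG]
  - [3423500, 3428000, rrnD]
  - [3941500, 3946000, rrnC]
  - [4035500, 4040000, rrnA]
  - [4166500, 4171000, rrnB]
  - [4208500, 4213000, rrnE]
macrodomains:
  - [Right, 300000, 1200000]
  - [Ter, 1200000, 2000000]
  - [Left, 2000000, 2800000]
  - [NS-L, 2800000, 3600000]
  - [Ori, 3600000, 4400000]
  - [NS-R, 4400000, 300000]
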