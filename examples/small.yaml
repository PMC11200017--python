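# A small two-chromosome run that finishes in a few seconds.
sim:
  chrom_lengths:
    chr1: 4000000
    chr2: 2000000
  bin_size: 20000
  n_contacts: 120000
  pairing_blocks:
    - ["chr1", 1000000, 1500000, 8.0]
  seed: 7
stages: ["E15", "D1"]
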