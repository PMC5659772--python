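# Demo study: three 200-kb chromosomes, four MNase concentrations,
# two replicates of control / clamp_rnai / msl2_rnai.
seed: 7
simulate:
  chrom_sizes:
    chrX: 200000
    chr2L: 200000
    chr2R: 200000
  depth: 200000
  n_genes: 60
  n_enhancers: 15
  n_peaks_x: 8
  n_peaks_autosome: 4
score:
  bin_size: 100
  z_threshold: 7.0
  size_range: [100, 200]
differential:
  p_threshold: 0.01
profiles:
  peak_flank: 5000
  ces_flank: 500
  metagene_flank: 500
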