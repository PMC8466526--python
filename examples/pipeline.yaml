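# Full example pipeline configuration.
#
# Every key is optional; defaults reproduce the standard synthetic study
# (4 groups x 50 cells). `input_path` switches from the synthetic
# generator to a stored spectra table.

seed: 42
out_dir: pipeline_out
n_per_group: 25

groups:
  - [GIC7, control]
  - [GIC7, 200uM]
  - [PG88, control]
  - [PG88, 200uM]

# region recipes: emsc_snv (fingerprint/lipids) or emsc_d2_uvn (DNA)
pca_regions:
  - [dna, emsc_d2_uvn]
  - [fingerprint, emsc_snv]
  - [lipids, emsc_snv]
pca_components: 3

metrics: [bh_index, unsaturation_index, ch3_ch2_ratio]

comparisons:
  - [[GIC7, control], [GIC7, 200uM]]
  - [[PG88, control], [PG88, 200uM]]
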