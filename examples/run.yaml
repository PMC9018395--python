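# Example full-pipeline configuration for `momp-screen run-all`.
# A reduced image-mode screen: 6 genes + controls on an 8x12 plate in
# triplicate, 2 sites per well, 256x256 px fields.  Raise plate_format,
# sites_per_well and image_shape toward the full assay (16x24 plate,
# 16 sites, 1024x1024) for production-scale runs.
n_genes: 6
replicates: 3
mode: images
spiked:
  G00002:
    III: 6.0
simulation:
  image_shape: [256, 256]
  plate_format: [8, 12]
  excluded_edge: 1
  sites_per_well: 2
  cells_per_field: 12.0
min_cells_per_well: 10
tail_fraction: 0.10
min_concordant: 3
seed: 5
outdir: mompscreen_run
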