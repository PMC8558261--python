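# Generator presets for the two study-like populations.
#
# Contrasts encoded (TG-like vs WT-like): reduced apical tuft, slightly
# thinner and shorter dendrites, spine density 1.00 vs 1.25 /μm, larger
# soma (205.2 vs 146.2 μm² sphere).  Values are the package's calibration
# of a qualitatively pyramidal-like tree, not fits to reconstructions.
wt_like:
  n_basal_stems: 5
  branch_probability: 0.55
  segment_length_mean: 46.0
  segment_length_sd: 18.0
  stem_diameter: 1.6
  taper_ratio: 0.78
  apical_trunk_length: 360.0
  tuft_size_factor: 1.0
  spine_density: 1.25
  max_total_extent: 650.0
  soma_radius: 3.411

tg_like:
  n_basal_stems: 5
  branch_probability: 0.56
  segment_length_mean: 50.0
  segment_length_sd: 16.0
  stem_diameter: 1.3
  taper_ratio: 0.75
  apical_trunk_length: 320.0
  tuft_size_factor: 0.6
  spine_density: 1.00
  max_total_extent: 600.0
  soma_radius: 4.041
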