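# Default study configuration: three groups, paired untreated/phosphatase-treated
# LC-MS runs, and velocity-pCa motility curves per condition.
seed: 12345

lcms:
  n_replicates: 3
  loading_sigma: 0.2
  noise_cv: 0.10
  phosphatase_completeness: 1.0
  groups:
    control:
      tni_mono_fraction: 0.15
      tni_bis_fraction: 0.05
      tm_phospho_fraction: 0.10
      tni_truncated_fraction: 0.0
      met_oxidation_probs: [0.80, 0.15, 0.05]
      tni_cterm_oxidation: 0.10
    IR2:
      tni_mono_fraction: 0.0405   # 0.27 x control mono
      tni_bis_fraction: 0.21      # 4.2 x control bis
      tm_phospho_fraction: 0.20
      tni_truncated_fraction: 0.0
      met_oxidation_probs: [0.80, 0.15, 0.05]
      tni_cterm_oxidation: 0.10
    IDNR:
      tni_mono_fraction: 0.0285   # 0.19 x control mono
      tni_bis_fraction: 0.14      # 2.8 x control bis
      tm_phospho_fraction: 0.10
      tni_truncated_fraction: 0.0
      met_oxidation_probs: [0.80, 0.15, 0.05]
      tni_cterm_oxidation: 0.10

motility:
  frame_interval: 0.1     # s (10 frames/s)
  n_frames: 300           # 30 s videos
  n_filaments: 30
  speed_cv: 0.10
  noise_sd: 0.05          # um localization noise per coordinate per frame
  fraction_moving_max: 0.9
  pca_grid: [6.8, 6.6, 6.4, 6.2, 6.0, 5.5, 5.0, 4.0]
  conditions:
    control: {vmax: 4.0, pca50: 6.34, n: 1.89}
    IR2:     {vmax: 4.0, pca50: 6.47, n: 1.27}
    IDNR:    {vmax: 5.0, pca50: 6.57, n: 3.46}
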