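# Default synthetic cohort composition and group-level truth distributions.
n_collected: 236
exclusions:
  small_lesion: 10
  no_pathology: 5
  poor_quality: 8
n_benign: 83
n_malignant: 130
benign_histology:
  fibroadenoma: 47
  adenopathy: 15
  inflammatory_lesion: 6
  intraductal_papilloma: 5
  foliate_tumor: 10
malignant_histology:
  invasive_carcinoma: 113
  invasive_lobular_carcinoma: 4
  ductal_carcinoma_in_situ: 11
  lymphoma: 2
er_pos: 87
pr_pos: 73
her2_pos: 46
ki67_high: 104
grades:
  I: 4
  II: 67
  III: 46
subtypes:
  LuminalA: 8
  LuminalB: 71
  HER2over: 26
  TN: 12
param_distributions:
  benign:
    d_mean: [14.38, 4.645]    # um
    f_in: [0.279, 0.212]
    D_ex: [2.378, 0.332]      # um^2/ms
  malignant:
    d_mean: [15.74, 2.677]
    f_in: [0.346, 0.125]
    D_ex: [2.119, 0.395]
fd_correlation: 0.7
rng_seed: 0
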