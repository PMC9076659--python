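nodes:
- dpfc_base
- dpfc_change
- cannabis_change
- tobacco_base
- tobacco_change
- alcohol_base
- alcohol_change
- handedness
- age_base
- cannabis_prs
- ses
- puberty
- adhd_base
- adhd_change
- trauma
- ss_base
- ss_change
arcs:
- from: adhd_base
  to: adhd_change
  weight: -0.56
- from: adhd_base
  to: cannabis_change
  weight: 0.08
- from: adhd_base
  to: dpfc_change
  weight: -0.08
- from: age_base
  to: dpfc_base
  weight: -0.13
- from: age_base
  to: puberty
  weight: 0.23
- from: alcohol_base
  to: alcohol_change
  weight: -0.32
- from: alcohol_base
  to: cannabis_change
  weight: 0.14
- from: cannabis_change
  to: dpfc_change
  weight: -0.2
- from: cannabis_prs
  to: cannabis_change
  weight: 0.1
- from: dpfc_base
  to: dpfc_change
  weight: -0.5
- from: dpfc_base
  to: tobacco_base
  weight: -0.13
- from: puberty
  to: alcohol_base
  weight: 0.15
- from: ses
  to: adhd_base
  weight: -0.1
- from: ses
  to: tobacco_base
  weight: -0.16
- from: ss_base
  to: alcohol_base
  weight: 0.18
- from: ss_base
  to: cannabis_change
  weight: 0.08
- from: ss_base
  to: ss_change
  weight: -0.49
- from: ss_base
  to: tobacco_base
  weight: 0.12
- from: tobacco_base
  to: alcohol_base
  weight: 0.36
- from: tobacco_base
  to: cannabis_change
  weight: 0.18
- from: tobacco_change
  to: alcohol_change
  weight: 0.26
- from: tobacco_change
  to: cannabis_change
  weight: 0.45
site_effect_sd: 0.15
sex_effect_sd: 0.15
nuisance_seed: 20240101
n_default: 637
wave_pairs:
- - dpfc_base
  - dpfc_change
  - dpfc
hemisphere_splits:
- latent: dpfc_base
  left: dpfc14_lh
  right: dpfc14_rh
  correlation: 0.8
- latent: dpfc_change
  left: dpfc_change_lh
  right: dpfc_change_rh
  correlation: 0.8
ordinal_columns:
- cannabis_change
- tobacco_base
- tobacco_change
- alcohol_base
- alcohol_change
ordinal_cutpoints:
- 0.0
- 0.55
- 1.0
- 1.4
- 1.8
- 2.2
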