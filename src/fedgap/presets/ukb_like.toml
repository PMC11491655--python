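# UK-Biobank-like cohort preset.
# Observed (truncated) age distribution: mean 52.32, sd 7.98, range [40, 74].
# 8434 subjects = 8315 healthy + 119 disease (type-1-diabetes-like, +3.5 y
# retinal age offset). Noise parameters calibrated once so a closed-form ridge
# readout attains a held-out MAE in the 3-4 year band (see docs/methods.md).
[cohort]
preset = "ukb_like"
n_subjects = 8434
age_mean = 52.32
age_sd = 7.98
age_min = 40.0
age_max = 74.0
feature_dim = 1024
n_centers = 8
signal_strength = 2.0
nonlinearity_coef = 0.15
latent_sd = 0.58
site_sd = 0.05
eye_sd = 0.10
noise_sd = 0.10
disease_fraction = 0.014109
disease_offset = 3.5
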