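# BRSET-like cohort preset (external validation population).
# Observed (truncated) age distribution: mean 46.97, sd 17.46, range [6, 91].
# 693 subjects = 479 healthy + 214 disease.
[cohort]
preset = "brset_like"
n_subjects = 693
age_mean = 46.97
age_sd = 17.46
age_min = 6.0
age_max = 91.0
feature_dim = 1024
n_centers = 8
signal_strength = 2.0
nonlinearity_coef = 0.15
latent_sd = 0.58
site_sd = 0.05
eye_sd = 0.10
noise_sd = 0.10
disease_fraction = 0.308802
disease_offset = 3.5
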