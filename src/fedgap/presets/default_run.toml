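# Full default experiment: 10 Monte-Carlo iterations x 5 training sizes x
# 3 strategies on the UK-Biobank-like cohort with 8-bit quantized features.
schema = "fedgap-run-v1"
seed = 0
out_dir = "runs/default"

[cohort]
preset = "ukb_like"
quantize_bits = 8

[split]
n_train = [150, 300, 600, 1200, 2400]
n_val = 1200
train_centers = [0, 1, 2, 3, 4]
test_centers = [5, 6, 7]
mc_iterations = 10

[protocol]
strategies = ["central", "fl", "tm"]
max_rounds = 200
patience = 10
fl_clients_per_round = 32
local_epochs = 1
batch_size_central = 64
lr = 5e-3
weight_decay = 1e-4

[stats]
bin_width = 5.0
B = 10000
alpha = 0.05
n_comparisons_mae = 15
n_comparisons_rag = 6
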