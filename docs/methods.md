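# Methods

This note documents the generative model behind the synthetic cohorts, the
training protocols and their cost accounting, the statistical procedures, and
the design decisions taken where the design was genuinely open. Everything
stated here is computed by the test suite or the example scripts; nothing is
an empirical claim about real retinal data.

## 1. Synthetic embedding cohorts

### Generative model

Each subject *i* contributes two records (left and right eye). A record's
1024-dimensional feature vector is

```
x = s_i · u + c_center(i) + e_eye + ε
s_i = A · (z_i + q·z_i² + η_i)
z_i = (age_i + δ_i − μ_ref) / σ_ref
```

with

| symbol | parameter | default | meaning |
| --- | --- | --- | --- |
| A | `signal_strength` | 2.0 | embedding amplitude of the age signal (dimensionless feature units) |
| q | `nonlinearity_coef` | 0.15 | quadratic departure from a linear age trend |
| η | `latent_sd` | 0.58 | subject-level biological deviation from the age norm, in z-units; **shared by both eyes** |
| δ | `disease_offset` | +3.5 y | age-acceleration applied inside z for disease subjects |
| u | — | seeded unit vector | fixed signal direction in feature space |
| c | `site_sd` | 0.05 | per-center offset vector, N(0, site_sd²·I) |
| e | `eye_sd` | 0.10 | per-eye-side offset vector (L/R, shared across subjects) |
| ε | `noise_sd` | 0.10 | isotropic per-record noise, N(0, noise_sd²·I) |
| μ_ref, σ_ref | `ref_age_mean/sd` | 52.32 / 7.98 y | the encoder's age standardization |

Two structural choices deserve emphasis:

* **The prediction-limiting noise is biological, not sensor-level.** The
  dominant error source is η, a *subject-level* scatter inside the latent age
  signal, shared by both eyes. This is deliberately what the retinal age gap
  is: healthy subjects deviate from the age norm along the age manifold
  itself. A consequence is that per-coordinate embedding noise is small, so
  gradient directions are coherent across clients — which is also the regime
  in which single-local-step federated averaging can converge within a
  200-round budget, matching the observed behaviour of the real pipeline. An
  earlier variant that carried all noise in the isotropic term ε could not
  reproduce that behaviour at any overall amplitude: the per-coordinate noise
  that slows federated sign-votes and the vector-norm noise that destabilizes
  sequential (traveling-model) updates are then the same dial as the task
  difficulty.
* **One encoder, many cohorts.** The feature map (u, the eye offsets, and the
  reference standardization μ_ref, σ_ref) derives from `feature_seed`,
  identical across presets, while ages, center assignments, center offsets
  and noise derive from the cohort `seed`. A head trained on one cohort
  therefore transfers to another — the premise of external validation.
  Cohorts outside the reference age range probe extrapolation: the quadratic
  term makes a linear head degrade gracefully there, which is why the
  wide-age-range external preset shows a higher MAE than the internal one.

### Age distributions

Ages follow a truncated normal. The preset parameters describe the
*observed* distribution (UK-Biobank-like: mean 52.32, sd 7.98 on [40, 74];
BRSET-like: mean 46.97, sd 17.46 on [6, 91]); the sampler solves for the
parent normal whose truncation has exactly those moments (scipy root solve on
the truncated-normal moment equations) and then rejection-samples the parent.
Solving matters: naively truncating a normal with the observed parameters
would shift the realized mean by ≈ +0.96 years for the UK-Biobank-like
preset because its bounds are asymmetric.

The presets fold healthy and disease subjects into one cohort:
`ukb_like` has 8434 subjects of which 119 are disease-labelled,
`brset_like` 693 of which 214 are disease-labelled. Disease subjects never
train; they are the target group of the age-gap analysis.

### Calibration

The free noise scales were calibrated **once**, against the closed-form ridge
oracle (`ridge_oracle_mae`: centered normal equations with α = 10, held-out
evaluation): `latent_sd = 0.58` puts the oracle's held-out MAE at ≈ 3.37
years for 2400 training subjects, the difficulty regime of real fundus-based
age prediction; the nuisance scales (site/eye/noise) are small relative to
the signal amplitude. These values are frozen in the presets. Note the
latent scatter is partially *irreducible but also partially unidentifiable*:
given the noiseless projection s, the optimal readout shrinks toward the age
norm, so the oracle MAE is slightly below σ_age·latent_sd·√(2/π).

### What the generator does not emulate

No images and no real encoder: embeddings are a rank-one signal plus
Gaussian structure, not RETFound outputs — real embeddings have higher
effective rank, non-Gaussian tails, and age information spread over many
directions. No covariates other than age, center and disease status; no
center–age confounding (assignment is uniform); no sex effects; both eyes
are exchangeable up to a global L/R offset. Passing tests therefore
demonstrate protocol behaviour (convergence, communication, statistics),
not clinical performance on real data.

## 2. Encoder accounting

The frozen ViT-Large/16 encoder (224×224×3 input, patch 16, embed 1024,
depth 24, MLP ratio 4, class token, learned positional embeddings over 197
tokens) appears only through closed forms:

* **Parameters** — patch-embed conv + cls token + positional embeddings +
  per-block (2 layer-norms, QKV, output projection, 2-layer MLP) + final
  layer-norm = **303,301,632**, hence 303.3 MB at 8 bits/parameter and
  1213.2 MB at 32 bits (MB ≡ 10⁶ bytes — the only definition under which the
  8-bit size prints as 303.3).
* **Forward FLOPs** — under the default convention (2 FLOPs per
  multiply-accumulate over the patch-embedding convolution and all linear
  layers; bias adds, attention score/value matrix products, norms and
  activations excluded): **119,292,297,216 ≈ 119.3 GFLOPs** per image. The
  convention is an explicit `FlopConvention` value because published FLOP
  figures are meaningless without one; every excluded term can be switched on
  and is specified exactly (e.g. attention matmuls add depth·2·T²·D MACs).
* **Quantization** — emulated on feature vectors (the encoder's outputs),
  not on weights, since no weights exist here: per-vector affine mapping with
  scale = (max−min)/(2^bits−1) and zero-point = round(−min/scale). The
  reconstruction error is bounded by scale/2 and the map is idempotent.

Head accounting counts the bias addition (a practitioner reading "2.0 kFLOPs"
for a 1024-input head implies 2·1024 + 1 = 2049). A training update is
billed as forward + backward (2× forward) + Adam at 9 FLOPs/parameter:
2049 + 4098 + 9225 = 15,372 ≈ 15.3 kFLOPs for the linear head. MLP heads
(n layers ≡ n weight matrices, 100-unit ReLU hidden layers) follow the same
rules; note that some published MLP-head figures correspond to a 3× multiple
of this convention's forward count.

## 3. Training protocols

All strategies share: linear head initialized with zero weights and **bias at
the training-set mean age** (a one-scalar aggregate; without it, Adam's
sign-magnitude steps of at most lr per coordinate could not move the bias
across ~50 years within the round budget); Adam with lr 5·10⁻³, weight decay
10⁻⁴ (coupled, added to the gradient), β = (0.9, 0.999), ε = 10⁻⁸; L2 loss;
at most 200 rounds/cycles/epochs; early stopping when validation MAE fails
to improve for 10 consecutive rounds, returning the best-validation snapshot.

* **Centralized** — minibatch Adam (batch 64, reshuffled per epoch, one
  persistent optimizer state).
* **FL (FedAvg)** — per round, 32 clients sampled without replacement (fresh
  draw every round); each performs `local_epochs` (default 1) Adam steps on
  its two records as one batch, starting from a *fresh* optimizer state (only
  parameters travel); the returned parameter sets are averaged unweighted
  (exact FedAvg, since every client holds n = 2).
* **TM** — a new random permutation of all training clients each cycle; the
  head chains client-to-client, one local update each. By default the Adam
  state is also fresh at each visit; `tm_carry_adam=True` lets the moments
  travel with the model.

With one fresh-state Adam step, a local update is approximately a sign step
of magnitude lr per coordinate; FedAvg then behaves like majority-vote
sign-SGD, and TM like a sequential sign-SGD random walk with drift. This
explains the observed regime: FL needs on the order of a hundred rounds
(≈ 25–35 updates per client at n = 150) while TM converges within one or two
cycles (1–3 updates per client) — and it is why the update-count comparison
between the two is meaningful at all: both use the identical local unit.

### Cost ledger

Each client update is billed at one train-step unit (15,372 FLOPs for the
linear head); centralized updates are itemized per record (3× forward per
record + one 9-FLOP/parameter Adam update per minibatch). Training parameter
transfers count 2 per participating client per round/visit (send + return)
at 4 bytes/parameter — heads travel at 32-bit precision; only the encoder is
8-bit. Model copies broadcast for validation are counted separately
(`validation_broadcasts`) and excluded from the headline byte totals, so
either reading of "number of times parameters were shared" can be
reconstructed. Per-client FLOP averages that include validation-time
inference are intentionally not reported.

## 4. Statistics

* **RAG** — per-image gap = prediction − age; per-subject RAG = mean of the
  two eye gaps. Subjects, not images, are the sampling unit everywhere
  downstream (two eyes of one subject are not independent).
* **Domain adaptation** — histogram-ratio importance weights on a shared
  5-year bin grid: weight of a target subject ∝ p_train(bin)/p_target(bin),
  zero where the training set has no support, renormalized to mean 1. This
  is the simplest estimator that aligns the target group's age distribution
  with the training distribution before group means are compared; it also
  removes most of the extrapolation bias a linear head incurs outside the
  trained age range.
* **Group test** — one-tailed weighted bootstrap, H1: mean RAG(disease) >
  mean RAG(healthy). B resamples (with replacement, selection probability ∝
  weights) per group; p = (1 + #{replicate diffs ≤ 0}) / (B + 1). The
  add-one estimator avoids p = 0; the direction is fixed a priori by the
  accelerated-aging hypothesis. The test's type-I error at the nominal 5%
  level is verified by simulation in the acceptance suite.
* **Strategy comparison** — per-strategy mean ± sd over Monte-Carlo
  iterations, pairwise two-sided pooled-variance t-tests and one-way ANOVA.
  The pooled-variance (independent-samples) form is used even though
  strategies share splits within an iteration: it is the standard analysis
  for Monte-Carlo MAE tables, and a paired test on shared splits would flag
  arbitrarily small but stable protocol differences (on this simulator,
  centralized training beats TM by a consistent ~0.05–0.09 years; a paired
  test detects this at n = 10, an independent test correctly treats it as
  small relative to the Monte-Carlo spread). Bonferroni corrections: 0.05/15
  for the 5-sizes × 3-models MAE grid, 0.05/6 for the 3-models × 2-datasets
  RAG tests.

## 5. Determinism and numerics

One integer seed reproduces everything: stage seeds derive via
`SeedSequence([seed, stage_code, *context])` (cohort = 0, split = 1,
train = 2, stats = 3; context = iteration/size/strategy indices), reduced
mod 2³¹. Identical (spec, seed) yields byte-identical cohort CSVs; identical
configs yield byte-identical experiment reports. Ties and degenerate inputs:
zero age-sd collapses to the mean (if inside the bounds); constant feature
vectors pass through quantization unchanged; identical MAE vectors define
t = 0, p = 1 and F = 0; empty-support weight grids raise.

Validation sampling order is fixed (validation drawn first, then training
from the remainder) — the order does not bias marginal inclusion but pins
determinism. The validation set is resampled per Monte-Carlo iteration.

## 6. Problem sizes used by the test suite

The acceptance suite runs the full default experiment — the 8434-subject
UK-Biobank-like cohort with 8-bit quantized features, 10 Monte-Carlo
iterations × training sizes {150, 300, 600, 1200, 2400} × 3 strategies —
plus 10 paired centralized runs on raw vs quantized features for the
quantization and age-gap checks, and 500 simulated null datasets (B = 1000)
for the bootstrap calibration. The whole suite completes in a few minutes on
a single CPU; the analytic accounting checks are instantaneous.

## 7. Known limitations

* The rank-one-signal Gaussian embedding model is a stand-in; none of its
  parameters are claims about RETFound embeddings.
* The head-level FLOP ledger is a convention, not a hardware measurement.
* The traveling model's small systematic MAE penalty (end-of-cycle iterate
  noise) is a real property of sequential single-step updating in this
  simulator; with richer local data per client it may vanish or grow.
* Multi-subject clients, stragglers, asynchronous rounds, privacy accounting
  and secure aggregation are out of scope.
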