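# Methods

## Problem setting

The framework simulates a privacy-preserving collaboration: several
clinics each hold a slice of a multimodal stroke cohort — static
clinical/demographic attributes plus one grayscale head image per
patient — and jointly train a single risk classifier without exchanging
raw records. Everything runs on one machine; "clients" are partitions
of one dataset, which isolates the federated optimization behaviour
from networking concerns.

## Synthetic data model

**Tabular.** Records follow the 12-attribute stroke-EHR schema.
Class-conditional distributions are deliberately simple and fully
controllable: continuous fields are clipped Gaussians with
class-shifted means (age 45 vs 65 years, SD 12; mean glucose 95 vs
135 mg/dL, SD 25; BMI 27 vs 30 kg/m², SD 5), binary comorbidities are
Bernoulli with class-dependent rates, and categorical fields are
multinomial draws matching the rough frequencies of public stroke EHR
data. The shifts point the same way as the associations in real
cohorts (stroke patients older, hyperglycemic, more hypertensive) and
make the classes learnably — but not trivially — separable: the Bayes
accuracy from the static features alone is around 0.88, so a model
must exploit the imaging modality to do better. Missingness is
injected completely at random (MCAR) into `bmi` and
`avg_glucose_level` only, the two fields that are actually incomplete
in public stroke EHR data; MCAR is the simplest mechanism under which
mean/median imputation is well behaved.

**Images.** Every image is Gaussian background noise
(mean 0.30, SD 0.08, clipped to [0, 1]). Stroke-class images carry one
bright square anomaly — side 25 % of the image, added intensity
`separation` (default 0.5) — at a uniformly random interior position.
The default size is 32×32 so that backpropagation through 32 GRU
timesteps stays fast; 128×128 generation is supported. The default
class mix 1,551 : 950 (total 2,501) mirrors a public brain-CT
collection. With `separation = 0` the classes are distributionally
identical, which the test suite uses as a negative control.

**What the generator does not emulate:** anatomy, acquisition physics,
inter-feature correlations beyond the class shifts, informative
missingness, label noise, and inter-client distribution shift (the
partitions are IID by construction). Passing tests therefore
demonstrate the correctness and convergence of the *pipeline*, not
clinical-grade performance on real data.

**Pairing.** The two public datasets this setting emulates have no
documented patient correspondence; per-patient pairing is a modeling
assumption. The generator sidesteps the issue by emitting matching
ids with consistent labels; the join is still a real inner join that
rejects and counts label-inconsistent pairs, and loading real data
requires an explicit id mapping.

## Preprocessing

All transforms are fit on the training split only and never mutate
their fitted state at apply time; fitted parameters serialize to JSON.

* **Imputation** — mean (default) or median for continuous fields,
  mode for categoricals. Mean is the default because the synthetic
  continuous fields are near-symmetric; median is one config key away.
* **Min-max scaling** — `(C − C_min)/(C_max − C_min)` per feature. A
  constant feature maps to 0. Out-of-range apply-time values are *not*
  clipped: the map stays affine, and downstream layers handle mild
  excursions; the contract is documented rather than silently changed.
* **Encoding** — one-hot with a schema-fixed column order (the
  categories are unordered, so ordinal codes would inject a fake
  metric); unseen categories either raise (default) or map to all
  zeros.
* **Image resize** — bilinear (PIL), then linear range-normalization to
  [0, 1] over the dataset-wide source range; a constant dataset maps to
  zeros.
* **SMOTE** — synthetic minority points `x_i + u·(x_nn − x_i)` with
  `u ~ U(0,1)` and `x_nn` among the k = 5 Euclidean nearest minority
  neighbors, generated until minority/majority reaches the target
  ratio (default 1.0). It runs on the *client's local training split
  only*, after the train/validation split, on the concatenated
  [static ‖ flattened-image] vector so a synthetic sample remains a
  coherent multimodal pair. Ordering SMOTE after the split prevents
  synthetic points interpolated from validation data from leaking into
  training. If a local minority is too small to define k neighbors, k
  is reduced (skipped below 2 samples).

## Network and training

Defaults: MLP `input → 32 → 16` with ReLU, GRU hidden size 32, fusion
`48 → 1`. All parameters are Glorot-uniform initialized from a seeded
generator; biases start at zero.

The GRU update `h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ h̃_t` puts the
update gate on the *candidate*; several textbooks write the mirrored
orientation. The choice only relabels `z ↔ 1 − z`, but forward and
backward passes here implement this orientation consistently, and the
tests pin it (zero parameters give `h_t = h_prev / 2`).

Images enter the GRU as a row-major scan (row t = timestep t) — the
minimal interpretation of sequential processing of a single static
image; a column scan is available (`model.transpose_scan`).

Loss is mean binary cross-entropy with probabilities clamped at
ε = 1e−12, which avoids −inf on saturated outputs without measurable
bias; the logit gradient uses the exact identity `∂L/∂logit = p − y`.
Gradients are hand-derived and batch-averaged; backpropagation through
time accumulates the update-, reset- and candidate-gate contributions
at every timestep. The non-negotiable correctness gate is agreement
with central finite differences (step 1e−5) for *every* parameter on a
small instance; the suite enforces ≤ 1e−5 relative error and typically
observes ~1e−7.

Optimizers: SGD and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8). Defaults
for local training are Adam, lr 0.001, batch 32, 10 epochs per round.
No learning-rate decay is applied. At these settings a 200-sample
training split needs roughly 35 epochs to exceed 0.9 training
accuracy — convergence speed, not a gradient defect; the federated
defaults (more data, repeated rounds) reach ≥ 0.99 validation accuracy
within 5 rounds.

## Federation

Per round: the server broadcasts `θ_global`; each client copies it,
trains locally with its own derived seed, and returns a `ClientUpdate`
(parameters + sample count + metrics) — never data; the server
aggregates with **uniform FedAvg**, `θ_global = (1/K) Σ θ_k`. A
sample-weighted variant (`n_k/Σn` weights) is available; with the
equal splits used here the two coincide. Adam moments are reset at
every broadcast: only parameters are aggregated, so client moments
have no meaningful average.

Partitioning is stratified by default (per-client class fractions
preserved within rounding; sizes differ by ≤ 1); purely random equal
splits are the alternative, since either reading of "equal parts" is
defensible. The global validation split (20 %, stratified) is held by
the server and never trained on; each client additionally holds out
20 % of its own slice for its local curves. Early stopping: maximum 20
rounds, patience 3, minimum improvement 1e−4 on global validation
loss.

All randomness derives from one experiment seed through a
`SeedSequence`-based labelled-child scheme (`derive_seed(seed, "local",
round, client)`), making every stage independently reproducible and
the whole run bit-identical on re-execution. A one-client federation
is bit-identical to a centralized training loop written as a separate
code path — the structural sanity check that FedAvg with K = 1 is the
identity.

## Evaluation

Confusion counts at threshold 0.5 (prediction = probability ≥
threshold; the threshold is configurable, 0.5 being the conventional
default). Accuracy, precision, recall; F1 is the harmonic mean of
precision and recall — the standard definition, used even though the
setting this emulates is sometimes described loosely as a mean of
"accuracy and recall". ROC sweeps the unique predicted probabilities
with ties grouped into single steps; AUC is trapezoidal and equals the
Mann–Whitney U statistic normalized by `n₁·n₀`, which the tests verify,
along with 1e−12 agreement with scikit-learn on random instances.

## Problem sizes

Unit tests run on 8–16 pixel images and ≤ 200 samples; the learning
benchmark uses the default conditions (600 samples, 32×32 images,
3 clients, 5 rounds, 3 seeds), chosen as the smallest configuration at
which the federated pipeline reliably demonstrates ≥ 0.9 global
validation accuracy. The acceptance script runs the same default
federation once plus the arithmetic identities; end to end it takes
about a minute on one CPU.

## Known limitations

* IID partitions only; no client drop-out, asynchrony, transport,
  encryption, or differential privacy — the scope is the optimization
  loop, not deployment.
* The image generator produces texture-free anomalies; models that
  exploit CT texture cannot be studied with it.
* SMOTE on concatenated multimodal vectors treats pixel and clinical
  dimensions as one Euclidean space after scaling; with very
  high-dimensional images the interpolation is dominated by pixels.
* Pure-numpy BPTT is single-threaded; 128×128 images are supported but
  slow for repeated federated rounds.
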