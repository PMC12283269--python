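# Methods

`pascl` reimplements, as a tested pipeline, a supervised-contrastive approach
to classifying prostate tissue from multi-wavelength photoacoustic (PA) power
spectra. Because the clinical recordings behind the original study are not
publicly deposited, the package ships a synthetic cohort generator whose
draws carry the statistical structure the analysis assumes; every other stage
(preprocessing, models, training, evaluation, robustness, baselines) operates
identically on synthetic or real 77x90 spectrum matrices.

## Data model

A detection point is a 77x90 matrix of calibrated log-power values: 77
optical excitation wavelengths (690-950 nm and 1200-1690 nm, step 10 nm) by
90 acoustic frequency bins (1.0-9.9 MHz, step 0.1 MHz), with a binary label
(0 normal, 1 tumor), a patient id and an acquisition-system id. Patients
contribute between 3 and 6 points and may be all-normal or mixed.

## Synthetic cohort generator (`pascl.synth`)

Per wavelength `lam` and frequency `f` (MHz) the log-power spectrum of one
point is an exact line plus noise:

    S(lam, f) = a(lam) * f + b(lam) + u_p(lam) + g_s(lam, f) + eps

* `a`, `b`: per-point slope (dB/MHz) and intercept (dB) drawn around class
  means. Tumor tissue is structurally more heterogeneous, which shows up
  twice: its slope mean is higher (less negative) and its point-to-point
  spread is wider. Defaults: normal slope -2.0 +- 0.30, intercept
  30.0 +- 0.8; tumor slope -1.94 +- 0.45, intercept 30.1 +- 1.1, plus
  band-localised offsets (+0.10 dB/MHz, +0.8 dB) in Gaussian neighbourhoods
  (sd 25 nm) of the characteristic wavelengths 700 / 1210 / 1370 nm, where
  hemoglobin, lipid and collagen absorption differ between tissue classes.
  The second-moment difference matters for the method ranking: it is
  invisible to a pooled-covariance linear discriminant but usable by QDA
  and by nonlinear feature learners, which is the ordering the analysis
  studies. An optional per-point band-expression mechanism
  (``band_express_prob``) can restrict each tumor point to a random subset
  of the characteristic bands; the default expresses all bands.
* `u_p`: a smooth per-patient random curve over wavelength (pointwise sd
  1.5 dB), shared by all points of a patient — the unit of heterogeneity, and
  the reason splits are patient-grouped.
* `g_s`: a smooth per-system calibration gain, linear in `f` (offset up to
  3 dB, tilt up to 0.06 dB/MHz) so the generating line stays exact and the
  latent slope/intercept of every sample remain available for recovery tests.
  System 0 is the reference (0 dB).
* `eps`: i.i.d. Gaussian, sd 0.8 dB on the reference system. The second
  system's cruder pulse-energy calibration leaves more residual
  variability, modelled as a higher noise level (x1.8 by default,
  ``system_noise_scale``). A pure gain offset alone would be absorbed by
  per-system retraining and input standardisation and would produce no real
  cross-system difficulty gap.

The class separation was calibrated once so that a single-feature threshold
(slope or median at one characteristic wavelength) sits near 0.6 held-out
accuracy while multi-wavelength learners do substantially better — the
qualitative ordering the analysis is about. Under that calibration and the
fixed 20-epoch budget the CNN reaches ~0.7 median held-out accuracy (close
to the clinical CNN's reported accuracy), with the combined-loss model
above it. Defaults are the study conditions; tests do not move them.

What the generator does *not* emulate: physical acoustics (no optical
absorption model, no transducer impulse response beyond an abstract gain),
within-patient spatial correlation between points, label noise from
histopathology, or non-linear (in `f`) spectral shapes. Passing tests
therefore show that the pipeline recovers the structure this model encodes,
not that it would reach any particular accuracy on clinical data.

`synthesize_waveform` inverts the preprocessing: white Gaussian noise is
spectrally shaped by inverse FFT to a prescribed band spectrum, giving raw
A-lines (250 MHz sampling) whose Welch PSD matches the target up to
estimator variance. A finite record carries roughly `2 n / nfft` degrees of
freedom per 0.1 MHz bin, i.e. an sd of about `4.34 / sqrt(dof)` dB, so
round-trip checks use 400 k-sample records where the maximum per-bin error
over the 90 bins stays below 1.5 dB with margin.

## Preprocessing (`pascl.preprocess`)

Welch PSD with a 2500-sample Hamming window, 90% overlap, `nfft = 2500` at
`fs = 250 MHz` — exactly 0.1 MHz resolution; one-sided, density scaling.
Band selection takes the 90 bins at 1.0, 1.1, ..., 9.9 MHz (the stored
matrix has 90 columns, which fixes the half-open reading of the "1-10 MHz"
band; the start bin is configurable). Calibration divides by the transducer
frequency response (90-vector) and per-wavelength pulse energy (77-vector)
in linear power before `10*log10`; defaults are all-ones, with synthetic
system gains playing their role.

Spectral features are ordinary least squares of the dB-scale band vector on
frequency in MHz: slope, intercept, and "median" — the fitted value at the
median bin frequency, 5.45 MHz. Fits are performed in the dB domain (the
norm in quantitative ultrasound/PA spectroscopy; it makes slope and
intercept gain-invariant up to an additive shift).

## Models and losses (`pascl.models`, `pascl.nn`)

All three classifiers share one small convolutional encoder:

    77x90 -> conv(64 kernels) -> 64x77x90 -> maxpool 2x2 -> 64x38x45
          -> conv(4 kernels)  -> 4x38x45  -> maxpool 3x3 -> 4x12x15
          -> flatten (720) -> fc 256 (h_i)

with a 2-unit prediction head on `h`, and, for the SC model, a 4-unit
projection head `z = g(h)`. Kernel sizes are not part of the printed layer
plan; the default is 3x3 with same padding (which preserves the 77x90 plane,
as the plan requires) and is configurable. Pooling floors the spatial
dimensions (77 -> 38, 90 -> 45; 38 -> 12, 45 -> 15), reproducing the printed
shapes exactly. Activations are rectifiers after each convolution and the
256-unit layer; no normalisation or dropout layers are used (none are part
of the plan). With 3x3 kernels the cnn/scl_adjust network has 188,038
trainable parameters (640 + 2,308 + 184,576 + 514).

The supervised contrastive loss over a batch of embeddings z_i with labels
y_i and temperature t = 0.5:

    SCL = - sum_i 1/(M_yi - 1) sum_{j != i, y_j = y_i}
            ln[ exp(s_ij/t) / (exp(s_ij/t) + sum_{k: y_k != y_i} exp(s_ik/t)) ]

with s_ij the cosine similarity and M_yi the batch count of label y_i. Two
deliberate reading choices: (1) the denominator contains only the anchor-
positive term plus the different-label terms — it excludes other positives,
unlike the canonical supervised-contrastive formulation; the canonical
variant is available via `variant="canonical"`. (2) Anchors with no
same-label partner are skipped (the 1/(M_yi - 1) weight is otherwise
singular); the class-balanced batch sampler prevents such anchors by
construction. Zero embedding rows (possible after a ReLU) get similarity 0
and subgradient 0. The loss is invariant to positive rescaling of any
embedding and to batch permutation, and is verified against a brute-force
triple-loop oracle and finite-difference gradients.

As written the loss sums over anchors, which makes its magnitude — and the
SCL:CE balance inside the combined loss — grow with batch size; the
reference implementation of this loss family averages over the batch
instead. ``scl_loss`` exposes both (``reduction="sum"`` is the default and
matches the hand-derived values; training uses ``"anchor_mean"`` so the
0.7/0.3 weighting means the same thing at every batch size).

Model variants:

* **cnn** — encoder + head, cross-entropy loss;
* **sc** — two stages: encoder + projector trained with SCL, then the
  projector is removed and the 2-unit head is trained with cross-entropy on
  the frozen encoder (a linear probe; `freeze_encoder=False` fine-tunes);
* **scl_adjust** — identical architecture to cnn, loss
  `SCL * ratio + CE * (1 - ratio)` with ratio 0.7; the SCL term is applied
  to the penultimate 256-d features by default (`scl_target="logits"`
  switches to the 2-d logits; which layer feeds the loss is an open choice).

The networks are implemented directly in numpy (explicit layer
forward/backward passes, single precision). Convolutions run either as
im2col + BLAS matmul or as FFT cross-correlation — the two paths agree to
float rounding and the faster one is chosen by channel count. Weights are
initialised uniformly with fan-in scaling from one seeded generator.

## Training (`pascl.training`)

Splits are patient-grouped: floor(0.75 n) patients form the train+validation
pool, ~20% of those (rounded; 2 of 9 at n = 12) are validation patients, the
rest of the cohort is test — 7/2/3 patients at n = 12. A redraw loop
(deterministic sub-seeds) guarantees both classes appear in every part when
labels allow it.

Optimisation is SGD with momentum for 20 epochs, seed 42, with the searched
hyperparameters as defaults: cnn lr 0.001 / momentum 0.7; sc and scl_adjust
lr 0.01 / momentum 0.95, ratio 0.7. (A ratio of 0.3 is also reported
elsewhere in the source study's discussion; 0.7 follows its hyperparameter
table, and both are exposed.) Batch size was searched but never printed;
per-variant defaults are cnn 4, sc 8, scl_adjust 8 — small batches give the
20-epoch budget enough update steps at these cohort sizes. Gradients are
clipped to a global L2 norm of 5 (the high-momentum contrastive phases
occasionally spike). Inputs are standardised per (wavelength, bin) element
with training-split statistics (configurable to a single global mean/sd).
Contrastive batches are built so no batch holds a singleton class unless
the class counts force it, and a trailing batch of one sample is folded
into its predecessor; the balanced sampler engages only when a contrastive
term is active, so ratio 0 reproduces the plain CNN run exactly.

`random_search` samples n_rounds configurations (lr log-uniform 1e-4..1e-1,
momentum 0.5..0.99, batch size {8, 16, 32}, ratio uniform 0.1..0.9,
projector dim {2, 4, 8, 16}), trains each, and ranks by the validation
five-metric score, ties to the earlier round.

## Evaluation (`pascl.evaluation`)

Accuracy, precision, recall, specificity from the confusion counts; AUC as
the pairwise rank statistic (ties credited 0.5, so constant scores give
0.5; a strict mode counts only strict inequalities); "score" is the mean of
the five. Zero-denominator metrics are 0 with a `degenerate` flag rather
than an error — an all-negative classifier then gets precision = recall = 0,
which is how such rows are conventionally tabulated. The subsampling
protocol evaluates 10 stratified random subsets at each fraction 10%..100%
and averages; model comparison uses the two-sided Welch t-test (a paired
mode exists for shared subsample draws). The silhouette of the 2-d
final-layer outputs uses Euclidean distances, with singleton clusters and
coincident points contributing 0. UMAP visualisation is a thin call into
umap-learn.

## Robustness and transfer (`pascl.robustness`)

Noise is added only at evaluation time, to the spectrum matrices the models
consume. Uniform noise draws each element from U(-rA, +rA) with A the
per-sample peak magnitude (per-element and global variants are available);
Gaussian noise is N(0, sigma^2) with sigma in dB. The benchmark keeps only
the samples the model classifies correctly clean, perturbs each 10 times,
and reports the fraction still correct plus the silhouette of the noisy
final-layer outputs — accuracy at zero noise is 1 by construction. Default
grids (uniform r in {0.02, 0.05, 0.1, 0.2}; Gaussian sigma in {0.5, 1, 2, 4} dB)
span gentle to destructive regimes on the default cohorts.

"Transfer" follows the study's protocol: the same procedure is trained
independently per acquisition system and the decline is
100 (score_1 - score_2) / score_1. A weight-transfer mode is not part of the
protocol and is out of scope here.

## Baselines (`pascl.baselines`)

Single-feature threshold classifiers use the Youden-optimal cut on the
training data with learned orientation (the strongest fair reading of an
unspecified thresholding rule). LDA runs on the 154-column slope+median
table with lsqr + automatic shrinkage; QDA, whose per-class covariances
need more samples than dimensions, first projects onto at most 20 principal
components and then applies regularised QDA (reg_param 0.5). Feature
screening scores every (wavelength, bin) scalar by the validation accuracy
of a closed-form one-dimensional Gaussian LDA rule and keeps the top k
(default 20).

## Study summary definitions

The multi-seed study (`pipeline.run_study`) reduces each pipeline run to the
comparisons the analysis is about: combined-loss vs CNN clean score;
accuracy under the strongest noise level of each family; unfiltered noisy
silhouettes of the three models; the deep / discriminant / threshold family
ordering; and the sign of the transfer decline. Family representatives are
selected by validation score, never by test performance — picking the best
of six thresholds on a ~15-sample test set is a multiple-comparisons
artifact, not a method. All orderings are reported as win counts or medians
over cohort seeds.

## Problem sizes and numerical choices

The default experiment uses 12 + 10 patients with 3-6 points each (~100
samples), 20 epochs, 10 noise replicates, and 10x10 subsample evaluations;
the acceptance study repeats the full pipeline over several cohort seeds
(seven in the test suite, five in the acceptance script).
These sizes keep a full run in the minutes range on one CPU while leaving
every qualitative comparison at the cohort scale the analysis targets.
Determinism: all randomness flows from explicit integer seeds through
numpy generators; two runs of the pipeline with the same seed produce
byte-identical reports.

## Known limitations

* The synthetic generator is linear in frequency by construction; slope and
  median are sufficient statistics for its class signal, so it cannot probe
  features beyond first-order spectral fits (by design).
* Test sets at clinical cohort sizes hold ~10-15 points from 3 patients;
  single-seed metric values are noisy, which is why qualitative claims are
  asserted as majorities/medians over seeds rather than per-seed.
* The SC model's two-stage training is sensitive to the representation
  phase's outcome at these sample sizes (the source study reports the same
  fragility), so only its silhouette ordering is asserted, not its score.
* Absolute clinical metric values are not reproducible from the synthetic
  conditions and are not asserted anywhere.
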