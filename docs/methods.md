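# Methods

## The classification problem

Samples are minced-meat patties of five categories: pure mutton, pure pork,
pure duck, mutton adulterated with pork, and mutton adulterated with duck.
Adulteration levels of 10–50 % (w/w) in 10 % steps are collapsed into the
two adulterated classes — the task is categorical authentication, not
quantification of the adulteration level. Each physical sample yields 16
point reflectance spectra: four points along the conveyor run direction,
repeated for four orientations of the patty at 45° intervals.

## Synthetic data model

No public instrument dataset exists for this design, so the generator
produces reflectance tables with its statistical structure.

**Endmembers.** Each species' pure reflectance curve is a smooth baseline
minus Gaussian absorption bands:

    R_s(λ) = clip( L_s − D_s · σ((λ − 1700)/k_s) − Σ_b d_{s,b} · exp(−(λ−c_b)²/2w_b²) )

with band centres c_b at 1260, 1520, 1650 and 1840 nm (fat C–H overtones
and the protein N–H band) and a logistic drop beyond ~1700 nm representing
the broad O–H/N–H/C–H combination bands. Constants are design choices
constrained by the qualitative physics: pork has the highest mean
reflectance and the deepest fat bands; duck has the deepest protein band
and the shallowest long-wave drop; all values stay strictly inside (0, 1);
every band centre is a local reflectance minimum within ±2 channels.
Species also differ in the steepness k_s of the long-wave drop — this
matters because per-spectrum min–max normalisation removes level and scale,
so only such shape differences carry class information downstream.

**Mixing.** Adulterated samples are convex combinations in reflectance,
R = (1−p)·R_mutton + p·R_adulterant. Linear reflectance mixing is the
simplest model consistent with the observation that reflectance varies
monotonically with the adulteration proportion; absorbance-domain mixing
(linear in −log₁₀R) is available behind the `domain="absorbance"` flag.

**Variability and noise.** Two levels:

* *Between-sample (biological) variability*: each physical sample rebuilds
  its endmember curves with every band depth scaled by
  N(1, `between_sample_sd`). This is what makes replicate patties of one
  recipe differ, and it is the principal confound for detecting 10 %
  admixtures.
* *Acquisition noise*: each of the 16 point spectra is a·x + b + ε with
  a ~ N(1, `scatter_slope_sd`) (multiplicative scatter), b ~ N(0,
  `scatter_offset_sd`) (offset) and channelwise ε ~ N(0, `additive_sd`),
  clipped to [0, 1].

**Preset calibration.** The instrument's noise levels are not documented,
so the presets were calibrated against pipeline behaviour: the "low" preset
(0.005, 0.002, 0.001, 0.005) is set so the full CNN-ELM pipeline reaches
high but not saturated validation accuracy (~0.99 at desk scale), i.e. the
classes are cleanly learnable but a 10 % duck admixture is still the
hardest boundary; the "paper-like" preset (0.02, 0.005, 0.005, 0.05) adds
enough variability that accuracy drops visibly below the ceiling. Two
findings from this calibration shaped the constants: per-spectrum min–max
normalisation amplifies additive channel noise by roughly the inverse of
the raw spectral range (~3×), and scatter slope/offset noise is removed
almost exactly by the normalisation, so `additive_sd` and
`between_sample_sd` are the two parameters that actually control task
difficulty.

What the generator does **not** emulate: wavelength-correlated instrument
noise, temperature drift, water-activity effects, surface-texture scatter
differences between species, and any radiative-transfer (Kubelka–Munk)
physics. Passing tests on synthetic data therefore demonstrate that the
pipeline's machinery is correct and that the method can exploit shape
differences of the documented kind — not that these accuracies transfer to
any particular instrument.

## Preprocessing

Order of operations: Savitzky–Golay smoothing (window 5, polynomial order
2 — the classic (−3, 12, 17, 12, −3)/35 interior kernel; edges by
polynomial extrapolation of the fitted edge windows) on raw point spectra →
crop to 1038–2475 nm → averaging (the four points of each direction; for
the four-direction scheme also the four direction means) → per-spectrum
min–max normalisation → outer product S = x xᵀ. Averaging acts on raw
reflectance before normalisation, so the direction mean is the physical
mean spectrum. Per-spectrum (rather than global) normalisation was chosen
because it is the convention that makes each rank-1 matrix span the full
[0, 1] range; a global variant would preserve between-spectrum level
differences but make matrices depend on the dataset they were processed
with. The order-2 polynomial is the standard chemometric default for a
five-point filter.

## SPXY partitioning

The combined distance is the standard additive normalised form
d = d_x/max d_x + d_y/max d_y with Euclidean d_x on the four-direction mean
spectra and Euclidean d_y on one-hot class encodings (0 within a class, √2
across classes) — one-hot avoids imposing an arbitrary ordering on
categorical classes. Selection is Kennard–Stone greedy: seed with the
maximal-distance pair, then repeatedly add the sample whose minimum
distance to the selected set is largest; every tie breaks to the lowest
sample index, making the split fully deterministic. The split is computed
at sample level and propagated to per-direction spectra, so no sample
contributes spectra to both sides (audited at every fit). The calibration
fraction defaults to 75 % of samples and is a user parameter.

## CNN feature extractor

Input: C×C×1 rank-1 matrices (C = channels after cropping; 230 for the
full grid, tests and the scaled experiment use 64). Architecture: three
convolution layers with one odd kernel size (3, 5 or 7), same padding,
stride 1, ReLU, each followed by 2×2 max pooling; dropout 0.3 after the
first two pooling stages; flatten; a 128-unit fully connected layer
(ReLU); a 5-way output layer. Training: Adam, learning rate 0.001, batch
size 32, mean squared error between the raw 5-way outputs and one-hot
targets; 500 epochs by default (50 in the scaled experiment). Softmax is
applied only at prediction time, which keeps the loss literally MSE while
still yielding probability scores. Filter counts 16/32/64 and the 128-unit
hidden layer are design choices (the smallest common pyramid that leaves a
rich flattened feature); both are configurable.

The engine is pure numpy: convolutions are lowered to BLAS matrix products
via im2col, pooling backpropagates through stored argmax indices (first
occurrence on ties), dropout uses inverted scaling, and all randomness
(initialisation, dropout masks, batch shuffling) derives from one seed, so
training is bit-reproducible. He-normal initialisation is used for the
ReLU stack. External heads tap the post-ReLU activations of the 128-unit
hidden layer with dropout inactive — the most common convention for
CNN-hybrid classifiers.

## Classifier heads

**Softmax** — argmax of the softmax over the CNN's 5 outputs (ties to the
lowest class index).

**ELM** — input weights and offsets ~ Uniform(−1, 1), sigmoid hidden
layer, output weights β = H⁺T by SVD pseudo-inverse (tolerance relative to
the largest singular value; an optional ridge term is off by default). The
hidden size is searched over 10–200 neurons in steps of 5 on a grouped
25 % holdout of the calibration samples; when the search is disabled the
default is 175. β is an exact least-squares minimiser, which tests verify
against the normal equations and random perturbations.

**SVM** — RBF kernel via scikit-learn's SVC; (log₂γ, log₂C) tuned by a
real-coded genetic algorithm (population 20, generations 30, tournament
selection of size 3, uniform crossover at rate 0.9, Gaussian mutation with
sd 10 % of each range at rate 0.2, elitism), searching γ ∈ 2^[−10, 4] and
C ∈ 2^[−5, 15]; fitness is stratified 5-fold cross-validated accuracy
(plain k-fold with a warning if the rarest class has fewer members than
folds). GA settings are standard grid-free chemometric practice; the
elitist incumbent guarantees the returned pair is the best ever evaluated.

## Evaluation protocol

Models trained on either averaging scheme are always scored on both
validation sets built from the same held-out samples: set 1 holds their
four-direction means (one spectrum per sample), set 2 their per-direction
means (four per sample). Cross-validation is stratified 5-fold grouped by
sample, with an option to reduce CNN epochs inside folds for desk-scale
runtimes. Head prediction wall-time is reported separately from CNN
feature extraction and is never a pass/fail quantity (hardware-dependent);
only the ELM-faster-than-SVM ordering is asserted.

## Problem sizes

The test suite and the acceptance script run two configurations chosen as
the package's own desk-scale defaults: the full 455-sample design at 230
channels for everything that only needs counts and splits (seconds), and a
scaled experiment for everything that needs CNN training — 64-channel
grid, 12 replicates per configuration (156 samples), kernel 7×7, 50
epochs, four-direction scheme (~3–4 minutes on one CPU). The scaled
experiment reaches validation accuracies of 0.99–1.00 at the "low" noise
preset.

## Known limitations

* The synthetic endmembers are parametric stand-ins; absolute accuracies
  on synthetic data say nothing quantitative about any real instrument.
* MSE-on-one-hot is a weaker training signal than cross-entropy; it is
  retained deliberately as part of the modelled design.
* The SPXY implementation is O(N²) in memory (distance matrix); fine for
  hundreds of samples, not for tens of thousands.
* Grouped stratified cross-validation can emit missing-class warnings on
  very small calibration sets; folds are still leakage-free.
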