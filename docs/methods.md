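# Methods

This note records the models, conventions and numerical choices behind
`dms-eeg`, and what the synthetic experiments do and do not demonstrate.

## Synthetic trial model

Each trial is 9 s at fs = 128 Hz on channels (C3, Cz, C4), emulating a cued
left/right motor-imagery paradigm with the cue at t = 3 s. Per channel:

    x(t) = σ·η(t) + a_mu·e(t)·sin(2π f_mu t + φ₁) + a_beta·e(t)·sin(2π f_beta t + φ₂)

* **Background** η(t): Gaussian noise shaped to a 1/f^α spectrum
  (α = 1 by default), band-limited to 0.5–30 Hz to mirror the acquisition
  filter of the emulated recordings, normalised to unit standard deviation
  and scaled by `noise_sigma` (default 1.0, in the same arbitrary µV-like
  units as the oscillation amplitudes).
* **Oscillations**: mu at 10 Hz (amplitude 1.0) and beta at 20 Hz
  (amplitude 0.5), phases drawn uniformly per trial per channel so no
  phase-locked shortcut exists.
* **ERD**: the envelope e(t) is 1 before imagery onset and (1 − erd_depth)
  from t = cue + onset_delay (3.5 s) onward, *only* on the channel
  contralateral to the imagined hand (left → C4, right → C3). The step
  change is deliberate; a smooth ramp is out of scope. Amplitude
  attenuation by (1 − d) appears in band power as (1 − d)², which the
  `bandpower_contrast` periodogram oracle verifies directly (d = 0.8 →
  power ratio 0.04).
* **Cz** is generated identically for both classes — a pure distractor.
  The random draws are side-independent, so at erd_depth = 0 the two
  class-conditional processes are bit-identical, which the symmetry tests
  exploit.

Default erd_depth is 0.7. No published quantitative ERD magnitude exists
for the emulated subject, so this is a tool parameter chosen to represent a
strong but noise-embedded effect: at σ = 1 the single-trial spectrogram
still shows visible trial-to-trial variability, yet the contrast is
decodable. What passing the end-to-end tests shows is that the pipeline
*recovers a lateralized band-power signal when one exists and finds nothing
when none exists*; it does not show competition-grade accuracy on real
recordings, which contain artifacts, non-stationarity and subject
idiosyncrasies this generator deliberately omits (no EOG/EMG, no volume
conduction, no ERS).

## Feature encoding

The STFT uses frame m = signal[mR : mR+N]·w, zero-padded to `n_fft`, with
no centering or edge padding — a signal shorter than one window is an
error, and the frame count is 1 + ⌊(L − N)/R⌋. Defaults N = 64 (0.5 s),
R = 16, n_fft = 64: 2 Hz bins that separate mu (8–12 Hz) from beta
(18–25 Hz), and 21 frames across a 3 s segment. Windows are the symmetric
(not periodic) textbook forms; `scipy.signal.windows` provides them and the
tests pin the closed forms pointwise. Magnitudes pass through log(1+|·|)
and per-trial z-scoring by default — standard dynamic-range conditioning
for spectrogram CNN input. Channels are stacked as image planes (not tiled
spatially) so the time-frequency axes stay aligned across electrodes. The
retained band defaults to 0.5–30 Hz, matching the acquisition passband.

An O(N²) direct-summation DFT (`dft_oracle`) is kept alongside the
production `numpy.fft` path purely as an independent oracle; the rotation
factor's antisymmetry and periodicity identities are asserted numerically
rather than assumed.

## DMS layer conventions

Several details of the layer are under-determined and were fixed as
follows:

* **d is the spatial dimension** of the sub-map (min(H, W) for non-square
  maps), since only a spatial size defines a 2-D receptive field. Target
  kernel sizes d, d/2, d/4 are mapped to the largest odd integers ≤
  min(d, round(d/2^{j−1})), floored at 1, so same-padding stays symmetric
  and the largest branch is realisable (d = 16 → 15, 7, 3).
* **Chaining is add-before-module** (zᵢ₋₁ added to the *input* of Mᵢ),
  following the Res2Net hierarchy the design descends from.
* **Branch convolutions preserve the sub-map channel count** and the 1×1
  fusion maps back to it — required for the additive chain and for output
  shape = input shape.
* **Unequal splits** (C mod n ≠ 0): the first n−1 sub-maps get ⌊C/n⌋
  channels, the last the remainder; the shape-mismatched addition into the
  last module is skipped and the shuffle falls back to groups = 1, keeping
  the layer total over the 1–6 split grid without padding channels.
* **Shuffle groups = n_splits** when the channel count divides evenly.
* ReLU follows every convolution including the 1×1 fusion; no batch
  normalisation inside the modules.

## Backbone and initialisation

Default layout: 3×3 stem conv to 16 filters + 2×2 max-pool, three stages of
two basic residual blocks at widths 16/32/64 (stride-2 entry to stages 2–3,
projection shortcuts where shape changes), one DMS layer after each stage,
global max-pool, FC → softmax. This is intentionally small (~188 k
parameters): the datasets in scope have a few hundred trials and the
default 15×21×2 input. The bottleneck block variant is selectable. Weights
use He/variance scaling from a seeded generator; builds are bit-reproducible
given the seed. Strided same-padding follows the ceil-mode convention
(output = ⌈H/s⌉, padding split low/high).

The tensor engine is an in-package NumPy reverse-mode autodiff tape in
float64 — adequate for these model sizes, exact enough that oracle
comparisons hold to ~1e−13, and gradient-checked against central
differences in the tests.

## Training

Adam (β = 0.9/0.999, ε = 1e−8) at 3e−4; plateau schedule on validation
accuracy with patience 10, factor 0.5 (the factor is this package's choice;
only the floor 1e−4 and patience are prescribed), clamped at the floor.
Stratified 0.3 hold-out with a seeded permutation; best checkpoint by
validation accuracy, earliest epoch on ties for determinism; probability
clamp ε = 1e−7 in the standalone cross-entropy. `max_epochs` defaults to
100, but the bundled experiments use 30 — on the synthetic generator the
separable case plateaus within ~10 epochs, so 30 keeps each full 280-trial
run around half a minute on one CPU while leaving the schedule room to act.

## Evaluation and grids

Left is the positive class throughout (TP = left classified left).
Accuracy is reported as a two-decimal percentage in tables. Each grid cell
(window × channels, interval, branch subset, split count) is an independent
encode → train → evaluate run on the held-out split, with a per-cell seed
derived from (base_seed, cell index) via `SeedSequence`, so grids are
reproducible and cells are statistically independent. A failing cell is
recorded in the results table with its error rather than dropped. The
grid-integrity checks run on 20 trials × 2 epochs with a reduced network —
they verify row sets, ordering and accuracy validity, not effect sizes.

## Known limitations

* The generator's step-ERD and stationary 1/f background are idealisations;
  real EEG adds artifacts and drift that this pipeline does not model.
* The NumPy engine is single-threaded and CPU-bound; it is sized for
  desk-scale experiments, not large imaging datasets.
* Accuracies on synthetic data characterise the pipeline, not any real
  subject; they are expected to exceed accuracies achievable on real
  recordings at equal effect strength.
* The `.mat` loader requires an explicit layout declaration; it does not
  guess array names or axis order.
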