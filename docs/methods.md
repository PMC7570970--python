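# Methods

## Problem and pipeline

A walk-over weighing platform records the vertical load while an animal
crosses. The trace has three stages — step-on, all-hooves-on, step-off —
and only the middle stage is valid for weighing. On the valid segment
the load oscillates with the gait; the amplitude and the crossing speed
grow with how agitated the animal is, and the best weight estimator
differs by regime. The pipeline is therefore two-stage: classify the
passage's activity grade from five segment features, then estimate the
weight with a grade-specific method.

## Segment extraction

Threshold at `K1 = η·Wmax` with η = 0.8 by default. η is a configuration
knob, not a constant: the 0.8 value is conventional and no sensitivity
analysis backs it, so `extract_valid_segment` and the CLI expose it.
Samples below K1 are zeroed; the first differences of the zeroed series
locate the rising and falling edges, read here as the support of the
thresholded signal: A is the first above-threshold sample and B the
last. The comparison is closed (`≥ K1`) so boundary samples are kept —
a fixed tie-break. Several disjoint above-threshold runs (an animal
hesitating mid-platform) are resolved by keeping the longest run, the
most probable full-contact interval, with a warning.

## Features

Range `R`, standard deviation `σ` (population form, divisor N — kept
exactly as the defining formula states, not N−1), peak factor
`PAR = R/RMS`, form factor `FF = RMS/mean` and speed `v = L/t` with
`L = 2.5 m`. `FF ≥ 1` with equality iff the segment is constant, so FF
and PAR are pure shape measures while R and σ carry the oscillation
scale and v the pace. Min-max normalisation statistics are fitted on
the training split only and reused for test data; a degenerate feature
(xmax = xmin) maps to 0 deterministically. Values outside the fitted
range are deliberately not clipped.

## Classifier

RBF-SVM with one-vs-one multiclass handling (the classical extension of
the binary formulation). sklearn's `gamma` is exactly the kernel
parameter `g = 1/(2σ_k²)`. Class imbalance is corrected with SMOTE
(synthetic points interpolated between a minority sample and one of its
k = 5 nearest same-class neighbours); balancing precedes the 8:2
stratified split by default, matching the field workflow this package
follows, although that ordering lets synthetic points derived from
future test rows inform training — the `train --split-first` variant
splits first for leakage-free evaluation. Grid search runs over
C, g ∈ {2⁻⁸ … 2⁸} (powers of two, the conventional grid) with 5-fold
stratified CV; ties in mean CV accuracy resolve to the smallest C, then
the smallest g, preferring the smoother model and making the selection
deterministic. The selected (C, g) depend on the data; they are not
universal constants.

## Empirical wavelet transform

The spectrum of the valid segment, taken on the normalised axis [0, π]
(DFT bin k of an N-sample signal ↦ 2πk/N), is partitioned into
`n_modes` bands: the `n_modes` largest local maxima of a lightly
smoothed magnitude spectrum are retained (DC included as a candidate)
and each interior boundary sits at the minimum of the raw spectrum
between consecutive retained maxima — minima-between-maxima
partitioning. When the valley between two peaks is numerically flat (a
noise floor), the boundary is placed at the centre of the minimal
plateau rather than at an arbitrary bin, keeping tones out of filter
transition bands. Spectra that resolve too few maxima fall back to an
equal-width partition with a warning.

Each band gets a Meyer-type filter: value 1 on the band interior,
cos/sin transitions of relative half-width γ at each boundary driven by
the polynomial `β(x) = x⁴(35 − 84x + 70x² − 20x³)` (which satisfies
`β(x) + β(1−x) = 1`). Admissibility requires
`γ < min (w₊ − w₋)/(w₊ + w₋)` over consecutive boundaries so that
transitions cannot overlap; the default γ is half that bound — always
admissible, maximally smooth. Because exactly one cos/sin pair is
active at any frequency, the squared responses sum to one identically:
the transform is a tight frame and the components reconstruct the
signal to machine precision (measured residuals ~1e-16, asserted below
1e-8). The transform is computed in the frequency domain over the full
signal length (circular convolution): coefficients are
`ifft(fft(f) · conj(ψ̂))` and component i is the coefficient filtered
once more by its own band. The approximation coefficient uses the scale
filter φ̂₁ (consistent with its inner-product definition). `n_modes`
defaults to 3 — trend plus two detail bands, matching the structure of
observed weighing decompositions — and is configurable.

The periodic continuation maps a length-N segment to length N + M − 1
by wrapping the head onto the tail. The wavelet filter length M is
never prescribed by the underlying construction for discrete signals;
the package defaults to M = N//2 + 1 (half the segment wrapped) and
exposes it in `EstimatorConfig`. After decomposition f0 is truncated
back to the original N samples before averaging: the extension exists
only to stabilise the transform near the edges, not to add data.

## Estimators and the meaning of "m"

All three estimators are exact on constant segments and
shift-equivariant. The trimmed mean removes exactly one occurrence of
the maximum and one of the minimum (not all tied occurrences), so a
constant 3-sample segment leaves one sample. For the EWT estimators the
averaging count m is the number of *samples* of f0 — the only
unit-consistent reading of "mean of the trend component".

A structural note: for the non-extended circular transform the DC bin
passes entirely through the scale filter, so `mean(f0) = mean(f)`
exactly — the EWT estimator equals the plain segment mean there, and
its value over mean filtering lies in the trend/detail separation and
in the periodic variant. The continuation changes the estimate because
truncation re-weights the trend: on short segments whose oscillation
does not complete whole cycles, the continuation estimator has a
measurably lower mean error than the plain one (Monte-Carlo over 200
partial-cycle segments in the test suite); on segments with whole
cycles the plain mean is already unbiased and the comparison can
reverse.

## Synthetic passages

The generator emulates the trapezoidal load curve: linear step-on ramp
from 0, plateau of duration `platform_length / speed` centred on the
true weight, linear step-off ramp. The gait model is a fundamental
sinusoid at the step frequency (default 2 Hz, a plausible stride rate —
the frequency is a free parameter of the gait, not a measured value)
plus a half-amplitude second harmonic, each with random phase; Gaussian
sensor noise (default SD 2 kg) is added on the plateau. Two deliberate
design choices:

* The oscillation frequency is snapped to an integer number of cycles
  over the plateau, so the oscillation sums to exactly zero over the
  plateau samples and the plateau mean is an unbiased estimator of the
  true weight (bias would otherwise depend on the arbitrary phase).
* Ramps are quantised to whole samples on the sampling grid. At the
  default ramp fraction (0.15 of the passage) every ramp sample stays
  below 0.8·Wmax, so the extracted valid segment is the plateau itself
  and the feature R measures the gait oscillation, not ramp truncation.

Per-grade defaults: speeds 0.75 / 1.25 / 1.67 m/s and fundamental
amplitudes 8.3 / 25.6 / 48.3 kg for low / medium / high, the latter
calibrated once by Monte-Carlo so the mean simulated segment range R
lands near 24 / 60 / 108 kg — the relative magnitudes seen in field
passages of ~600 kg cows. `simulate_labelled_dataset` jitters speed
(SD 0.08 m/s), amplitude (15 %) and true weight (±80 kg uniform) so
grades overlap slightly as in a real herd.

What the generator does *not* emulate: hoof-by-hoof loading dynamics,
platform fouling, bouncing/sneezing transients, sensor drift, or
multi-animal crowding. Passing tests therefore demonstrate that the
algorithms recover known ground truth under idealised gait and noise —
they do not certify field error rates, which depend on animal behaviour
the simulation leaves out.

## Problem sizes and numerics

The parameter-recovery study uses 300 simulated passages per grade and
the classifier study 200 per grade (SMOTE-balanced, 8:2 split, full
17×17 grid, 5-fold CV) — large enough for stable Monte-Carlo means
while keeping the whole suite and the acceptance script each under a
minute on one CPU. Tolerances: tight-frame reconstruction asserted
below 1e-8 relative, partition of unity below 1e-10, estimator
exactness on constants below 1e-8; per-grade mean recovery error
asserted below 1 % with the low ≤ medium ≤ high ordering (driven by
segment length: a slower crossing yields more valid samples).

## Known limitations

* Boundary detection assumes the trend and the gait fundamental are
  spectrally separated; segments only a few samples long fall back to
  equal-width partitions.
* SMOTE-before-split reproduces the reference workflow but optimistically
  biases held-out accuracy; use `--split-first` for honest evaluation.
* Absolute per-grade amplitude defaults target ~600 kg animals; for much
  lighter stock, scale `oscillation_amplitude_kg` accordingly or the
  oscillation troughs may cross the detection threshold.
* Estimates assume a tared, single-animal passage; taring and animal
  separation are operational concerns outside this package.
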