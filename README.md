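# walkweigh

Dynamic walk-over weighing of cattle from load-platform time series.

Static weighing stresses animals and ties up staff; a walk-over platform
placed in an exit corridor records a weight curve while the animal
crosses, but the curve oscillates with the animal's gait and the error
of a naive average grows with how vigorously it moves. `walkweigh`
implements a two-stage approach: first classify the passage's *activity
grade* (low / medium / high), then compute the dynamic weight with an
estimator matched to that grade.

## Method

For a raw trace `W` sampled at 100 ms:

1. **Valid-segment extraction.** Threshold at `K1 = η·Wmax` (default
   η = 0.8), differentiate the thresholded series, and keep the samples
   between the start of the rising edge and the start of the falling
   edge — the interval with all four hooves on the platform, `f(t)`.
2. **Features.** Five quantities summarise the segment: range
   `R = fmax − fmin`, population standard deviation σ, peak factor
   `PAR = R / RMS`, form factor `FF = RMS / f̄`, and crossing speed
   `v = L / t` for a platform of length `L = 2.5 m`. Features are
   min-max normalised with statistics fitted on the training split.
3. **Activity classification.** A three-class RBF-SVM
   (`κ(x, x′) = exp(−g‖x − x′‖²)`, `g = 1/2σ²`) over the normalised
   features, trained after SMOTE balancing and an 8:2 stratified split,
   with C and g chosen by grid search over powers of two under
   stratified cross-validation.
4. **Weight estimation.**
   - *low*: trimmed mean — drop one occurrence each of the segment's
     max and min, average the rest;
   - *medium*: empirical wavelet transform (EWT) — partition the
     segment's Fourier spectrum at the minima between its dominant
     peaks, build Meyer-type band filters, and average the
     approximation component `f0`, which carries the weight trend;
   - *high*: periodic-continuation EWT — wrap the head of the short,
     strongly oscillating segment onto its tail before transforming to
     suppress edge artefacts, then average `f0` truncated back to the
     original support.
5. **Evaluation.** Confusion matrix (rows = predicted grade) with
   overall accuracy, per-class precision/recall/specificity/F1, and the
   weight error `|mc − ms| / ms × 100 %` against a static reference.

A synthetic passage generator with known ground-truth weight and grade
(trapezoidal load curve, grade-dependent gait oscillation, sensor
noise) makes every stage testable without farm data.

## Worked example

```python
from walkweigh import (SimConfig, simulate_trace, extract_valid_segment,
                       compute_features, estimate_weight, weight_error)

cfg = SimConfig(grade=1, true_weight_kg=602.2, seed=314)   # medium activity
trace = simulate_trace(cfg)
segment = extract_valid_segment(trace, eta=0.8)
fv = compute_features(segment)
est = estimate_weight(segment, grade=1)                    # EWT estimator
err = weight_error(est.mc_kg, 602.2)
```

prints, via the obvious format strings:

```
segment: n=20 samples, duration=2.0 s, K1=504.6 kg
features: R=52.94 kg  sigma=20.61 kg  PAR=0.0879  FF=1.0006  v=1.25 m/s
dynamic weight mc = 602.2 kg (ewt)
error vs static reference 602.2 kg: 0.0017 %
```

The animal crossed the 2.5 m platform in 2.0 s (1.25 m/s, a typical
medium-activity speed); the gait oscillation spans ~53 kg peak to peak,
yet the mean of the EWT trend component recovers the 602.2 kg reference
to a small fraction of a percent.

The same pipeline is scriptable from the shell:

```sh
walkweigh simulate --out-dir traces --n-per-grade 10 --seed 1
walkweigh features traces/sim-*.csv --out features.csv
walkweigh train features.csv --model-out model.joblib   # needs a label column
walkweigh run traces --model model.joblib --out weights.csv
walkweigh evaluate --matrix '[[101,2,0],[0,88,2],[0,0,113]]'
```

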