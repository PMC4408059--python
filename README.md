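# odp — ocular dicrotic pulse detection from corneal-pulse signals

The corneal pulse (CP) is the micrometre-scale cyclic displacement of the
corneal surface driven by the cardiovascular system, recorded without
contact by an ultrasonic distance sensor (10 s at 400 Hz). In a
substantial fraction of older and glaucomatous eyes each cardiac cycle
carries a *double* peak — the **ocular dicrotic pulse (ODP)**, the ocular
analogue of the arterial dicrotic wave. Detecting the ODP from the CP
signal alone (without synchronous blood-pulse or ECG recordings) matters
for large longitudinal studies of ocular biomechanics and glaucoma.

This package implements a complete ODP detection pipeline:

1. **Continuous wavelet transform** of the signal derivative with the
   complex Gaussian derivative mother wavelet
   `ψ(x) = (−2x − i)·exp(−x² − ix)`, `x ∈ [−5, 5]`. Each scale-`s`
   wavelet is sampled at `s` points, made exactly zero-sum, and
   L¹-normalised, so constants are rejected exactly and the response to
   white noise of sd σ has sd `σ·‖ψ_s‖₂`, decreasing with scale.
   Coefficients whose wavelet support leaves the observation window are
   blanked (trapezoidal cone of influence).
2. **Texture featurisation**: each of the four planes (real, imaginary,
   modulus, phase) is quantised into `N = 8` gray levels; ordered level
   pairs at horizontal offset `L = 25` pixels (0.0625 s) form a gray-level
   co-occurrence matrix, from which homogeneity, correlation, energy and
   contrast are computed — 16 features per signal.
3. **Detection**: a univariate rule (dicrotic iff phase-plane homogeneity
   ≤ 0.428), a conditional inference tree (permutation-test-based splits,
   Bonferroni-adjusted, α = 0.05), and a random forest (entropy
   criterion). Features are chosen by backward sequential selection driven
   by forest importance; accuracy is estimated by the **bootstrap 632+**
   method, `err⁶³²⁺ = (1−w)·err_train + w·err⁽¹⁾` with
   `w = 0.632/(1 − 0.368·R)` and `R` the relative overfitting rate against
   the no-information rate.

A synthetic-signal module generates the harmonic test signals (1 Hz,
1 Hz + 2 Hz, 25 dB additive white Gaussian noise, 0.3 Hz breathing
component) and labelled dicrotic / non-dicrotic CP-like signals, so the
whole pipeline is testable without any recordings.

## Worked example

```python
from odp import (DEFAULT_CP_CONFIG, ScaleGrid, backward_select,
                 bootstrap_632plus, build_dataset, make_dataset)

signals = make_dataset(30, DEFAULT_CP_CONFIG, jitter=0.05, seed=42)
data = build_dataset(signals, ScaleGrid(200, 1000, 32))
selected = backward_select(data, "random_forest", seed=42, inner_B=50)
for kind in ("random_forest", "conditional_tree", "homogeneity_threshold"):
    rep = bootstrap_632plus(data, kind, B=100, seed=42,
                            selected_features=selected if kind == "random_forest" else None)
    print(kind, round(rep.accuracy_632plus, 3))
```

prints (`examples/04_detection_validation.py`):

```
backward selection kept 1 feature(s): ('real_contrast',)
random_forest          632+ accuracy = 1.000 (sd 0.000, B=100)
conditional_tree       632+ accuracy = 1.000 (sd 0.000, B=100)
homogeneity_threshold  632+ accuracy = 0.500 (sd 0.092, B=100)
```

The multivariate detectors separate dicrotic from non-dicrotic synthetic
signals essentially perfectly, while the fixed univariate threshold
(calibrated on real recordings) is uninformative here — single-feature
detection generalises poorly, multivariate texture conglomerates do not.
The other scripts in `examples/` walk through signal synthesis, the
scalogram pattern of the 1 Hz reference signal (two modulus maxima per
cycle, at the raw signal's extrema), and the feature tables.

## Command line

```sh
odp simulate --n-per-class 10 --seed 0 --out-dir signals/
odp features signals/ --out features.csv
odp validate features.csv --model forest -B 200 --seed 0
odp transform signals/cp-dicrotic-*.csv --out-dir scalograms/
odp pipeline signals/ --out-dir results/
```

Every run echoes its full configuration (`run_config.json`) into the
output directory for provenance.

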