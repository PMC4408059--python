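# Methods

## The transform

The mother wavelet is the derivative of a complex Gaussian,
`ψ(x) = (−2x − i)·exp(−x² − ix)`, treated as compactly supported on
`x ∈ [−5, 5]`; `|ψ(±5)| ≤ √101·e⁻²⁵ < 10⁻⁹`, so the truncation is
numerically immaterial. Two sign conventions exist for this family
(mutual complex conjugates); this package fixes
`(−2x−i)exp(−x²−ix)`. The conventions share the modulus plane but flip
the sign of the phase plane, and since phase-plane GLCM statistics are
not invariant under a global sign flip, the choice is fixed and recorded
in every run's configuration echo.

A discrete wavelet of scale `s` (support exactly `s` samples) evaluates
ψ at `s` equidistant points spanning `[−5, 5]`, subtracts the sample
mean, and divides by the L¹ norm. The mean subtraction makes the
discrete sum *exactly* zero (up to one rounding step, < 10⁻¹²), so a
constant input maps to exactly zero rather than approximately — the
wavelet "integrates to zero" at the discrete level. L¹ normalisation
makes responses comparable across scales and bounds the white-noise
response: for i.i.d. input noise of sd σ, the complex output at scale
`s` has root-mean-square modulus `σ·‖ψ_s‖₂`, and `‖ψ_s‖₂` is strictly
decreasing in `s` (verified over `s ∈ {10,…,3500}`), so coarse scales
progressively suppress measurement noise. No pre-filtering of the input
is needed: restricting the scale interval acts as the band-pass.

The transform computes, per scale, the same-length FFT convolution of
the input with the wavelet (zero-padding to `n+s−1`, cropping so output
sample `t` corresponds to the wavelet centred on input sample `t`) —
`O(n log n)` per scale, `O(w·n log n)` overall. Columns where the
wavelet support leaves the observation window (`t < ⌊s/2⌋` or
`t ≥ n−⌊s/2⌋`) are masked, giving the trapezoidal valid region; because
these columns are excluded everywhere downstream, the boundary treatment
of the convolution cannot leak into features. For even `s` the centre
index is `⌊s/2⌋` and blanking uses `⌊s/2⌋` on both ends.

**Derivative input.** Pulse features are matched on the *derivative* of
the recorded trace: the wavelet has the shape of the derivative of a
wide peak, so convolving the derivative signal gives a matched response
whose modulus peaks where the raw signal has extrema. On the 1 Hz
reference sinusoid, modulus rows at scales 800–2500 then show exactly
two maxima per cycle, at the times of the signal's maxima and minima
(within one or two samples), and the phase plane changes sign at the
same times — the signature pattern the texture features encode.
Convolving the *raw* sinusoid instead puts the maxima at the zero
crossings. The high-level entry points (`signal_features`,
`run_pipeline`, the CLI) therefore differentiate by default
(central differences, `numpy.gradient`); `transform` itself remains a
pure convolution of whatever samples it receives, and `differentiate=False`
is available for experiments on the raw trace.

Scale grids are equidistant on a linear or logarithmic axis and rounded
to integers (duplicates dropped with a warning). The feature band is
`[200, 1000]` samples — at 400 Hz this covers roughly 0.6–3.2 Hz, i.e.
the cardiac fundamental and its first harmonics, the band in which
dicrotic and non-dicrotic recordings differ most — with 64 logarithmic
scales by default (the count balances resolution against runtime and is
configurable; results are insensitive to it well before 64). The
visualisation preset spans `[10, 3500]`, nearly all technically possible
scales for a 4000-sample signal.

## Texture features

Each plane (real, imaginary, modulus, phase) is quantised into `N = 8`
uniform bins between the minimum and maximum of its *valid* pixels
(`level = min(N, 1+⌊N·(v−lo)/(hi−lo)⌋)`; a degenerate plane maps to
level 1). Min–max binning makes the features invariant to positive
affine transforms of a plane, hence to input scaling — consistent with
the transform's own scale invariance. Phase is quantised as an ordinary
linear variable on its observed range; its circularity is ignored, the
plane being treated as a plain image.

The co-occurrence matrix counts *ordered* level pairs `(i, j)` at a
horizontal offset of `L = 25` pixels (0.0625 s at 400 Hz) within each
scale row — single direction, no symmetrisation. Offsetting beyond
direct neighbours counteracts the smoothness of the transform, which at
`L = 1` would pile almost all mass on the diagonal and flatten the
statistics' range. Pairs with either pixel masked are excluded, and
normalisation is by the count of valid pairs, so the trapezoid blanking
biases nothing. From the normalised matrix the four classical statistics
are computed: homogeneity `Σ p_ij/(1+|i−j|)`, energy `Σ p_ij²`, contrast
`Σ p_ij(i−j)²`, correlation `Σ p_ij(i−μ_i)(j−μ_j)/(σ_i σ_j)`. A zero
marginal variance leaves correlation undefined; it is then encoded as 0
in the 16-feature vector with the feature name recorded in an
`undefined` flag, so classifiers always receive complete numeric input.
Features are computed on the coefficient matrices directly (not on
rendered images), making them resolution- and colormap-independent.

## Detectors and validation

**Univariate rule.** Dicrotic iff phase-plane homogeneity ≤ τ, boundary
inclusive; the reference threshold τ = 0.428 was calibrated on real
recordings. A fittable variant (`homogeneity_threshold` with
`threshold=None`) chooses the cut minimising training error.

**Conditional inference tree.** At each node the association between
every feature and the binary label is tested by a permutation test of
the absolute Pearson correlation (499 permutations by default, shared
across features and drawn from the seeded generator, so fits are
deterministic); p-values are Bonferroni-adjusted over the features under
test, and the node becomes a leaf when the smallest adjusted p-value
exceeds α = 0.05. Otherwise the winning feature is split at the cutpoint
maximising the standardised two-sample statistic
`|Σ_{x≤c}(y−ȳ)|/√(n_L·n_R)` subject to a minimum of 3 samples per side.
This test-then-split construction gives near-unbiased variable selection
and a statistical stopping rule without post-pruning. It is implemented
here directly (no native Python implementation of test-based trees was
suitable); the permutation test replaces the asymptotic linear-statistic
distribution used by some implementations, with the same contract.

**Random forest.** scikit-learn's `RandomForestClassifier` with the
entropy criterion (100 trees by default). Its mean-decrease-in-entropy
importances drive **backward sequential feature selection**: starting
from all 16 features, each step scores the current subset by a bootstrap
632+ estimate (inner `B = 50` for tractability) and drops the
least-important feature; the subset with the highest estimate wins, ties
going to the smaller subset, and the empty set is never returned.
Selection runs before the final validation; on strongly separable data
this is immaterial, on marginal data the final estimate can be slightly
optimistic (a known property of select-then-validate designs).

**Bootstrap 632+.** `B = 200` resamples by default (configurable; the
estimate is stable well below that). Per resample, the detector is
refitted on the bootstrap sample and evaluated on its out-of-bag
samples. `err⁽¹⁾` averages each sample's error over the resamples
excluding it (samples never out-of-bag are dropped with a warning);
`err_train` is the resubstitution error of a fit on all data; the
no-information rate is `γ = Σ_k p̂_k(1−q̂_k)` over classes with `p̂` the
label and `q̂` the prediction marginals; `R = (err⁽¹⁾ −
err_train)/(γ − err_train)` clipped to `[0, 1]` (and 0 when either
difference is non-positive); `w = 0.632/(1 − 0.368·R)`. The report
retains every ingredient (per-sample leave-one-out errors, per-resample
accuracies, γ, R, w), so the estimate is exactly recomputable, and the
quoted sd is that of the per-resample out-of-bag accuracies. By
construction the estimate lies between the resubstitution and
leave-one-out bootstrap accuracies.

## Synthetic signals

The generator emulates the acquisition protocol: 10 s at 400 Hz, ~1 Hz
cardiac fundamental, zero mean, unit fundamental amplitude (exact
experimental amplitudes are unavailable; the pipeline is scale-invariant
so units are immaterial). Harmonic test signals are exact sums of
sinusoids. White Gaussian noise is added at a prescribed SNR,
`10·log10(P_signal/P_noise)` with signal power about the mean; 25 dB is
the typical biomedical value and the study default. Breathing is an
additive 0.3 Hz sinusoid at half the fundamental amplitude by default
(a multiplicative amplitude-modulation mode is available for
experiments, the physiological coupling being not precisely known).

CP-like signals concatenate cycles of an analytic unit-period template
`sin(2πu) + r·sin(4πu + π/3)`: `r = 0.5` yields a morphologically clear
double peak (dicrotic), `r = 0.05` a single peak (non-dicrotic) —
mirroring the 1 Hz + 2 Hz composite used to characterise the transform.
Each cycle's period is jittered by a uniform factor (default ±5%) and
the template is evaluated on the jittered grid, so cycles vary in length
but join continuously. What the simulator does *not* model: blink and
head-movement artifacts, heart-rate drift, cycle-shape variability
beyond period jitter, device noise colour, or any hemodynamics — it is
morphological only. Consequently the synthetic classes are far cleaner
than real recordings: detectors reaching ~1.0 on synthetic data shows
the pipeline is consistent end-to-end (features carry the morphology,
selection finds them, validation is calibrated), not that real-data
accuracy would be ~1.0; real recordings with subtle dicrotism near the
labelling boundary are precisely what synthetic data cannot emulate.

## Numerical choices and problem sizes

- Zero-sum and L¹ constraints are enforced constructively; tests assert
  `|Σc| < 10⁻¹²` and `|‖c‖₁ − 1| < 10⁻¹²`.
- Phase of an exactly-zero coefficient is 0 (`numpy.angle` convention);
  phase range is `(−π, π]`.
- Convolution oracle equivalence (FFT vs direct time-domain) is asserted
  at 10⁻¹⁰ relative error; filter invariances (constants, scaling,
  shifts) at the same tolerance.
- The white-noise contract is measured on 4000-sample windows (the
  recording length) over 100 realisations: shorter windows hold too few
  correlation lengths at coarse scales for a 5%-accurate sd estimate.
- The end-to-end study uses 100 signals per class, 64 scales in
  `[200, 1000]`, inner `B = 50` for selection and `B = 200` for final
  validation — a few minutes on one CPU.
- Seeds: every stochastic component (noise, jitter, bootstrap,
  permutation tests, forests) is driven by explicit integer seeds;
  per-signal and per-resample seeds are derived deterministically from
  the master seed.

## Known limitations

- The conditional-tree permutation test uses the absolute Pearson
  correlation as its node statistic; heavily tied or pathological
  features could in principle favour different splits than a
  rank-based statistic would.
- GLCM features use a single offset and direction; multi-offset stacks
  and further Haralick statistics (entropy, cluster shade, …) are out of
  scope.
- The univariate threshold τ = 0.428 is a property of the real
  population it was calibrated on and transfers to other populations
  only as an example of a fixed single-feature rule.
- No inverse transform, no discrete (dyadic) wavelet transform, and no
  modelling of auxiliary physiological channels (blood pulse, ECG).
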