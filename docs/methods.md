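# Methods

## Signal model and segmentation

The input is a mono tracheal-sound recording, nominally sampled at
44 100 Hz by a microphone embedded in the ventilator airway. Breath flow
is wide-band noise strongly autocorrelated at short lags; the inter-cycle
pauses contain only sensor/ambient noise, whose short-lag autocorrelation
is far smaller. Segmentation therefore frames the signal (Hamming window,
L = 1024 samples ≈ 23 ms, non-overlapping) and computes per frame

    R_i(k) = sum_{m=0}^{L-1-k} [x_i(m) w(m)] [x_i(m+k) w(m+k)],  k = 1..400

keeping the maximum over lags. Lag 0 is excluded by default
(`include_lag_zero=False`): it equals the frame energy, which would make
the envelope a plain energy detector rather than a correlation detector;
the flag restores the inclusive definition.

The noise floor C0 is the mean envelope over every frame whose start lies
in the leading `silence_duration` (default 0.025 s) of the recording,
which the protocol assumes silent; with non-overlapping 1024-sample frames
at 44.1 kHz that window covers the first two frame starts. If the window
is shorter than one hop, the first frame alone is used (degenerate-input
safety). Because R_i(k) and C0 both scale with the square of a global
gain, the segmentation is gain-invariant (tested).

Thresholds: C1 = a·C0 opens/closes a cycle, C2 = b·C0 confirms it.
Defaults a = 2, b = 4; these are environment-dependent dials — quiet
airway-embedded sensors tolerate small multipliers, noisy rooms need
larger ones. The state machine is a hysteresis: open on the first frame
strictly above C1, confirm on any frame strictly above C2, close once the
envelope has stayed at or below C1 for longer than Ts (default 0.3 s,
chosen to bridge the inspiration–expiration pause at adult breathing
rates while still splitting distinct cycles ~1 s apart). "Strictly
greater" is used at both thresholds; candidates never reaching C2 are
dropped silently (counted in logs). An all-zero lead-in gives C0 = 0, in
which case a fallback floor of 1e-3 times the smallest positive envelope
value is used so thresholds stay finite.

## Spectrogram

Per cycle, a one-sided STFT with N = 1024, hop = N/2 (standard 50 %
overlap; the hop is not dictated by the method, so it is a config knob)
and a symmetric 4-term Blackman–Harris window. The window convention
(symmetric, as in offline spectral analysis) applies to all windows in
the package. Power E(n,k) = |X(n,k)|²; the image is 10·log10 E with
entries at or below `floor_db` (default −120 dB) clamped there to avoid
−inf on digitally silent bins. Rows index frequency (low first), columns
time, so the "vertical striations" produced by crackles are along the
frequency axis at a fixed time column.

## Texture attributes

The dB image is reduced to G = 16 gray levels by per-image linear min–max
scaling — a shape-preserving remapping of the histogram, not
equalization; a constant image maps to level 0 everywhere. Co-occurrence
matrices are counted at distance d = 1 (the conventional Haralick
default; configurable) for the four orientations, each pair counted in
both directions (symmetric) and normalized to sum to 1. On this image
grid ψ=0° pairs step along time, ψ=90° along frequency, 45°/135° the two
diagonals.

Measures per orientation: energy ΣP², inertia Σ(i−j)²P², correlation
(Σ i·j·P − u1·u2)/(d1·d2), entropy −ΣP log10 P with 0·log 0 = 0. Two
deliberate definition choices:

- **Inertia squares P.** The package's inertia is Σ(i−j)²P², not the
  classical Haralick contrast Σ(i−j)²P. `classic_inertia=True` switches
  to the classical form. Both are monotone in the same image structure;
  the classifier z-scores features, so the choice mostly rescales.
- **Marginal SD centering.** `d2` is computed about the row-marginal mean
  u1 by default (`classic_marginal_sd=True` uses the column mean u2).
  With symmetric counting the marginals coincide, so the two forms are
  identical for every matrix the pipeline itself produces; the flag only
  matters for externally supplied asymmetric matrices. Correlation is
  therefore always in [−1, 1] in pipeline use; for a single-level
  (degenerate) image it is defined as 0 with a warning.
- **Entropy uses log base 10**, so the uniform 16×16 matrix has entropy
  log10(256) ≈ 2.408, not the bit/nat values other packages report.

Orientation note: scikit-image's `graycomatrix` measures its diagonal
angles with the row axis pointing down, so its 45° equals this package's
135°; the oracle tests align the conventions explicitly.

## Feature selection and classifier

Attributes are ranked by |Pearson r| (point-biserial against the 0/1
label); ties break by the fixed attribute order, constant columns get
r = 0 with a warning. Ranking runs inside each CV training fold by
default — computing it on all data would leak the held-out patient's
labels; `global_ranking=True` reproduces the leaky variant for
comparison.

The classifier maximizes l(θ) − λΣ_{j≥1}θj² with λ = 1e-8. The penalty is
the squared norm, consistent with the −2λθ gradient; a `penalty_form`
flag provides the plain-norm variant. The intercept is excluded from the
penalty (standard ridge practice). Features are z-scored on the training
data (means/scales stored in the model and replayed at prediction);
without standardization the raw attribute scales differ by orders of
magnitude and quasi-Newton steps are poorly conditioned.

Optimization is DFP: H0 = I, ascent direction H·∇, Armijo backtracking
(initial step 1, κ = 0.5, sufficient-increase constant 1e-4, at most 60
halvings), DFP rank-two update applied with the sign convention of the
negated (minimization) problem so the secant condition H·(∇_k − ∇_{k+1})
= step holds; when the curvature product is non-positive H resets to the
identity. Stopping: ‖∇‖∞ < 1e-6 or 200 iterations. On nearly separable
training folds the tiny λ leaves the optimum almost flat and the cap is
reached with gradient ~1e-5; prediction is unaffected, so
cross-validation suppresses the `ConvergenceWarning` that a direct
`fit_dfp` call would surface. Tests verify the fitted objective agrees
with scipy's BFGS and with scikit-learn's ridge logistic (C = 1/(2λ)) to
1e-6, and that simulated-data coefficients are recovered within 3
standard errors.

## Evaluation

Folds are leave-one-patient-out; patients are held out in sorted order.
Both aggregation conventions are reported — the mean of per-fold rates
and the pooled-count accuracy — because they differ whenever patients
contribute unequal cycle counts. Metrics are computed with exact rational
arithmetic and displayed with half-up rounding to one decimal in percent;
zero-denominator metrics are returned as None with a warning. A fold
whose training labels are single-class is skipped and recorded.

## Synthetic data

`SynthSpec` defaults define the simulated study conditions: 44.1 kHz,
10 s recordings, 18 breaths/min with a 1.2 s inter-cycle gap and a 0.15 s
intra-cycle pause (below Ts, so the segmenter must bridge it), flow noise
band-passed to 100–2000 Hz at 15 dB above a σ = 0.01 Gaussian floor,
0.3 s of lead-in silence for the noise-floor estimate. Sputum recordings
add crackles: exponentially damped sinusoids (the standard crackle
model), ~25 per active second, 2–8 ms long, 500–8000 Hz, peaking at 4×
the breath RMS. Cohorts take per-patient multiplicative lognormal jitter
(σ = 0.2) on breathing rate and SNR so leave-one-patient-out folds face
genuine inter-subject shift; the sputum-label count is
round(total × 145/272), mirroring the class balance of the motivating
clinical dataset, spread evenly over patients.

What the generator does **not** emulate: ventilator valve noise, heart
sounds, wheezes/rhonchi, sensor saturation, time-varying breathing
rhythm within a recording, or the acoustic coupling of real secretions.
Passing the synthetic end-to-end tests therefore demonstrates the
pipeline is implemented correctly and can discriminate crackle-textured
from clean cycles — not that it attains any particular accuracy on
clinical recordings.

## Problem sizes

The test suite and acceptance script scale the simulations to desk size:
the end-to-end cohort is 12 patients × 6 recordings × 10 s (≈ 180–220
cycles, comparable to the 272 clinical samples of the motivating study;
the suite uses 4 recordings/patient), segmentation recall uses 12 × 15 s
recordings (≈ 48 cycles), and the permutation null 200 balanced samples
across 5 pseudo-patients. At these sizes the whole acceptance run takes
seconds.

## Known limitations

- Segmentation assumes the recording *starts* silent; a recording that
  opens mid-breath inflates C0 and can suppress detections.
- Per-image min–max quantization makes the texture attributes dependent
  on each image's dynamic range; a fixed global dB range may be
  preferable when comparing across devices.
- The DFP implementation stores a dense inverse-Hessian approximation —
  fine for 17 parameters, not meant for wide feature sets.
- With λ as small as 1e-8, perfectly separable folds produce large
  (finite, capped) weights; raise λ if calibrated probabilities matter.
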