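# Methods

## The calibration problem

A post-beamformed RF ultrasound frame factorizes, per frequency `f` and
depth `x`, into a system response and a tissue signal,

    W(f, x) = S_φ(f, x) · P(f, x),

where `S_φ` collects everything the scanner contributes under setting `φ`
(excitation pulse, transducer electromechanical response, diffraction /
focal gain, output power) and `P` collects everything the medium
contributes (backscatter form factor, attenuation, transmission loss).  A
classifier trained on raw RF at one setting learns features of
`S_train · P`; data acquired at another setting follows `S_test · P` and
falls outside the training distribution even when the tissue is identical.

If the same medium realization is imaged under both settings — a clamped
transducer on a uniform calibration phantom — the tissue term cancels in
the spectral ratio and the **setting transfer function**

    Γ(f, x) = W_test(f, x) / W_train(f, x) = S_test(f, x) / S_train(f, x)

is directly estimable.  `Γ` maps training-setting data to the testing
setting (train-time calibration, applied before model training) and `Γ⁻¹`
maps testing-setting data back to the training setting (test-time
calibration, applied before inference; no retraining needed).

## Estimation pipeline

1. **Depth-aware spectra.** Because the patch grid draws inputs from nine
   distinct 200-sample depth gates, one transfer function is estimated per
   gate: each gate is Hann-windowed on every A-line of every repeat frame
   (10 repeats × 256 lines = 2560 segments) and the periodograms are
   averaged; `n_fft = 512` (≈78 kHz bins at 40 MHz sampling).  Hann is the
   conventional leakage/variance compromise; the zero-padded grid is dense
   enough for the smooth responses involved.
2. **Noise floor and SNR.** The floor is the mean power in 18–20 MHz,
   outside the transducer band and just below Nyquist.  Per-bin SNR is
   `(P − floor)₊ / floor`, computed for both settings, and the pairwise
   **minimum** is used — a bin is only trusted if both acquisitions carry
   signal there.
3. **Magnitude ratio.** `|Γ| = sqrt(P_test / P_train)` per bin.  Bins with
   zero train power are set to zero rather than infinity; they carry
   SNR = 0 and are eliminated by the next step regardless.
4. **Wiener regularization.**

       Γ_W   = (1/|Γ|) / ((1/|Γ|)² + 1/SNR)  →  |Γ|   as SNR → ∞
       Γ_W⁻¹ =   |Γ|   / (  |Γ|²   + 1/SNR)  →  1/|Γ| as SNR → ∞

   Both tend to zero where SNR → 0, so the filters deliberately *suppress*
   bands that cannot be transferred instead of amplifying noise.  Note the
   forward-backward product `Γ_W · Γ_W⁻¹ ≤ 1`, with equality only in the
   infinite-SNR limit: a round trip through both filters is mildly lossy
   at band edges by design.
5. **FIR realization.** Each magnitude response becomes a 51-tap type-I
   linear-phase filter via frequency sampling (`scipy.signal.firwin2`
   with a Kaiser β = 3 taper — noticeably less smoothing bias than the
   default Hamming window on the steep Wiener responses, while still
   damping ripple from the out-of-band cutoffs).  Symmetric taps plus center-aligned same-length
   convolution give zero net group delay, so patch-grid coordinates remain
   valid after filtering.  The phase of `Γ` is discarded throughout —
   only magnitude is matched.
6. **Depth-aware application.** The exact rule on the classifier path:
   convolve the frame with depth line *i*'s filter and take only line
   *i*'s patches from the result, which keeps the 51-tap edge transients
   out of the 200-sample gates.  Whole-frame outputs (file-level
   calibration) assign each axial sample to its nearest gate center's
   filter; adjacent responses differ smoothly, so the band seams are
   negligible, and the patch path remains exact.

The 50% train-time variant calibrates a uniformly random half of the
training *frames* (frame-level selection keeps all patches of a frame
consistent); labels are never altered.

## Synthetic data generator

All testing runs on a pulse-echo simulator that realizes the same
factorization the method assumes, so the estimated `Γ` can be compared
against closed-form ground truth:

- geometry: 2080 axial samples × 256 A-lines at 40 MHz, ≈4 cm depth at
  1540 m/s — the reference acquisition geometry;
- per A-line, a Poisson reflectivity train (10 scatterers/mm, unit-normal
  amplitudes — several per resolution cell, giving developed speckle);
- medium: Gaussian backscatter form factor `R(f) = exp(−f²/2σ_ff²)` and a
  blockwise (100-sample) two-way attenuation tilt in dB/cm/MHz.  Classes:
  "phantom1" (σ_ff = 4 MHz, 0.7 dB/cm/MHz) vs "phantom2" (σ_ff = 8 MHz,
  0.5 dB/cm/MHz); calibration medium σ_ff = 12 MHz, 0.1 dB/cm/MHz (a
  weakly scattering low-attenuation agar analogue);
- system: Gaussian-modulated cosine pulse (9 or 5 MHz, fractional −6 dB
  bandwidth 0.85) convolved with a fixed broadband transducer response
  (5.5 MHz center, 3 MHz Gaussian sigma).  The transducer factor is
  common to both settings, so it cancels exactly in `Γ`, but it keeps both
  settings' spectra SNR-reliable across the shared 2–7.5 MHz analysis
  band — matching the hardware regime in which the method is meant to
  operate, where the observed spectral shift between the 9 and 5 MHz
  settings is considerably smaller than 4 MHz.  A short broad pulse was
  chosen deliberately: with narrowband pulses the two settings share
  almost no usable band and no linear filter could transfer between them;
- focal gain: frequency-independent depth envelope
  `1 + Σ_k exp(−(z−z_k)²/2σ²)` with σ = 5 mm over the transmit foci; the
  2 cm vs 1+3 cm presets then give a ≈0.64 gain ratio at the 2 cm gate;
- output power: an exact amplitude scale `10^(dB/20)`;
- white Gaussian noise, `σ = 0.005`, giving ≈45 dB peak in-band SNR for
  the calibration medium — typical for averaged RF acquisitions — and a
  genuine noise floor near 20 MHz for the SNR estimator to find;
- calibration stacks share one scatterer realization across settings and
  redraw only the noise per repeat frame (the stable acquisition).

**What the simulator does not emulate:** wave propagation (no diffraction
integrals, no elevational beam), lateral speckle correlation (A-lines are
independent), nonlinear propagation, phase aberration, time-gain
compensation, and any phase difference between settings (the simulated
system responses are magnitude-plus-linear-phase by construction, which is
exactly the regime the magnitude-only filter design assumes).  Passing
tests therefore demonstrate that the pipeline recovers and inverts
system-response ratios under the model's own assumptions — not that those
assumptions hold on any particular scanner.

### Oracles

`analytic_transfer_ratio` gives the exact in-band ground truth for `Γ`
(pulse DTFT ratio × focal-gain ratio × power ratio; medium terms cancel).
A windowed periodogram, however, estimates the PSD *smeared* by the
window's spectral kernel, which biases steep spectral skirts;
`predicted_line_spectrum` therefore convolves the analytic PSD with the
Hann gate's kernel and adds the noise level, producing the exact expected
value of the estimator at every bin.  Recovery tests compare against the
smeared oracle wherever SNR > 10 and against the raw analytic ratio
inside the analysis band, both at 1 dB.

## Classifiers

- `small_cnn` — conv 8@9×5 stride (4,2) → ReLU → conv 16@3×3 stride (2,2)
  → ReLU → global average pooling → linear softmax, written in numpy with
  an explicit backward pass; Adam (lr 1e-3), batch 128, cross-entropy with
  uniform class weights, per-patch z-score, horizontal (lateral-axis) flip
  augmentation with probability 0.5, 4 epochs.  Global pooling over ReLU
  feature maps makes the network a learnable band-energy detector — an
  appropriate inductive bias for spectral tissue classification and small
  enough to train repeatedly on one CPU.
- `spectral_logreg` — logistic regression on per-patch averaged log power
  spectra (the classical spectral-QUS feature set), via scikit-learn.
- `resnet50_mod` / `densenet201_mod` — the full-scale architecture stage
  tables for 200×26 RF patches, shipped as specification presets with a
  dry-run shape checker (`dry_run_shapes`); training them requires a GPU
  deep-learning framework and is outside this package's runtime scope.

z-scoring is per-patch by default ("patch-level" normalization); a
`dataset` mode shares one mean/std across the stack.  Per-patch scoring
exactly removes any global amplitude scale, which is why the −6 dB output
power mismatch is largely invisible to the classifier after normalization
— the interesting mismatches for classification are the spectral ones.

## Scaled-down experiment defaults

The repeated experiment uses 100 training frames per class, 30 test frames
per class, a 10-repeat calibration stack, a 6000-patch training subsample,
and 5 repeats with fresh frame draws; the calibrator is built once per
experiment, as one stable acquisition would be.  The uncalibrated model is
shared by the benchmark, no-calibration and test-time conditions (they
differ only in the evaluation data), so each repeat trains two networks.
These sizes keep a full experiment around five minutes on one CPU while
leaving the statistical margins (pooled standard deviations across
repeats) far smaller than the effects being measured.

Observed behaviour at these conditions mirrors the full-scale study
qualitatively: the benchmark sits near 98–99 % accuracy, the uncalibrated
frequency-mismatch condition collapses to chance-level *accuracy* while
retaining high AUC (the class separation survives; the decision threshold
does not), and both calibrated conditions recover most of the gap.
Train-time calibration trails test-time calibration here: the Wiener
response zeroes out-of-band content, so calibrated training data lacks
the broadband noise present in real test frames, a mismatch the small
network partially keys on.  The full-scale study observed the same
ordering for some mismatches and the reverse for others.

## Numerical choices and degenerate inputs

- Frame samples are stored as float32 (calibration is linear; integer ADC
  counts only gain a scale); spectral accumulation is float64.
- Constant patches z-score to all zeros with a warning.
- `compute_gamma` on zero train power yields 0, never infinity.
- `wiener_regularize` is total: SNR = 0 bins produce exactly 0.
- FIR taps are symmetrized (`(t + t[::-1])/2`) to remove floating-point
  asymmetry before the linear-phase invariant is checked.
- All randomness flows through `numpy.random.SeedSequence` spawns of a
  single user seed; repeated experiments re-draw data but share the
  calibrator.

## Known limitations

- The transfer function is magnitude-only; any true phase difference
  between settings (e.g. different pulse shapes with non-minimal phase)
  is not corrected.
- Transfer is only possible where both settings carry signal: bands with
  SNR near zero at either setting are suppressed, not synthesized.  The
  round trip train-filter-then-test-filter is therefore intentionally
  lossy out of band.
- The frame-level calibration output uses nearest-gate banding between
  the nine depth filters; consumers needing exactness should use the
  patch-level path.
- The importer for vendor RF dumps handles flat binary only; proprietary
  formats need a reader added at the documented hook in the CLI.
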