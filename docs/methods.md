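# Methods

## The system being simulated

`fibrc` is a software model of a physical reservoir computer built from
Ag/MoS₂-quantum-dot/Ag fiber memristors. In physical reservoir computing a
fixed nonlinear dynamical system — here a volatile ("diffusive") memristor —
projects input pulse sequences into a high-dimensional space of analog
current responses; only a simple readout is trained. The simulator covers
the full chain: biosignal → feature matrix → pulse trains → device bank →
reservoir state vector → trained readout, plus conductance-quantized
inference and per-pulse energy accounting.

## Device model

The device is described by one internal state variable `w ∈ [w_min, w_max]`
(filament strength, dimensionless) and three rules:

- **Potentiation.** A pulse with amplitude `V ≥ v_set` moves the state a
  fixed fraction of the remaining headroom: `w ← w + a_write (w_max − w)`.
  The saturating form gives the sub-linear pulse-number response
  characteristic of diffusive devices.
- **Volatility (fading memory).** During idle time `Δt` the state relaxes
  exponentially toward baseline: `w ← w_min + (w − w_min) e^{−Δt/τ}`.
- **Readout.** The non-destructive read current is a power law between the
  OFF and ON currents,
  `I(w) = i_off + (i_on − i_off) ((w − w_min)/(w_max − w_min))^{p_nl}`,
  strictly increasing in `w`.

A pulse at or below `v_reset` ruptures the filament abruptly (`w ← w_min`);
gradual depression is not modeled. Bipolar threshold switching with
`v_set = +1 V`, `v_reset = −1 V` produces the pinched hysteresis loop in
`iv_sweep`. Cycle-to-cycle variability is a multiplicative log-normal
factor `e^{N(0, σ²)}` on each potentiation increment, seed-controlled and
off by default so the reference behaviour is reproducible.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| `a_write` | 0.3 | potentiation fraction per write pulse |
| `tau_decay` | 0.5 s | state relaxation constant (2 × the 0.25 s slot period) |
| `v_write` / `v_read` | 1.5 V / 1.0 V | write amplitude, read voltage |
| `v_set` / `v_reset` | +1.0 V / −1.0 V | switching thresholds |
| `i_off` / `i_on` | 10 pA / 0.5 nA | currents at `w=0` and `w=1` |
| `p_nl` | 2 | readout nonlinearity exponent |
| slot / gap | 200 ms / 50 ms | pulse duration and inter-pulse idle |
| `sigma_c2c` | 0 | cycle-to-cycle noise s.d. |

With these values the 16 binary 4-pulse programming frames map to 16
mutually distinct current levels whose minimum adjacent relative separation
is ≈3.5%, comfortably above the 1% margin used to declare two levels
distinguishable (a threshold far above double-precision noise and below
any realistic read resolution). Worst-case read power is
`v_read · i_on = 0.5 nW`, i.e. sub-nanowatt continuous operation.

Energy is accounted per pulse as `|V · I| · duration` with the current
taken from the state at pulse onset; since the state changes only at pulse
edges, this piecewise-constant product equals the dense-time integral of
`V(t)I(t)` (verified against a trapezoidal oracle in the tests).

## Encoders

- **EEG → MTF.** 30-s single-channel epochs (clinical convention) are
  quantile-binned into `n_bins = 8` amplitude states; the first-order
  Markov transition matrix `W` is estimated by counting; the full field
  `M[i,j] = W[q(x_i), q(x_j)]` is block-averaged to 64×64. Quantile
  binning makes the field invariant to monotone amplitude transforms, so
  only temporal correlation structure survives — exactly the property that
  separates slow delta-dominated deep sleep from fast wake activity. A
  constant epoch returns the uniform field `1/n_bins` with a warning.
- **Audio → MFCC.** Pre-emphasis (0.97), 25 ms Hann frames at 10 ms hop,
  magnitude FFT, 26 triangular HTK-scale mel filters, `log(E + 10⁻¹⁰)`,
  DCT-II (orthonormal), first 13 coefficients. Conventional
  speech-processing settings; with the fixed log floor, coefficients
  beyond c0 are gain-invariant.
- **Images → pulses.** Pixels above threshold become fixed 1.5 V / 200 ms
  write pulses, others zero-amplitude slots, row-major.

### Feature-to-pulse mapping

Three modes turn a feature row into pulse amplitudes:

- `binary`: per-row median threshold → 0 / `v_write` slots (images,
  and the mode used by the compression demo).
- `amplitude`: per-row min–max rescale into `[0, v_write]` (MFCC default —
  the within-row temporal modulation of each cepstral coefficient is the
  snore signature, and rescaling preserves it).
- `scaled`: absolute scaling `v_write · clip(value/ref, 0, 1)` with
  `ref = 1.6/n_bins` for MTFs. This is the MTF default, and the choice is
  deliberate: over a 30-s epoch the block-averaged field concentrates
  around the memoryless baseline `1/n_bins`, and its *absolute* contrast
  against that baseline is the stage signature. A per-row min–max rescale
  erases that contrast (it amplifies residual noise in near-uniform rows
  to full scale and drives the linear readout to chance). The `scaled`
  reference places the device write threshold `v_set/v_write · ref =
  (2/3)(1.6/n_bins) ≈ 1.07/n_bins` just above baseline, so devices fire
  where the transition probability persistently exceeds chance. The
  reference is tied to `n_bins` only — the MTF is scale-free, so the
  mapping does not depend on signal amplitudes.

## Reservoir

Each frame of `frame_k = 4` consecutive slots drives a device freshly
initialized at the common baseline; the current after the frame's last
slot (including its trailing decay) is one state component, ordered
row-major by (row, frame). Frame-wise fresh devices mirror a fixed bank of
16 programmable conductance states; within a frame the fading memory
weights later pulses more (position ordering is strict), and binary input
can reach at most 2⁴ current values. The implementation vectorizes the
per-pulse recurrence across frames and is verified against the scalar
single-device composition to 1e−12.

Multimodal fusion concatenates the EEG and audio state vectors (EEG
first) after per-modality z-normalization — the two encoders produce
different current statistics, and unnormalized concatenation would let one
modality dominate the readout. The original vectors are retained so the
fusion is losslessly invertible.

Image compression stores one current per 4-pixel frame (4:1 along
columns); decoding maps each current to the nearest of the 16 programmed
levels (ties toward the lower level) and expands its bit pattern. Because
the level map is injective with margin on the noiseless device, binary
images round-trip exactly.

## Readouts

- **Linear.** Multinomial softmax with L2 penalty on weights (bias free),
  on internally standardized features, minimized by full-batch L-BFGS to
  gradient tolerance 1e−9 — deterministic from zero initialization, and
  the analytic gradient is finite-difference checked in the tests.
- **CNN.** A deliberately tiny grid readout: conv 3×3×8 → ReLU → 2×2
  max-pool → conv 3×3×16 → ReLU → global average pool → dense softmax
  (≈1.3k parameters), trained by full-batch gradient descent with a fixed
  step (default 0.2, 300 epochs) from seeded He initialization; a
  mini-batch variant is available behind `batch_size`. Grids too small for
  the pooled double conv fall back to a single conv layer with a log
  message.
- **CAM.** For the linear model, the class-c activation map is the weight
  vector reshaped to the grid times the standardized state grid (so maps
  sum, plus bias, to the logits exactly). For the CNN, the standard
  global-average-pooling CAM — class-weighted sum of final conv maps,
  bilinearly upsampled.
- **Quantization.** Per-tensor symmetric uniform quantization to 16
  magnitude levels `k·max|w|/15`; the sign is carried separately, modeling
  a differential pair of non-negative physical conductances. Biases stay
  in the digital periphery. Per-weight error is bounded by half the level
  spacing; the accuracy change on a held-out set is recorded.

Train/validation splitting is stratified 80/20 and seed-controlled. All
randomness in a pipeline run flows from one global seed through named
substreams (`data`, `split`, `cnn`, …) derived via `SeedSequence`.

## Synthetic study conditions

No recordings are bundled; generators produce data with the statistical
structure the pipeline assumes:

- **EEG**: sums of band-limited Gaussian processes (delta/theta/alpha/
  beta + bursty 11–16 Hz spindles) with stage-dependent weights on a
  white-noise floor, ~±50 µV scale, 64 Hz, 30-s epochs. Weights follow
  the canonical picture (delta rising wake→deep, alpha/beta dominant in
  wake, spindles in light sleep) and are synthetic design constants.
- **Snore audio**: bursts at the ~0.25 Hz breathing rate, each a 90–180 Hz
  fundamental with 4 harmonics under a jittered AM envelope over low-level
  broadband breathing noise; 16 kHz, peak-normalized. Ambient mixes are
  pink-ish broadband "rain" or low-frequency "traffic" rumble with sparse
  transient passes, mixed at a requested full-clip SNR (±0.5 dB realized).
- **Nights**: a three-state (wake/light/deep; no REM) Markov chain over
  30-s epochs, snore events concentrated in light sleep and never in wake
  under the default plan; the default night is scaled to 10 minutes so
  tests remain desk-scale, with longer nights available by parameter.
- **Glyphs**: stroke bitmaps of "W", "G", "6" at 8×8 (replicated for
  larger sizes) with optional pixel-flip noise.

Classification datasets default to 60 windows per class (EEG epochs for
stage3, 2-s clips for snore2, paired windows for joint6).

What the generators do **not** emulate: real polysomnography artifacts
(electrode pops, movement, EMG bleed), inter-subject and inter-rater
variability, REM sleep, apnea events, or realistic room acoustics. Passing
tests therefore demonstrate that the pipeline is information-preserving
and learnable under its stated assumptions — not clinical-grade accuracy
on real recordings.

## Numerical choices and degenerate inputs

- Level distinguishability margin: 1% relative separation between adjacent
  sorted currents.
- Decode ties break toward the lower level (deterministic).
- Constant EEG epochs → uniform MTF with a warning; all-equal feature rows
  in amplitude mode → all-zero amplitudes; empty pulse rows are skipped
  with a warning; zero-variance features are left unscaled by the
  standardizer.
- PCA is computed by eigendecomposition of the covariance with the sign of
  each component fixed so its largest-magnitude loading is positive;
  cross-checked against an SVD oracle to 1e−8.
- Epoch intervals are half-open `[start, end)` seconds from stream start.

## Known limitations

- The device model is phenomenological: no electrochemical filament
  physics, temperature effects, crossbar parasitics, or device-to-device
  mismatch beyond the scalar cycle-to-cycle noise.
- Gradual RESET (depression) is not modeled; the reservoir only exercises
  the potentiation/decay regime.
- The CNN readout is intentionally small and trained full-batch; it is a
  demonstration of grid-structured readout, not a tuned architecture.
- The 16-level bit-pattern→current assignment is a property of the model
  defaults, not a published calibration table.
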