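# fibrc — fiber-memristor reservoir computing for sleep monitoring

`fibrc` is a desk-scale software simulator of a physical reservoir
computing system built from Ag/MoS₂-quantum-dot/Ag fiber memristors, aimed
at multimodal sleep monitoring. It is written for researchers in
neuromorphic computing and biomedical signal processing who want to study
this class of system — its temporal pulse encoding, multilevel conductance
programming, fading-memory dynamics, readout training and energy budget —
without fabricated devices or clinical recordings.

The pipeline mirrors the physical system end to end:

1. **Encode.** EEG epochs become Markov transition field (MTF) images
   (quantile binning → transition counting → full field → block
   averaging); snore audio becomes mel-frequency cepstral coefficient
   (MFCC) matrices; binary images map directly to fixed-voltage pulses
   (1.5 V, 200 ms per above-threshold pixel).
2. **Reserve.** Feature rows become pulse trains that drive banks of
   virtual memristors. Each device obeys a volatile phenomenological
   model — saturating potentiation `w ← w + a(w_max − w)` above the +1 V
   SET threshold, exponential state decay `e^{−Δt/τ}` while idle, abrupt
   RESET at −1 V, and a power-law read current
   `I(w) = i_off + (i_on − i_off)·w^p` at sub-nanoampere scale. Every
   4-pulse frame programs a fresh device from a common baseline, so binary
   input exercises a fixed bank of 16 programmable conductance levels; the
   read currents form the high-dimensional reservoir state.
3. **Read out.** A ridge-penalized softmax layer or a tiny CNN
   (< 5k parameters) is trained on the state vectors; trained weights can
   be quantized onto 16 discrete conductance magnitudes (differential-pair
   sign convention) to model inference mapped back onto the device array.
   Class activation maps, PCA projections, confusion matrices, hypnogram
   timelines and per-pulse energy reports round out the analysis.

Because no recordings are distributed, the `synth` module generates the
study conditions: stage-dependent EEG spectra (wake/light/deep), snore
bursts with rain/traffic ambience, Markov-chain night timelines, and glyph
images. See `docs/methods.md` for the model, defaults, and limitations.

## Worked example

Program the sixteen 4-bit frames and read the resulting current levels:

```python
from fibrc.device import DeviceParams, program_levels

levels = program_levels(DeviceParams())
for k in ("0000", "1000", "0001", "1111"):
    print(k, f"{levels[k]*1e12:.2f} pA")
```

```
0000 10.00 pA
1000 29.82 pA
0001 46.11 pA
1111 199.12 pA
```

The empty frame reads the 10 pA OFF current; a single write pulse read
later in the frame (`0001`) leaves more current than the same pulse four
slots earlier (`1000`) because the state decays during the idle slots —
the fading memory that makes the device a reservoir. All 16 frames land on
distinct levels (minimum adjacent separation ≈3.5%), which is what makes
the 4:1 image compression demo losslessly invertible.

Full pipeline runs from the command line:

```bash
$ fibrc run --task snore2 --seed 7 --out out_snore
task=snore2 accuracy=1.000 readout=linear

$ fibrc run --task image_demo --seed 1 --out out_img
task=image_demo accuracy=1.000 readout=-

$ fibrc energy --seed 7
{
  "energy_j": 1.397390273590714e-08,
  "n_frames": 1024,
  "mean_power_w": 1.3646389390534316e-11,
  "read_power_w": 5e-10,
  "read_power_exceeds_1nw": false
}
```

The snore run generates 120 labeled synthetic clips, encodes them as
MFCCs, drives the reservoir, trains the linear readout on a stratified
80/20 split and reports held-out accuracy (1.000 here); `out_snore/`
receives the report JSON, confusion CSV, CAM heatmap and a reproducibility
manifest. The energy report integrates every pulse of one encoded EEG
window (1024 device frames): ~14 nJ per inference at ~14 pW mean drive
power, with worst-case continuous read power 0.5 nW — below the 1 nW
flag threshold. `fibrc run --task stage3` trains the 3-class sleep-stage
task the same way (94.4% held-out accuracy with the linear readout at
seed 7; the CNN readout reaches 100%), and `--task joint6` fuses both
modalities.

Other commands: `fibrc gen-data` (synthetic night → CSV/WAV/PGM),
`fibrc encode` (files → feature CSVs), `fibrc device-iv` (pinched
hysteresis sweep → CSV), `fibrc eval` (metrics from label CSVs).
Exit codes: 0 success, 2 configuration error, 3 data error.

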