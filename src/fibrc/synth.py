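"""Synthetic signal generators for the sleep-monitoring pipeline.

Real overnight recordings are not bundled; these generators produce inputs
with the statistical structure the pipeline assumes — stage-dependent EEG
spectra (wake / light / deep), snore-event audio with environmental rain or
traffic noise, Markov-chain hypnogram timelines, and binary glyph images —
so every stage of the system runs and is testable offline. All generators
are pure functions of (parameters, seed).

The spectral weights below are synthetic design constants chosen to mimic
the canonical sleep-EEG picture (delta power rising monotonically from wake
to deep sleep, alpha/beta dominant in wake, spindle-band bursts in light
sleep); they are not fitted to any recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .encoders import AudioClip, EEGEpoch

__all__ = [
    "StageSpec",
    "NightPlan",
    "NightData",
    "STAGES",
    "gen_eeg_epoch",
    "gen_snore_clip",
    "add_ambient",
    "gen_night",
    "sample_stage_sequence",
    "gen_glyphs",
    "make_stage3_dataset",
    "make_snore2_dataset",
    "make_joint6_dataset",
]

STAGES = ("wake", "light", "deep")

BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
         "beta": (13.0, 30.0), "spindle": (11.0, 16.0)}


@dataclass(frozen=True)
class StageSpec:
    """Per-stage EEG band-power weights (relative amplitudes).

    Each weight is the standard deviation of that band's component in
    units of ``unit_uv`` microvolts; ``noise_floor`` sets the white-noise
    component the same way. The spindle band is rendered as bursts rather
    than a stationary process.
    """

    weights: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "wake": {"delta": 0.5, "theta": 0.7, "alpha": 1.5,
                 "beta": 1.2, "spindle": 0.0},
        "light": {"delta": 1.5, "theta": 1.5, "alpha": 0.7,
                  "beta": 0.4, "spindle": 1.0},
        "deep": {"delta": 3.5, "theta": 1.0, "alpha": 0.3,
                 "beta": 0.2, "spindle": 0.2},
    })
    noise_floor: float = 0.5
    unit_uv: float = 5.0

    def __post_init__(self) -> None:
        for stage, w in self.weights.items():
            if any(v < 0 for v in w.values()):
                raise ValueError(f"negative band weight for stage {stage}")


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", fs=fs,
                              output="sos")
    x = scipy.signal.sosfiltfilt(sos, rng.standard_normal(n + int(4 * fs)))
    x = x[int(2 * fs):int(2 * fs) + n]
    s = x.std()
    return x / s if s > 0 else x


def gen_eeg_epoch(stage: str, fs: float = 64.0, epoch_s: float = 30.0,
                  spec: StageSpec | None = None, seed: int = 0) -> EEGEpoch:
    """One synthetic single-channel EEG epoch for a sleep stage.

    Sum of band-limited Gaussian processes with stage-weighted amplitudes
    plus a white-noise floor; the spindle band is amplitude-modulated into
    ~1 s bursts. Amplitudes land around +/-50 microvolts for the default
    deep-sleep weights. Deterministic per seed.
    """
    if fs < 64:
        raise ValueError("EEG sampling rate must be >= 64 Hz")
    spec = spec or StageSpec()
    if stage not in spec.weights:
        raise ValueError(f"unknown stage {stage!r}")
    rng = np.random.default_rng(seed)
    n = int(round(fs * epoch_s))
    w = spec.weights[stage]
    x = spec.noise_floor * spec.unit_uv * rng.standard_normal(n)
    for band, amp in w.items():
        if amp == 0:
            continue
        comp = _band_noise(n, fs, BANDS[band], rng) * amp * spec.unit_uv
        if band == "spindle":
            comp = comp * _burst_envelope(n, fs, rng, rate_hz=0.2,
                                          burst_s=1.0)
        x += comp
    return EEGEpoch(x, fs=fs, stage_label=stage)


def _burst_envelope(n: int, fs: float, rng: np.random.Generator,
                    rate_hz: float, burst_s: float) -> np.ndarray:
    env = np.zeros(n)
    t = rng.exponential(1.0 / rate_hz)
    blen = int(burst_s * fs)
    win = np.hanning(max(blen, 2))
    while t * fs < n:
        i0 = int(t * fs)
        seg = win[:max(0, min(blen, n - i0))]
        env[i0:i0 + seg.size] += seg
        t += rng.exponential(1.0 / rate_hz) + burst_s
    return env


def gen_snore_clip(duration_s: float = 2.0, fs: int = 16000,
                   snore: bool = True, seed: int = 0) -> AudioClip:
    """Synthetic snore (or quiet breathing) audio clip.

    Snore: a burst train at the breathing rate (~0.25 Hz); each burst is a
    90-180 Hz fundamental with 4 harmonics under a jittered AM envelope.
    No snore: low-level broadband breathing noise. Peak-normalized into
    [-1, 1]. Deterministic per seed.
    """
    if fs < 8000:
        raise ValueError("audio sampling rate must be >= 8000 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    sos = scipy.signal.butter(4, [300, min(3000, 0.45 * fs)],
                              btype="bandpass", fs=fs, output="sos")
    breath = scipy.signal.sosfiltfilt(sos, rng.standard_normal(n))
    breath /= max(np.abs(breath).max(), 1e-12)
    if not snore:
        return AudioClip(0.1 * breath, fs=fs, snore_label=False)
    x = 0.05 * breath
    period = 4.0                                # 0.25 Hz breathing rate
    burst_s = 0.9
    onset = 0.3 + 0.1 * rng.random()
    while onset + burst_s < duration_s + burst_s:
        f0 = rng.uniform(90.0, 180.0)
        i0 = int(onset * fs)
        m = min(int(burst_s * fs), n - i0)
        if m <= 0:
            break
        tb = t[:m]
        tone = sum((1.0 / (h + 1)) * np.sin(2 * np.pi * f0 * (h + 1) * tb
                                            + rng.uniform(0, 2 * np.pi))
                   for h in range(5))
        env = np.hanning(m) * (1.0 + 0.2 * rng.standard_normal())
        x[i0:i0 + m] += np.abs(env) * tone
        onset += period + rng.normal(0.0, 0.15)
    peak = np.abs(x).max()
    if peak > 0:
        x = 0.9 * x / peak
    return AudioClip(x, fs=fs, snore_label=True)


def _ambient_noise(kind: str, n: int, fs: int,
                   rng: np.random.Generator) -> np.ndarray:
    if kind == "rain":
        # pink-ish broadband: 1/f amplitude shaping in the frequency domain
        spec = np.fft.rfft(rng.standard_normal(n))
        f = np.fft.rfftfreq(n, 1 / fs)
        f[0] = f[1]
        return np.fft.irfft(spec / np.sqrt(f), n=n)
    if kind == "traffic":
        sos = scipy.signal.butter(4, 150, btype="lowpass", fs=fs,
                                  output="sos")
        rumble = scipy.signal.sosfiltfilt(sos, rng.standard_normal(n))
        x = rumble / max(rumble.std(), 1e-12)
        # sparse vehicle passes: short band-limited swells
        for _ in range(max(1, int(n / fs / 5))):
            i0 = rng.integers(0, max(1, n - fs))
            m = min(int(0.8 * fs), n - i0)
            sos2 = scipy.signal.butter(2, [80, 400], btype="bandpass",
                                       fs=fs, output="sos")
            burst = scipy.signal.sosfiltfilt(sos2, rng.standard_normal(m))
            x[i0:i0 + m] += 2.0 * np.hanning(m) * burst / max(
                burst.std(), 1e-12)
        return x
    raise ValueError(f"unknown ambient kind {kind!r}")


def add_ambient(clip: AudioClip, kind: str, snr_db: float,
                seed: int = 0) -> AudioClip:
    """Mix environmental noise into a clip at a requested SNR.

    ``rain`` is pink-ish broadband noise; ``traffic`` is low-frequency
    rumble with sparse transient passes. The noise is scaled so the
    signal-to-noise power ratio over the full clip equals ``snr_db``; the
    mix is then peak-renormalized (which preserves the SNR). ``kind='none'``
    or an infinite SNR returns the clip unchanged.
    """
    if kind in (None, "none") or np.isinf(snr_db):
        return clip
    rng = np.random.default_rng(seed)
    x = clip.samples
    noise = _ambient_noise(kind, x.size, clip.fs, rng)
    p_sig = float(np.mean(x ** 2))
    p_noise = float(np.mean(noise ** 2))
    if p_sig == 0 or p_noise == 0:
        return clip
    noise = noise * np.sqrt(p_sig / (p_noise * 10 ** (snr_db / 10)))
    y = x + noise
    peak = np.abs(y).max()
    if peak > 1.0:
        y = y / peak
    return AudioClip(y, fs=clip.fs, snore_label=clip.snore_label)


# ---------------------------------------------------------------------------
# Night plans and streams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NightPlan:
    """Plan for one synthetic night: stage dynamics and snore schedule.

    Stages follow a first-order Markov chain over (wake, light, deep);
    snore events are scheduled per epoch with stage-dependent probability
    (never in wake by default, concentrated in light sleep). The default
    night is scaled to 10 minutes of stream at 30-s epochs — long nights
    are available by raising ``n_epochs``.
    """

    epoch_s: float = 30.0
    n_epochs: int = 20
    transition: tuple[tuple[float, ...], ...] = (
        (0.60, 0.40, 0.00),
        (0.10, 0.65, 0.25),
        (0.00, 0.30, 0.70),
    )
    initial: tuple[float, ...] = (1.0, 0.0, 0.0)
    snore_prob: tuple[float, ...] = (0.0, 0.6, 0.15)   # per stage
    ambient: str = "none"
    snr_db: float = 10.0
    eeg_fs: float = 64.0
    audio_fs: int = 16000
    seed: int = 0

    def __post_init__(self) -> None:
        for row in self.transition:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError("transition matrix rows must sum to 1")
        if abs(sum(self.initial) - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")


def sample_stage_sequence(plan: NightPlan, n_epochs: int | None = None,
                          rng: np.random.Generator | None = None
                          ) -> np.ndarray:
    """Sample the per-epoch stage index sequence of a plan's Markov chain."""
    rng = rng or np.random.default_rng(plan.seed)
    n = n_epochs if n_epochs is not None else plan.n_epochs
    P = np.asarray(plan.transition)
    out = np.empty(n, dtype=int)
    out[0] = rng.choice(3, p=np.asarray(plan.initial))
    for i in range(1, n):
        out[i] = rng.choice(3, p=P[out[i - 1]])
    return out


@dataclass
class NightData:
    """Epoch-aligned synthetic night: EEG stream, audio stream, labels."""

    eeg: np.ndarray
    eeg_fs: float
    audio: np.ndarray
    audio_fs: int
    labels: pd.DataFrame          # epoch,start_s,stage,snore
    plan: NightPlan

    def eeg_epoch(self, i: int) -> EEGEpoch:
        n = int(self.plan.epoch_s * self.eeg_fs)
        return EEGEpoch(self.eeg[i * n:(i + 1) * n], fs=self.eeg_fs,
                        stage_label=self.labels.stage.iloc[i])

    def audio_epoch(self, i: int) -> AudioClip:
        n = int(self.plan.epoch_s * self.audio_fs)
        return AudioClip(self.audio[i * n:(i + 1) * n], fs=self.audio_fs,
                         snore_label=bool(self.labels.snore.iloc[i]))


def gen_night(plan: NightPlan, spec: StageSpec | None = None) -> NightData:
    """Generate one epoch-aligned synthetic night from a plan.

    EEG and audio streams are concatenations of per-epoch generations;
    ambient noise (if any) is mixed into each epoch's audio at the plan's
    SNR. Deterministic per the plan's seed.
    """
    rng = np.random.default_rng(plan.seed)
    stages = sample_stage_sequence(plan, rng=rng)
    snore_p = np.asarray(plan.snore_prob)
    snores = rng.random(plan.n_epochs) < snore_p[stages]
    eeg_parts, audio_parts, rows = [], [], []
    for i, (s, sn) in enumerate(zip(stages, snores)):
        e_seed, a_seed, amb_seed = rng.integers(0, 2 ** 31, size=3)
        ep = gen_eeg_epoch(STAGES[s], plan.eeg_fs, plan.epoch_s, spec,
                           seed=int(e_seed))
        clip = gen_snore_clip(plan.epoch_s, plan.audio_fs, bool(sn),
                              seed=int(a_seed))
        if plan.ambient != "none":
            clip = add_ambient(clip, plan.ambient, plan.snr_db,
                               seed=int(amb_seed))
        eeg_parts.append(ep.samples)
        audio_parts.append(clip.samples.astype(np.float32))
        rows.append({"epoch": i, "start_s": i * plan.epoch_s,
                     "stage": STAGES[s], "snore": int(sn)})
    return NightData(np.concatenate(eeg_parts), plan.eeg_fs,
                     np.concatenate(audio_parts), plan.audio_fs,
                     pd.DataFrame(rows), plan)


# ---------------------------------------------------------------------------
# Glyph images
# ---------------------------------------------------------------------------

_GLYPHS_8x8 = {
    "W": ["10000001",
          "10000001",
          "10000001",
          "10011001",
          "10100101",
          "10100101",
          "11000011",
          "10000001"],
    "G": ["01111110",
          "11000011",
          "10000000",
          "10000000",
          "10001111",
          "10000011",
          "11000011",
          "01111110"],
    "6": ["00111100",
          "01100110",
          "11000000",
          "11111100",
          "11000110",
          "11000011",
          "01100110",
          "00111100"],
}


def gen_glyphs(symbols=("W", "G", "6"), size: int = 8, seed: int = 0,
               flip_p: float = 0.0) -> dict[str, np.ndarray]:
    """Binary glyph images for the image-compression demonstration.

    Stroke bitmaps are defined at 8x8 and scaled up by pixel replication
    for larger sizes; ``flip_p`` applies independent pixel-flip noise.
    With zero noise the output is seed-independent.
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    rng = np.random.default_rng(seed)
    out = {}
    for sym in symbols:
        if sym not in _GLYPHS_8x8:
            raise ValueError(f"no glyph defined for {sym!r}")
        base = np.array([[int(c) for c in row] for row in _GLYPHS_8x8[sym]],
                        dtype=np.int8)
        rep = size // 8
        img = np.kron(base, np.ones((rep, rep), dtype=np.int8))
        if img.shape[0] < size:
            pad = size - img.shape[0]
            img = np.pad(img, ((0, pad), (0, pad)))
        if flip_p > 0:
            flips = rng.random(img.shape) < flip_p
            img = np.where(flips, 1 - img, img).astype(np.int8)
        out[sym] = img
    return out


# ---------------------------------------------------------------------------
# Labeled task datasets
# ---------------------------------------------------------------------------

def make_stage3_dataset(n_per_class: int = 60, fs: float = 64.0,
                        epoch_s: float = 30.0, spec: StageSpec | None = None,
                        seed: int = 0) -> tuple[list[EEGEpoch], np.ndarray]:
    """Labeled EEG epochs for the 3-class sleep-stage task."""
    rng = np.random.default_rng(seed)
    epochs, labels = [], []
    for c, stage in enumerate(STAGES):
        for _ in range(n_per_class):
            epochs.append(gen_eeg_epoch(stage, fs, epoch_s, spec,
                                        seed=int(rng.integers(0, 2 ** 31))))
            labels.append(c)
    return epochs, np.array(labels)


def make_snore2_dataset(n_per_class: int = 60, duration_s: float = 2.0,
                        fs: int = 16000, ambient: str = "none",
                        snr_db: float = 10.0, seed: int = 0
                        ) -> tuple[list[AudioClip], np.ndarray]:
    """Labeled audio clips for the binary snore-detection task."""
    rng = np.random.default_rng(seed)
    clips, labels = [], []
    for c, snore in enumerate((False, True)):
        for _ in range(n_per_class):
            clip = gen_snore_clip(duration_s, fs, snore,
                                  seed=int(rng.integers(0, 2 ** 31)))
            if ambient != "none":
                clip = add_ambient(clip, ambient, snr_db,
                                   seed=int(rng.integers(0, 2 ** 31)))
            clips.append(clip)
            labels.append(c)
    return clips, np.array(labels)


def make_joint6_dataset(n_per_class: int = 20, fs_eeg: float = 64.0,
                        epoch_s: float = 30.0, duration_s: float = 2.0,
                        fs_audio: int = 16000, ambient: str = "none",
                        snr_db: float = 10.0, seed: int = 0
                        ) -> tuple[list[tuple[EEGEpoch, AudioClip]],
                                   np.ndarray]:
    """Paired (EEG, audio) windows for the joint stage x snore task.

    Class index = 2 * stage_index + snore_flag.
    """
    rng = np.random.default_rng(seed)
    pairs, labels = [], []
    for s, stage in enumerate(STAGES):
        for snore in (False, True):
            for _ in range(n_per_class):
                ep = gen_eeg_epoch(stage, fs_eeg, epoch_s,
                                   seed=int(rng.integers(0, 2 ** 31)))
                clip = gen_snore_clip(duration_s, fs_audio, snore,
                                      seed=int(rng.integers(0, 2 ** 31)))
                if ambient != "none":
                    clip = add_ambient(clip, ambient, snr_db,
                                       seed=int(rng.integers(0, 2 ** 31)))
                pairs.append((ep, clip))
                labels.append(2 * s + int(snore))
    return pairs, np.array(labels)
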