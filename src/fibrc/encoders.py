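"""Signal encoders: MTF for EEG, MFCC for audio, threshold pulse maps for
images, and the mapping from feature matrices to per-row pulse trains.

EEG epochs become Markov transition field (MTF) images: the series is
quantile-binned, the first-order bin-to-bin transition matrix is estimated
by counting, and the full field ``M[i, j] = W[q(x_i), q(x_j)]`` is block-
averaged down to a fixed output size. Snore audio becomes mel-frequency
cepstral coefficient (MFCC) matrices through the conventional
pre-emphasis / Hann / mel filterbank / log / DCT-II chain. Binary images map
directly to fixed-voltage pulse trains (1.5 V, 200 ms per above-threshold
pixel).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.fft
import scipy.signal

from .device import Pulse, PulseTrain

__all__ = [
    "EEGEpoch",
    "AudioClip",
    "FeatureMatrix",
    "mtf_transform",
    "mfcc_transform",
    "mel_filterbank",
    "image_to_pulsemap",
    "matrix_to_pulserows",
    "read_eeg_csv",
    "write_eeg_csv",
    "read_wav",
    "write_wav",
    "read_image",
    "read_edf",
]

logger = logging.getLogger(__name__)

# image-to-pulse constants: fixed-voltage pulse per above-threshold pixel
IMAGE_PULSE_V = 1.5
IMAGE_PULSE_S = 0.2
DEFAULT_SLOT_GAP = 0.05


@dataclass
class EEGEpoch:
    """One single-channel EEG epoch in microvolts."""

    samples: np.ndarray
    fs: float
    stage_label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEG samples must be finite")


@dataclass
class AudioClip:
    """Mono audio clip with samples in [-1, 1]."""

    samples: np.ndarray
    fs: int
    snore_label: bool | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio samples must be finite")
        if self.fs < 8000:
            raise ValueError("audio sampling rate must be >= 8000 Hz")


@dataclass
class FeatureMatrix:
    """2-D encoded representation of one signal epoch."""

    values: np.ndarray
    kind: Literal["MTF", "MFCC", "IMAGE"]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaN")
        if self.kind == "MTF" and (
                self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("MTF entries must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_csv(self, path) -> None:
        """Write as CSV with a leading '#' metadata header line."""
        with open(path, "w") as fh:
            meta = ",".join(f"{k}={v}" for k, v in sorted(self.meta.items()))
            fh.write(f"# kind={self.kind},{meta}\n")
            np.savetxt(fh, self.values, delimiter=",")


# ---------------------------------------------------------------------------
# Markov transition fields
# ---------------------------------------------------------------------------

def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each sample to a quantile bin in {0, ..., n_bins-1}."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="left")


def markov_transition_matrix(samples: np.ndarray, n_bins: int
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-bin a series and estimate its transition matrix.

    Returns ``(W, q)``: the row-normalized first-order transition matrix
    and the per-sample bin assignment. Rows with no observed transitions
    fall back to the uniform distribution.
    """
    x = np.asarray(samples, dtype=float)
    q = _quantile_bins(x, n_bins)
    counts = np.zeros((n_bins, n_bins))
    np.add.at(counts, (q[:-1], q[1:]), 1.0)
    row = counts.sum(axis=1, keepdims=True)
    w = np.where(row > 0, counts / np.where(row == 0, 1, row), 1.0 / n_bins)
    return w, q


def _block_average(m: np.ndarray, out_size: int) -> np.ndarray:
    """Downsample a square matrix to out_size x out_size by block means."""
    n = m.shape[0]
    if n <= out_size:
        return m
    edges = np.linspace(0, n, out_size + 1).astype(int)
    summed = np.add.reduceat(np.add.reduceat(m, edges[:-1], axis=0),
                             edges[:-1], axis=1)
    counts = np.diff(edges)
    return summed / np.outer(counts, counts)


def mtf_transform(epoch: EEGEpoch, n_bins: int = 8,
                  out_size: int = 64) -> FeatureMatrix:
    """Markov transition field of an EEG epoch.

    Quantile-bins the series into ``n_bins`` states, estimates the
    first-order transition matrix ``W`` by transition counting with row
    normalization, builds the full field ``M[i, j] = W[q(x_i), q(x_j)]``,
    and block-averages it to ``out_size`` x ``out_size``. Entries lie in
    [0, 1]. Quantile binning makes the result invariant under strictly
    monotone transformations of the series.

    A constant series occupies a single bin and has no estimable
    transitions; the uniform matrix (all entries ``1/n_bins``) is returned
    with a warning.
    """
    x = epoch.samples
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if x.size < max(n_bins, 2):
        raise ValueError("epoch too short for the requested bin count")
    if np.ptp(x) == 0:
        warnings.warn("constant series: returning the uniform MTF")
        m = np.full((out_size, out_size), 1.0 / n_bins)
        return FeatureMatrix(m, "MTF", {"n_bins": n_bins, "degenerate": True})
    w, q = markov_transition_matrix(x, n_bins)
    m_full = w[np.ix_(q, q)]
    m = _block_average(m_full, out_size)
    meta = {"n_bins": n_bins, "fs": epoch.fs, "stage": epoch.stage_label}
    return FeatureMatrix(m, "MTF", meta)


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, fs: float,
                   f_min: float = 0.0, f_max: float | None = None
                   ) -> np.ndarray:
    """Triangular mel filterbank (HTK mel scale), shape (n_mels, n_fft//2+1)."""
    if f_max is None:
        f_max = fs / 2.0
    if f_max > fs / 2.0:
        raise ValueError("filterbank upper edge exceeds Nyquist")
    mel_pts = np.linspace(_hz_to_mel(f_min), _hz_to_mel(f_max), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    fb = np.zeros((n_mels, freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (freqs - lo) / (ctr - lo)
        down = (hi - freqs) / (hi - ctr)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mfcc_transform(clip: AudioClip, n_mfcc: int = 13,
                   frame_len: float = 0.025, hop: float = 0.010,
                   n_mels: int = 26, pre_emphasis: float = 0.97,
                   log_floor: float = 1e-10) -> FeatureMatrix:
    """MFCC matrix (n_mfcc x n_frames) of an audio clip.

    Per frame: pre-emphasis, Hann window, magnitude spectrum, triangular
    mel filterbank on the HTK mel scale, log with an additive floor, then
    DCT-II keeping the first ``n_mfcc`` coefficients. With a fixed log
    floor, coefficients beyond c0 are gain-independent for signals well
    above the floor.
    """
    x = clip.samples
    frame_n = int(round(frame_len * clip.fs))
    hop_n = int(round(hop * clip.fs))
    if x.size < frame_n:
        raise ValueError("clip too short for one analysis frame")
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - pre_emphasis * x[:-1]
    n_frames = (x.size - frame_n) // hop_n + 1
    idx = (np.arange(frame_n)[None, :]
           + hop_n * np.arange(n_frames)[:, None])
    frames = y[idx] * scipy.signal.get_window("hann", frame_n, fftbins=True)
    n_fft = 1 << (frame_n - 1).bit_length()
    spec = np.abs(np.fft.rfft(frames, n=n_fft, axis=1))
    fb = mel_filterbank(n_mels, n_fft, clip.fs)
    mel_energy = spec @ fb.T
    log_mel = np.log(mel_energy + log_floor)
    cepstra = scipy.fft.dct(log_mel, type=2, axis=1, norm="ortho")[:, :n_mfcc]
    meta = {"fs": clip.fs, "frame_len": frame_len, "hop": hop,
            "n_mels": n_mels, "snore": clip.snore_label}
    return FeatureMatrix(cepstra.T, "MFCC", meta)


# ---------------------------------------------------------------------------
# Images -> pulses, feature matrices -> pulse rows
# ---------------------------------------------------------------------------

def image_to_pulsemap(image: np.ndarray, threshold: float = 0.5
                      ) -> tuple[np.ndarray, list[PulseTrain]]:
    """Encode an image into per-row fixed-voltage pulse trains.

    Each pixel with intensity above ``threshold`` becomes a write pulse
    (1.5 V, 200 ms); pixels at or below threshold become zero-amplitude
    slots of equal duration. Row-major order is preserved. Returns the
    binary map and one PulseTrain per image row.
    """
    img = np.atleast_2d(np.asarray(image, dtype=float))
    if img.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image intensities must be finite")
    binary = (img > threshold).astype(np.int8)
    rows = []
    for r in binary:
        rows.append(PulseTrain(
            Pulse(IMAGE_PULSE_V if b else 0.0, IMAGE_PULSE_S,
                  DEFAULT_SLOT_GAP)
            for b in r))
    return binary, rows


def matrix_to_pulserows(fm: FeatureMatrix,
                        mode: Literal["binary", "amplitude",
                                      "scaled"] = "amplitude",
                        frame_k: int = 4,
                        v_write: float = 1.5,
                        slot_duration: float = 0.2,
                        slot_gap: float = 0.05,
                        ref: float | None = None) -> list[PulseTrain]:
    """Turn a feature matrix into per-row pulse trains for the reservoir.

    binary mode: each row is thresholded at its median into 0/1 slots
    (write pulse at ``v_write`` / zero slot). amplitude mode: each row is
    min-max rescaled into [0, v_write] and the values become pulse
    amplitudes directly; an all-equal row yields all-zero amplitudes.
    scaled mode: absolute scaling ``v_write * clip(value / ref, 0, 1)`` —
    the feature values keep their matrix-wide meaning instead of being
    renormalized per row. For MTF matrices the default reference is
    ``1.6 / n_bins``, which places the device write threshold just above
    the memoryless-baseline field value ``1/n_bins``: devices fire where
    the transition probability persistently exceeds chance, so the field's
    absolute contrast (the stage signature) survives the pulse mapping.
    Rows are padded with zero slots to a multiple of ``frame_k``.
    """
    vals = fm.values
    n_cols = vals.shape[1]
    n_pad = (-n_cols) % frame_k
    if mode == "scaled" and ref is None:
        n_bins = fm.meta.get("n_bins")
        if fm.kind == "MTF" and n_bins:
            ref = 1.6 / n_bins
        else:
            ref = float(np.abs(vals).max()) or 1.0
    trains = []
    for row in vals:
        if mode == "binary":
            amps = np.where(row > np.median(row), v_write, 0.0)
        elif mode == "amplitude":
            lo, hi = row.min(), row.max()
            if hi == lo:
                amps = np.zeros_like(row)
            else:
                amps = (row - lo) / (hi - lo) * v_write
        elif mode == "scaled":
            amps = v_write * np.clip(row / ref, 0.0, 1.0)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        amps = np.concatenate([amps, np.zeros(n_pad)])
        trains.append(PulseTrain(
            Pulse(float(a), slot_duration, slot_gap) for a in amps))
    return trains


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_eeg_csv(path, fs: float | None = None,
                 stage_label: str | None = None) -> EEGEpoch:
    """Read an EEG epoch from a ``time_s,uv`` CSV."""
    df = pd.read_csv(path)
    if not {"time_s", "uv"} <= set(df.columns):
        raise ValueError("EEG CSV must have columns time_s,uv")
    t = df["time_s"].to_numpy()
    if fs is None:
        dt = np.diff(t)
        if t.size < 2 or not np.allclose(dt, dt[0]):
            raise ValueError("cannot infer sampling rate from time column")
        fs = 1.0 / dt[0]
    return EEGEpoch(df["uv"].to_numpy(), fs=fs, stage_label=stage_label)


def write_eeg_csv(path, epoch: EEGEpoch) -> None:
    t = np.arange(epoch.samples.size) / epoch.fs
    pd.DataFrame({"time_s": t, "uv": epoch.samples}).to_csv(path, index=False)


def read_wav(path, snore_label: bool | None = None) -> AudioClip:
    """Read a 16-bit PCM mono WAV into a [-1, 1] float clip."""
    import scipy.io.wavfile
    fs, data = scipy.io.wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    else:
        x = np.asarray(data, dtype=float)
    return AudioClip(x, fs=int(fs), snore_label=snore_label)


def write_wav(path, clip: AudioClip) -> None:
    import scipy.io.wavfile
    x = np.clip(clip.samples, -1.0, 1.0)
    scipy.io.wavfile.write(path, int(clip.fs),
                           (x * 32767).astype(np.int16))


def read_image(path) -> np.ndarray:
    """Read a PGM (P2/P5) or PNG image as a float array in [0, 1]."""
    import imageio.v3 as iio
    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1:
        img = img / 255.0
    return img


def read_edf(path, channel: int = 0, epoch_s: float = 30.0
             ) -> list[EEGEpoch]:
    """Read one channel of an EDF recording into 30-s epochs (needs mne)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("EDF reading requires the optional 'mne' package") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()[channel] * 1e6  # volts -> microvolts
    n = int(epoch_s * fs)
    return [EEGEpoch(data[i:i + n], fs=fs)
            for i in range(0, data.size - n + 1, n)]
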