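"""Virtual device banks: drive encoded pulse rows through memristor frames,
collect current readouts into state vectors, fuse modalities, and run the
image-compression demonstration.

Each frame of ``frame_k`` consecutive slots drives one device freshly
initialized at the common baseline; the current read after the frame's last
slot becomes one component of the reservoir state vector. In binary mode a
frame can therefore take at most ``2**frame_k`` current values — the fixed
bank of 16 programmable conductance levels for the default ``frame_k = 4``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .device import (DeviceParams, DeviceState, PulseTrain, program_levels,
                     read_current)
from .encoders import FeatureMatrix, image_to_pulsemap

__all__ = [
    "ReservoirConfig",
    "ReservoirStateVector",
    "run_reservoir",
    "encode_matrix",
    "fuse_modalities",
    "unfuse",
    "compress_image",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReservoirConfig:
    """Configuration of the virtual reservoir.

    ``frame_k`` pulses are grouped per device frame (default 4, giving the
    16-level bank); ``slot_duration``/``slot_gap`` set the pulse timing,
    and ``mode`` selects how feature rows become pulse amplitudes.
    """

    frame_k: int = 4
    slot_duration: float = 0.2
    slot_gap: float = 0.05
    device_params: DeviceParams = field(default_factory=DeviceParams)
    mode: Literal["binary", "amplitude"] = "amplitude"

    def __post_init__(self) -> None:
        if self.frame_k < 1:
            raise ValueError("frame_k must be >= 1")


@dataclass
class ReservoirStateVector:
    """High-dimensional current response of one window.

    ``currents`` is the flat vector in row-major (row, frame) order;
    ``layout`` records the (n_rows, n_frames) grid it reshapes to.
    """

    currents: np.ndarray
    layout: tuple[int, int]
    modality: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float).ravel()
        if self.currents.size != self.layout[0] * self.layout[1]:
            raise ValueError("currents length does not match layout")

    @property
    def grid(self) -> np.ndarray:
        return self.currents.reshape(self.layout)

    def __len__(self) -> int:
        return self.currents.size


def _row_amplitudes(train: PulseTrain, frame_k: int
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (amplitude, duration, gap) arrays padded to full frames."""
    amps = np.array([p.amplitude for p in train.pulses], dtype=float)
    durs = np.array([p.duration for p in train.pulses], dtype=float)
    gaps = np.array([p.gap_after for p in train.pulses], dtype=float)
    pad = (-amps.size) % frame_k
    if pad:
        d = durs[-1] if durs.size else 0.2
        g = gaps[-1] if gaps.size else 0.05
        amps = np.concatenate([amps, np.zeros(pad)])
        durs = np.concatenate([durs, np.full(pad, d)])
        gaps = np.concatenate([gaps, np.full(pad, g)])
    return amps, durs, gaps


def _frames_to_currents(amps: np.ndarray, gaps: np.ndarray,
                        p: DeviceParams, frame_k: int,
                        noise_seeds: np.ndarray | None = None) -> np.ndarray:
    """Vectorized device recurrence over all frames of one row.

    Implements exactly the per-pulse update of ``device.apply_pulse``
    (potentiate if amplitude >= v_set, hard reset if <= v_reset, then
    exponential decay over the idle gap), batched across frames.
    """
    n_frames = amps.size // frame_k
    a = amps.reshape(n_frames, frame_k)
    g = gaps.reshape(n_frames, frame_k)
    w = np.full(n_frames, p.w_min)
    rngs = None
    if p.sigma_c2c > 0:
        seeds = (noise_seeds if noise_seeds is not None
                 else np.arange(n_frames))
        rngs = [np.random.default_rng([p.seed, int(s)]) for s in seeds]
    for j in range(frame_k):
        write = a[:, j] >= p.v_set
        dw = p.a_write * (p.w_max - w)
        if rngs is not None:
            noise = np.array([r.normal(0.0, p.sigma_c2c) for r in rngs])
            dw = dw * np.exp(noise)
        w = np.where(write, np.clip(w + dw, p.w_min, p.w_max), w)
        w = np.where(a[:, j] <= p.v_reset, p.w_min, w)
        w = p.w_min + (w - p.w_min) * np.exp(-g[:, j] / p.tau_decay)
    x = (w - p.w_min) / (p.w_max - p.w_min)
    return p.i_off + (p.i_on - p.i_off) * x ** p.p_nl


def run_reservoir(rows: Sequence[PulseTrain], cfg: ReservoirConfig,
                  modality: str = "", meta: dict | None = None
                  ) -> ReservoirStateVector:
    """Drive per-row pulse trains through frame-wise virtual devices.

    Every frame of ``frame_k`` slots programs a fresh device from the
    common baseline; the current read after the frame's last slot (and its
    trailing idle decay) is one state component. Components are ordered
    row-major by (row, frame). Empty rows are skipped with a warning.
    """
    rows = [r for r in rows if _warn_if_empty(r)]
    if not rows:
        raise ValueError("no non-empty pulse rows to process")
    p = cfg.device_params
    per_row = []
    for i, train in enumerate(rows):
        amps, _durs, gaps = _row_amplitudes(train, cfg.frame_k)
        n_frames = amps.size // cfg.frame_k
        seeds = (np.arange(n_frames) + i * 1_000_003
                 if p.sigma_c2c > 0 else None)
        per_row.append(_frames_to_currents(amps, gaps, p, cfg.frame_k, seeds))
    n_frames = max(c.size for c in per_row)
    if any(c.size != n_frames for c in per_row):
        raise ValueError("rows produce unequal frame counts")
    grid = np.vstack(per_row)
    return ReservoirStateVector(grid.ravel(), grid.shape, modality,
                                dict(meta or {}))


def _warn_if_empty(train: PulseTrain) -> bool:
    if len(train) == 0:
        warnings.warn("skipping empty pulse row")
        return False
    return True


def encode_matrix(fm: FeatureMatrix, cfg: ReservoirConfig,
                  modality: str | None = None,
                  mode: str | None = None) -> ReservoirStateVector:
    """Convenience: feature matrix -> pulse rows -> reservoir state."""
    from .encoders import matrix_to_pulserows
    rows = matrix_to_pulserows(fm, mode=mode or cfg.mode,
                               frame_k=cfg.frame_k,
                               v_write=cfg.device_params.v_write,
                               slot_duration=cfg.slot_duration,
                               slot_gap=cfg.slot_gap)
    return run_reservoir(rows, cfg, modality or fm.kind, dict(fm.meta))


def _znorm(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def fuse_modalities(s_eeg: ReservoirStateVector,
                    s_audio: ReservoirStateVector) -> ReservoirStateVector:
    """Concatenate two modality responses into one unified feature vector.

    EEG components come first. Each modality is z-normalized before
    concatenation so that the two current ranges contribute comparably to
    the readout. The original (unnormalized) parts are retained so
    ``unfuse`` can recover them exactly.
    """
    wa = s_eeg.meta.get("window")
    wb = s_audio.meta.get("window")
    if wa is not None and wb is not None and wa != wb:
        raise ValueError(f"window mismatch: {wa!r} vs {wb!r}")
    if len(s_audio) == 0:
        return s_eeg
    if len(s_eeg) == 0:
        return s_audio
    fused = np.concatenate([_znorm(s_eeg.currents), _znorm(s_audio.currents)])
    meta = {"fused": True, "split": len(s_eeg),
            "parts": (s_eeg, s_audio)}
    if wa is not None:
        meta["window"] = wa
    return ReservoirStateVector(fused, (1, fused.size), "fused", meta)


def unfuse(fused: ReservoirStateVector
           ) -> tuple[ReservoirStateVector, ReservoirStateVector]:
    """Recover the original per-modality vectors from a fused vector."""
    if "parts" not in fused.meta:
        raise ValueError("vector does not carry fusion metadata")
    return fused.meta["parts"]


def compress_image(image: np.ndarray, cfg: ReservoirConfig,
                   threshold: float = 0.5
                   ) -> tuple[np.ndarray, np.ndarray, ReservoirStateVector]:
    """Compress a binary image through the reservoir and reconstruct it.

    Each row of the thresholded image is grouped into frames of
    ``frame_k`` pixels; every frame programs one device, so the compressed
    representation is the (n_rows, n_cols/frame_k) current grid — a
    ``frame_k:1`` compression along columns. Reconstruction decodes every
    current to the nearest level of the ``2**frame_k``-level programming
    map (ties toward the lower level) and expands the recovered bits back
    into pixels; it is exact for a noiseless device because the level map
    is injective.

    Returns (compressed grid, reconstructed binary image, state vector).
    """
    binary, rows = image_to_pulsemap(image, threshold)
    cfg_bin = ReservoirConfig(cfg.frame_k, cfg.slot_duration, cfg.slot_gap,
                              cfg.device_params, "binary")
    state = run_reservoir(rows, cfg_bin, modality="image")
    level_map = program_levels(cfg.device_params, cfg.frame_k,
                               cfg.slot_duration, cfg.slot_gap)
    patterns = sorted(level_map)              # '0000' ... '1111'
    level_vals = np.array([level_map[p] for p in patterns])
    order = np.argsort(level_vals, kind="stable")
    sorted_vals = level_vals[order]
    sorted_pats = [patterns[i] for i in order]

    n_rows, n_frames = state.layout
    recon = np.zeros((n_rows, n_frames * cfg.frame_k), dtype=np.int8)
    grid = state.grid
    for r in range(n_rows):
        for f in range(n_frames):
            k = int(np.argmin(np.abs(sorted_vals - grid[r, f])))
            bits = sorted_pats[k]
            recon[r, f * cfg.frame_k:(f + 1) * cfg.frame_k] = [
                int(b) for b in bits]
    recon = recon[:, :binary.shape[1]]
    return grid, recon, state
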