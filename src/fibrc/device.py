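"""Phenomenological model of the Ag/MoS2-QD/Ag fiber memristor.

The device is a diffusive, volatile memristor with fading memory: a write
pulse above the SET threshold potentiates an internal state variable ``w``
toward saturation, the state relaxes exponentially toward baseline during
idle time, and the read current is a power-law function of ``w`` between the
OFF and ON currents. Sixteen conductance levels arise from programming the
device with every 4-bit pulse pattern from a common baseline.

The model is deliberately minimal: saturating potentiation + exponential
decay + power-law readout is the standard phenomenology for diffusive
memristor reservoirs, and it reproduces the three behaviours the simulator
needs — nonlinear pulse response, a separable multi-level programming map,
and echo-state (initial-condition-forgetting) dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DeviceParams",
    "DeviceState",
    "Pulse",
    "PulseTrain",
    "reset_to_baseline",
    "apply_pulse",
    "read_current",
    "program_states",
    "program_levels",
    "iv_sweep",
    "energy_of_train",
]


class ConfigurationError(ValueError):
    """Raised for invalid device parameters or sweep settings."""


@dataclass(frozen=True)
class DeviceParams:
    """Parameters of the phenomenological fiber-memristor model.

    Defaults realize a device that switches at +/-1 V, reads at
    sub-nanoampere currents, and programs 16 separable conductance levels
    from 4-pulse binary frames (minimum adjacent relative margin ~3.5%).

    Attributes
    ----------
    w_min, w_max : float
        Bounds of the internal state variable (dimensionless).
    a_write : float
        Per-pulse potentiation fraction in (0, 1): one write pulse moves
        ``w`` a fraction ``a_write`` of the remaining distance to ``w_max``.
    tau_decay : float
        Spontaneous state decay time constant in seconds.
    v_write, v_read : float
        Write-pulse amplitude and (non-destructive) read voltage, volts.
    v_set, v_reset : float
        Bipolar switching thresholds, volts (+1.0 / -1.0 by default).
    i_off, i_on : float
        Read currents at ``w=w_min`` and ``w=w_max`` under ``v_read``,
        amperes; sub-nanoampere by default.
    p_nl : float
        Readout nonlinearity exponent (>= 1); ``I`` is a power law in the
        normalized state.
    sigma_c2c : float
        Cycle-to-cycle variability: s.d. of the multiplicative log-normal
        noise applied to each potentiation increment. 0 disables noise.
    seed : int
        Seed of the device-local RNG (used only when ``sigma_c2c > 0``).
    """

    w_min: float = 0.0
    w_max: float = 1.0
    a_write: float = 0.3
    tau_decay: float = 0.5
    v_write: float = 1.5
    v_read: float = 1.0
    v_set: float = 1.0
    v_reset: float = -1.0
    i_off: float = 10e-12
    i_on: float = 0.5e-9
    p_nl: float = 2.0
    sigma_c2c: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [self.w_min, self.w_max, self.a_write, self.tau_decay,
                self.v_write, self.v_read, self.v_set, self.v_reset,
                self.i_off, self.i_on, self.p_nl, self.sigma_c2c]
        if not all(math.isfinite(v) for v in vals):
            raise ConfigurationError("device parameters must be finite")
        if not self.w_min < self.w_max:
            raise ConfigurationError("w_min must be < w_max")
        if not 0.0 < self.a_write < 1.0:
            raise ConfigurationError("a_write must be in (0, 1)")
        if self.tau_decay <= 0:
            raise ConfigurationError("tau_decay must be positive")
        if not self.i_on > self.i_off > 0:
            raise ConfigurationError("require i_on > i_off > 0")
        if not self.v_set > 0 > self.v_reset:
            raise ConfigurationError("require v_set > 0 > v_reset")
        if self.p_nl < 1:
            raise ConfigurationError("p_nl must be >= 1")
        if self.sigma_c2c < 0:
            raise ConfigurationError("sigma_c2c must be >= 0")

    def replace(self, **kw) -> "DeviceParams":
        return replace(self, **kw)


@dataclass
class DeviceState:
    """Internal state of one device: state variable ``w`` and local clock.

    The RNG carried here is created from ``DeviceParams.seed`` at reset so
    that trajectories with ``sigma_c2c > 0`` are reproducible.
    """

    w: float
    t: float = 0.0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0), compare=False)


@dataclass(frozen=True)
class Pulse:
    """One voltage pulse: amplitude (V), duration (s), idle gap after (s)."""

    amplitude: float
    duration: float
    gap_after: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")
        if self.gap_after < 0:
            raise ValueError("gap_after must be >= 0")


@dataclass(frozen=True)
class PulseTrain:
    """Ordered sequence of pulses."""

    pulses: tuple[Pulse, ...]

    def __init__(self, pulses: Iterable[Pulse]):
        object.__setattr__(self, "pulses", tuple(pulses))

    @property
    def total_duration(self) -> float:
        return sum(p.duration + p.gap_after for p in self.pulses)

    def __len__(self) -> int:
        return len(self.pulses)

    def __iter__(self):
        return iter(self.pulses)


def reset_to_baseline(params: DeviceParams) -> DeviceState:
    """Return a device freshly initialized at the common baseline.

    All devices start from the same baseline state ``w = w_min`` (reading
    ``i_off``) with the local clock at zero.
    """
    return DeviceState(w=params.w_min, t=0.0,
                       rng=np.random.default_rng(params.seed))


def apply_pulse(state: DeviceState, pulse: Pulse,
                params: DeviceParams) -> DeviceState:
    """Apply one pulse and the subsequent idle decay; return the new state.

    Amplitude >= v_set potentiates ``w`` by ``a_write * (w_max - w)``
    (optionally perturbed by multiplicative log-normal cycle-to-cycle
    noise); amplitude <= v_reset hard-resets to ``w_min`` (abrupt filament
    rupture); intermediate amplitudes leave ``w`` unchanged. The state then
    decays toward ``w_min`` over ``gap_after`` with time constant
    ``tau_decay``, and the clock advances by ``duration + gap_after``.
    """
    w = state.w
    if pulse.amplitude >= params.v_set:
        dw = params.a_write * (params.w_max - w)
        if params.sigma_c2c > 0:
            dw *= math.exp(state.rng.normal(0.0, params.sigma_c2c))
        w = min(max(w + dw, params.w_min), params.w_max)
    elif pulse.amplitude <= params.v_reset:
        w = params.w_min
    if pulse.gap_after > 0:
        w = params.w_min + (w - params.w_min) * math.exp(
            -pulse.gap_after / params.tau_decay)
    return DeviceState(w=w, t=state.t + pulse.duration + pulse.gap_after,
                       rng=state.rng)


def read_current(state: DeviceState, params: DeviceParams) -> float:
    """Non-destructive current readout at ``v_read``.

    ``I = i_off + (i_on - i_off) * ((w - w_min)/(w_max - w_min))**p_nl``;
    strictly increasing in ``w``.
    """
    x = (state.w - params.w_min) / (params.w_max - params.w_min)
    return params.i_off + (params.i_on - params.i_off) * x ** params.p_nl


def _frame_pulses(frame: Sequence[int], params: DeviceParams,
                  slot_duration: float, slot_gap: float) -> list[Pulse]:
    pulses = []
    for b in frame:
        if b not in (0, 1):
            raise ValueError(f"frame entries must be 0 or 1, got {b!r}")
        amp = params.v_write if b == 1 else 0.0
        pulses.append(Pulse(amplitude=amp, duration=slot_duration,
                            gap_after=slot_gap))
    return pulses


def program_states(frame: Sequence[int] | str, params: DeviceParams,
                   slot_duration: float = 0.2,
                   slot_gap: float = 0.05) -> float:
    """Program a device from baseline with a binary pulse frame; read it.

    Each bit maps to one slot: 1 -> a write pulse at ``v_write``, 0 -> a
    zero-amplitude slot of equal duration; all slots share the same idle
    gap. Returns the final read current. With ``sigma_c2c = 0`` the map
    from the 2^k binary frames to currents is injective (adjacent sorted
    levels separated by >= 1% relative margin at the defaults).
    """
    bits = [int(c) for c in frame]
    state = reset_to_baseline(params)
    for p in _frame_pulses(bits, params, slot_duration, slot_gap):
        state = apply_pulse(state, p, params)
    return read_current(state, params)


def program_levels(params: DeviceParams, frame_k: int = 4,
                   slot_duration: float = 0.2,
                   slot_gap: float = 0.05) -> dict[str, float]:
    """Enumerate all 2**frame_k binary frames -> programmed current map."""
    out: dict[str, float] = {}
    for i in range(2 ** frame_k):
        bits = format(i, f"0{frame_k}b")
        out[bits] = program_states(bits, params, slot_duration, slot_gap)
    return out


def count_distinct_levels(currents: Sequence[float],
                          margin_min: float = 0.01) -> int:
    """Count mutually distinguishable levels among programmed currents.

    Levels are sorted; a new level is counted whenever the relative
    separation from the previous counted level is at least ``margin_min``.
    """
    vals = np.sort(np.asarray(currents, dtype=float))
    n = 1
    last = vals[0]
    for v in vals[1:]:
        if (v - last) / v >= margin_min:
            n += 1
            last = v
    return n


def iv_sweep(params: DeviceParams, v_max: float,
             n_points: int = 201) -> np.ndarray:
    """Quasi-static triangular I-V sweep 0 -> +v_max -> 0 -> -v_max -> 0.

    SET (w -> w_max) occurs at the first sample with ``v >= v_set`` and
    RESET (w -> w_min) at the first with ``v <= v_reset``, producing the
    pinched hysteresis loop characteristic of bipolar resistive switching.
    Current is ohmic in the instantaneous conductance:
    ``I = G(w) * v`` with ``G(w)`` interpolated between ``i_off/v_read``
    and ``i_on/v_read``.

    Returns an (N, 2) array of (voltage, current) samples.
    """
    if v_max <= params.v_set:
        raise ConfigurationError(
            f"v_max={v_max} must exceed v_set={params.v_set} for switching")
    quarter = np.linspace(0.0, v_max, n_points)
    voltages = np.concatenate([quarter, quarter[-2::-1],
                               -quarter[1:], -quarter[-2::-1]])
    g_off = params.i_off / params.v_read
    g_on = params.i_on / params.v_read
    w = params.w_min
    out = np.empty((voltages.size, 2))
    for i, v in enumerate(voltages):
        if v >= params.v_set:
            w = params.w_max
        elif v <= params.v_reset:
            w = params.w_min
        x = (w - params.w_min) / (params.w_max - params.w_min)
        g = g_off + (g_on - g_off) * x ** params.p_nl
        out[i] = (v, g * v)
    return out


def energy_of_train(train: PulseTrain | Iterable[Pulse],
                    params: DeviceParams,
                    state: DeviceState | None = None
                    ) -> tuple[float, float]:
    """Energy dissipated by a pulse train and its mean power.

    ``E = sum |V * I(w during pulse)| * duration`` over pulses, with the
    current evaluated from the state trajectory at the start of each pulse
    (the state changes only at pulse edges in this model, so the product is
    exact, not a quadrature approximation). Returns ``(energy_J, mean_W)``;
    mean power is energy over the total train duration (0 for an empty
    train).
    """
    pulses = list(train.pulses if isinstance(train, PulseTrain) else train)
    if state is None:
        state = reset_to_baseline(params)
    energy = 0.0
    total_t = 0.0
    for p in pulses:
        # current while the pulse is applied, from the state at pulse onset
        # (potentiation takes effect at the trailing edge)
        i_during = read_current(state, params)
        energy += abs(p.amplitude * i_during) * p.duration
        total_t += p.duration + p.gap_after
        state = apply_pulse(state, p, params)
    mean_power = energy / total_t if total_t > 0 else 0.0
    return energy, mean_power
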