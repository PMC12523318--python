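"""Stacked audio augmentation for four-valve channel sets.

Each augmented copy of a patient's recordings is produced by a plan of
randomly chosen transforms — Gaussian noise injection, pitch shift, time
shift (circular), time warp — applied in order with identical structural
parameters on all four channels, so their correlation is preserved.
Pitch shift and time warp run through an STFT phase vocoder: pitch shift
scales all frequency content by a factor alpha at constant duration,
time warp rescales duration by a rate factor at constant pitch.

Parameter ranges are deliberately modest (alpha in [0.8, 1.25], warp
rate in [0.85, 1.18], noise at 0.1-1% of full scale): aggressive pitch
or tempo changes can push heart sounds outside physiological plausibility.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import ShortTimeFFT, get_window

from .io import VALVES, AudioSignal
from .sync import ValveChannelSet, loop_to_length

__all__ = [
    "AugmentOp",
    "AugmentPlan",
    "AugmentRanges",
    "add_gaussian_noise",
    "pitch_shift",
    "time_shift",
    "time_warp",
    "make_plan",
    "apply_plan",
    "make_augmented_copies",
    "derive_seed",
]

OP_KINDS = ("noise", "pitch", "shift", "warp")

DEFAULT_DEPTH = 10
DEFAULT_N_COPIES = 3


@dataclass
class AugmentRanges:
    """Uniform sampling ranges for the four transform kinds."""

    noise_factor: tuple = (0.001, 0.01)
    alpha: tuple = (0.8, 1.25)
    warp_rate: tuple = (0.85, 1.18)
    # time-shift offsets are drawn uniformly over the full signal length


@dataclass
class AugmentOp:
    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in OP_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")


@dataclass
class AugmentPlan:
    """An ordered stack of transforms; a pure function of its seed."""

    ops: list
    seed: int


def _stft_op(rate: int, n_fft: int = 1024, hop: int = 256) -> ShortTimeFFT:
    win = get_window("hann", n_fft)
    return ShortTimeFFT(win, hop=hop, fs=rate)


def add_gaussian_noise(signal: AudioSignal, noise_factor: float, seed) -> AudioSignal:
    """Add standard-normal noise scaled by ``noise_factor`` element-wise."""
    if noise_factor < 0:
        raise ValueError("noise_factor must be non-negative")
    if noise_factor == 0:
        return AudioSignal(signal.samples.copy(), signal.rate)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(len(signal.samples))
    return AudioSignal(signal.samples + noise_factor * z, signal.rate)


def time_shift(signal: AudioSignal, offset: int) -> AudioSignal:
    """Circular rotation by ``offset`` samples, wrapped at the boundary."""
    n = len(signal.samples)
    return AudioSignal(np.roll(signal.samples, int(offset) % n), signal.rate)


def _phase_vocoder(S: np.ndarray, rate: float, hop: int, n_fft: int) -> np.ndarray:
    """Resample STFT frames along time by ``rate`` with phase accumulation.

    Output frame k reads input position k*rate; magnitudes are linearly
    interpolated and phases advanced by the measured per-bin instantaneous
    frequency, so a tone's pitch survives the time rescaling.
    """
    n_bins, n_frames = S.shape
    if n_frames < 2:
        return S.copy()
    steps = np.arange(0, n_frames - 1, rate)
    lo = steps.astype(int)
    frac = steps - lo
    S0, S1 = S[:, lo], S[:, lo + 1]
    mag = (1.0 - frac) * np.abs(S0) + frac * np.abs(S1)
    expected = 2.0 * np.pi * hop * np.arange(n_bins)[:, None] / n_fft
    dphi = np.angle(S1) - np.angle(S0) - expected
    dphi -= 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
    increment = expected + dphi
    phase = np.angle(S[:, lo[0]])[:, None] + np.concatenate(
        [np.zeros((n_bins, 1)), np.cumsum(increment[:, :-1], axis=1)], axis=1
    )
    return mag * np.exp(1j * phase)


def time_warp(signal: AudioSignal, rate: float, n_fft: int = 1024, hop: int = 256) -> AudioSignal:
    """Rescale duration by 1/``rate`` while preserving pitch (STFT vocoder)."""
    if rate <= 0:
        raise ValueError("warp rate must be positive")
    sft = _stft_op(signal.rate, n_fft, hop)
    S = sft.stft(signal.samples)
    warped = _phase_vocoder(S, rate, hop, n_fft)
    n_out = int(round(len(signal.samples) / rate))
    y = sft.istft(warped, k1=n_out)
    return AudioSignal(y[:n_out], signal.rate)


def pitch_shift(signal: AudioSignal, alpha: float, n_fft: int = 1024, hop: int = 256) -> AudioSignal:
    """Scale all frequency content by ``alpha`` (>1 raises pitch), same duration.

    Implemented as a vocoder time-stretch by ``alpha`` followed by reading
    the stretched signal back at speed ``alpha`` (circular at the tail), so
    duration is exactly preserved while every component lands at alpha
    times its original frequency.
    """
    if alpha <= 0:
        raise ValueError("pitch factor alpha must be positive")
    n = len(signal.samples)
    if alpha == 1.0:
        stretched = time_warp(signal, 1.0, n_fft, hop).samples
        pad = stretched
    else:
        stretched = time_warp(signal, 1.0 / alpha, n_fft, hop).samples
        pad = stretched
    positions = (np.arange(n) * alpha) % len(pad)
    y = np.interp(positions, np.arange(len(pad)), pad, period=len(pad))
    return AudioSignal(y, signal.rate)


def derive_seed(*parts) -> int:
    """Stable 31-bit seed from heterogeneous parts (ids, indices)."""
    key = ":".join(str(p) for p in parts).encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def make_plan(
    depth: int = DEFAULT_DEPTH,
    seed: int = 0,
    ranges: AugmentRanges | None = None,
    n_samples: int | None = None,
) -> AugmentPlan:
    """Draw ``depth`` transforms uniformly with replacement from the four kinds.

    ``n_samples`` sets the range for time-shift offsets (required if the
    plan may draw a shift).  Reproducible from ``seed``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    ranges = ranges or AugmentRanges()
    rng = np.random.default_rng(seed)
    ops = []
    for _ in range(depth):
        kind = OP_KINDS[rng.integers(len(OP_KINDS))]
        if kind == "noise":
            params = {"noise_factor": float(rng.uniform(*ranges.noise_factor))}
        elif kind == "pitch":
            params = {"alpha": float(rng.uniform(*ranges.alpha))}
        elif kind == "shift":
            if n_samples is None:
                raise ValueError("n_samples required to draw time-shift offsets")
            params = {"offset": int(rng.integers(n_samples))}
        else:  # warp
            params = {"rate": float(rng.uniform(*ranges.warp_rate))}
        ops.append(AugmentOp(kind=kind, params=params))
    return AugmentPlan(ops=ops, seed=seed)


def apply_plan(group: ValveChannelSet, plan: AugmentPlan) -> ValveChannelSet:
    """Apply the plan with identical parameters on all four channels.

    Structural transforms (pitch/shift/warp) share parameters exactly
    across channels; Gaussian noise shares its scale but draws an
    independent realization per channel (four sensors never pick up one
    identical noise trace).  Time warp changes duration, so the stack's
    output is re-looped/truncated to the group's original length.
    """
    target_n = group.n_samples
    rate = group.rate
    channels = {v: group.channels[v].samples.copy() for v in VALVES}
    for op_idx, op in enumerate(plan.ops):
        for ch_idx, valve in enumerate(VALVES):
            sig = AudioSignal(channels[valve], rate)
            if op.kind == "noise":
                seed = derive_seed(plan.seed, op_idx, ch_idx)
                sig = add_gaussian_noise(sig, op.params["noise_factor"], seed)
            elif op.kind == "pitch":
                sig = pitch_shift(sig, op.params["alpha"])
            elif op.kind == "shift":
                sig = time_shift(sig, op.params["offset"] % len(sig.samples))
            else:
                sig = time_warp(sig, op.params["rate"])
            channels[valve] = sig.samples
    out = {}
    for valve in VALVES:
        sig = AudioSignal(channels[valve], rate)
        if len(sig.samples) != target_n:
            sig = loop_to_length(sig, target_n / rate)
        out[valve] = sig
    return ValveChannelSet(
        channels=out,
        label=group.label,
        patient_id=group.patient_id,
        provenance="augmented",
        lineage=f"{group.lineage or group.patient_id}+aug(seed={plan.seed})",
    )


def make_augmented_copies(
    group: ValveChannelSet,
    n_copies: int = DEFAULT_N_COPIES,
    depth: int = DEFAULT_DEPTH,
    seed: int = 0,
    ranges: AugmentRanges | None = None,
) -> list:
    """Generate ``n_copies`` independently-planned augmented groups.

    Per-copy seeds are derived from (seed, patient_id, copy index), so
    adding patients to a dataset never perturbs other patients' copies.
    The original group is untouched.
    """
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")
    copies = []
    for i in range(n_copies):
        copy_seed = derive_seed(seed, group.patient_id, i)
        plan = make_plan(depth=depth, seed=copy_seed, ranges=ranges, n_samples=group.n_samples)
        copies.append(apply_plan(group, plan))
    return copies
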