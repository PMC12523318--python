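"""Heartbeat-based synchronization of four-valve recordings.

The four auscultation points of one patient are recorded independently,
so their heartbeats start at different offsets.  Before multivariate
processing the channels are made congruous: heartbeat peaks are detected
on a smoothed energy envelope, every channel is circularly rotated so
that all first heartbeats coincide, and each channel is looped to a
common fixed duration so all model inputs share one length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io import VALVES, AudioSignal

__all__ = [
    "BeatTrack",
    "ValveChannelSet",
    "SyncError",
    "detect_beats",
    "align_group",
    "loop_to_length",
    "synchronize_group",
]

#: defaults: 50 ms envelope smoothing, 0.35 s minimum beat separation
#: (about a 170 bpm ceiling), 58 s common duration.
DEFAULT_SMOOTH_WIN_S = 0.05
DEFAULT_MIN_SEP_S = 0.35
DEFAULT_TARGET_LEN_S = 58.0


class SyncError(ValueError):
    """Raised when a channel yields no detectable heartbeat."""


@dataclass
class BeatTrack:
    """Detected heartbeat peaks and the envelope they came from."""

    peak_times: np.ndarray  # seconds, strictly increasing
    envelope: np.ndarray    # smoothed energy, same rate as the source
    rate: int


@dataclass
class ValveChannelSet:
    """The four time-aligned, equal-length channels of one patient instance.

    ``provenance`` is "original" or "augmented"; ``lineage`` tracks how an
    augmented copy was derived (patient id, copy index, seeds).
    """

    channels: dict  # valve -> AudioSignal
    label: str
    patient_id: str = ""
    provenance: str = "original"
    lineage: str = ""

    def __post_init__(self) -> None:
        if set(self.channels) != set(VALVES):
            raise ValueError(f"expected channels {VALVES}, got {sorted(self.channels)}")
        lengths = {len(s) for s in self.channels.values()}
        rates = {s.rate for s in self.channels.values()}
        if len(lengths) != 1 or len(rates) != 1:
            raise ValueError("all four channels must share one length and rate")

    @property
    def rate(self) -> int:
        return next(iter(self.channels.values())).rate

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


def energy_envelope(signal: AudioSignal, smooth_win: float = DEFAULT_SMOOTH_WIN_S) -> np.ndarray:
    """Squared signal smoothed by a moving average of ``smooth_win`` seconds."""
    w = max(1, int(round(smooth_win * signal.rate)))
    kernel = np.ones(w) / w
    return np.convolve(signal.samples**2, kernel, mode="same")


def detect_beats(
    signal: AudioSignal,
    min_sep: float = DEFAULT_MIN_SEP_S,
    smooth_win: float = DEFAULT_SMOOTH_WIN_S,
) -> BeatTrack:
    """Find heartbeat peaks as local maxima of the energy envelope.

    Peaks must clear an adaptive threshold (half the envelope's 95th
    percentile, floored at a tenth of its maximum) and be at least
    ``min_sep`` seconds apart.

    Raises
    ------
    SyncError
        If no peak clears the threshold (flat or silent input).
    """
    env = energy_envelope(signal, smooth_win)
    # percentile threshold for regular beat trains, max-based floor for
    # sparse signals where the 95th percentile sits in the silence
    threshold = max(0.5 * np.percentile(env, 95), 0.1 * env.max())
    if threshold <= 0:
        raise SyncError("no beats detected: silent signal")
    distance = max(1, int(round(min_sep * signal.rate)))
    peaks, _ = find_peaks(env, height=threshold, distance=distance)
    if len(peaks) == 0:
        raise SyncError("no beats detected")
    return BeatTrack(peak_times=peaks / signal.rate, envelope=env, rate=signal.rate)


def align_group(
    signals: dict,
    min_sep: float = DEFAULT_MIN_SEP_S,
    smooth_win: float = DEFAULT_SMOOTH_WIN_S,
) -> dict:
    """Circularly rotate each channel so all first heartbeats coincide.

    The common timestamp is the latest of the four original first-beat
    times, so every rotation is forward (rightward) and no silence is
    injected.  Rotation preserves the multiset of sample values exactly.
    """
    firsts = {}
    for valve, sig in signals.items():
        try:
            firsts[valve] = detect_beats(sig, min_sep, smooth_win).peak_times[0]
        except SyncError as exc:
            raise SyncError(f"channel {valve}: {exc}") from exc
    target = max(firsts.values())
    out = {}
    for valve, sig in signals.items():
        shift = int(round((target - firsts[valve]) * sig.rate))
        out[valve] = AudioSignal(np.roll(sig.samples, shift), sig.rate)
    return out


def loop_to_length(signal: AudioSignal, target: float) -> AudioSignal:
    """Tile the signal end-to-start and truncate to ``round(target*rate)`` samples."""
    if target <= 0:
        raise ValueError("target duration must be positive")
    n = int(round(target * signal.rate))
    reps = -(-n // len(signal.samples))  # ceil division
    return AudioSignal(np.tile(signal.samples, reps)[:n], signal.rate)


def synchronize_group(
    group: ValveChannelSet,
    target_len: float = DEFAULT_TARGET_LEN_S,
    min_sep: float = DEFAULT_MIN_SEP_S,
    smooth_win: float = DEFAULT_SMOOTH_WIN_S,
) -> ValveChannelSet:
    """Align the four channels on their first heartbeat and loop to ``target_len``."""
    aligned = align_group(group.channels, min_sep=min_sep, smooth_win=smooth_win)
    looped = {v: loop_to_length(s, target_len) for v, s in aligned.items()}
    return ValveChannelSet(
        channels=looped,
        label=group.label,
        patient_id=group.patient_id,
        provenance=group.provenance,
        lineage=group.lineage or group.patient_id,
    )
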