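"""Mel spectrograms and SpecAugment-style masking.

The time-frequency front end: a magnitude STFT on a Hann window passed
through a bank of triangular Mel-spaced filters (higher resolution at
low frequencies, coarser at high, mimicking auditory processing), then
per-spectrogram min-max normalization to [0, 1].  Spectrogram-level
augmentation zeroes a random contiguous band of frames (time mask) or
Mel bins (frequency mask).

Defaults target the heart-sound band: 1024-sample window, hop 256,
64 Mel bins between 10 and 1000 Hz.  Frames are counted without
padding: frames = 1 + floor((N - win)/hop).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import get_window

from .io import AudioSignal

__all__ = [
    "MelSpec",
    "MaskSpec",
    "MelParams",
    "mel_filterbank",
    "mel_spectrogram",
    "normalize",
    "apply_mask",
    "random_mask",
    "expand_to_four",
    "expand_group_to_four",
]

DEFAULT_MAX_MASK_MS = 20.0
DEFAULT_MAX_FREQ_MASK_BINS = 8


@dataclass
class MelParams:
    win: int = 1024
    hop: int = 256
    n_mels: int = 64
    fmin: float = 10.0
    fmax: float = 1000.0


@dataclass
class MelSpec:
    """A Mel-scaled time-frequency matrix with its axis calibration."""

    matrix: np.ndarray  # (n_mels, frames), non-negative pre-normalization
    rate: int
    hop: int
    win: int
    n_mels: int
    fmin: float
    fmax: float
    normalized: bool = False

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MaskSpec:
    """A zeroed band: contiguous frames (time) or Mel bins (frequency)."""

    axis: str   # "time" | "frequency"
    start: int
    width: int

    def __post_init__(self) -> None:
        if self.axis not in ("time", "frequency"):
            raise ValueError(f"unknown mask axis {self.axis!r}")
        if self.width < 0 or self.start < 0:
            raise ValueError("mask start/width must be non-negative")


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(rate: int, n_fft: int, n_mels: int, fmin: float, fmax: float) -> np.ndarray:
    """Triangular filters on Mel-spaced center frequencies, peak height 1.

    Returns an (n_mels, n_fft//2 + 1) matrix applied to a power STFT.
    """
    if not 0 <= fmin < fmax <= rate / 2:
        raise ValueError("need 0 <= fmin < fmax <= Nyquist")
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, len(freqs)))
    for i in range(n_mels):
        lo, center, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (freqs - lo) / (center - lo)
        down = (hi - freqs) / (hi - center)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def filterbank_centers(rate: int, n_mels: int, fmin: float, fmax: float) -> np.ndarray:
    """Center frequencies (Hz) of the triangular filters."""
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    return _mel_to_hz(mel_pts)[1:-1]


def mel_spectrogram(signal: AudioSignal, params: MelParams | None = None) -> MelSpec:
    """Power STFT (Hann, no padding) through the Mel filter bank.

    Raises if the signal is shorter than one analysis window.
    """
    p = params or MelParams()
    x = signal.samples
    if len(x) < p.win:
        raise ValueError(f"signal length {len(x)} shorter than window {p.win}")
    n_frames = 1 + (len(x) - p.win) // p.hop
    frames = np.lib.stride_tricks.sliding_window_view(x, p.win)[:: p.hop][:n_frames]
    window = get_window("hann", p.win)
    spectrum = np.abs(np.fft.rfft(frames * window, axis=1)) ** 2
    fb = mel_filterbank(signal.rate, p.win, p.n_mels, p.fmin, p.fmax)
    return MelSpec(
        matrix=fb @ spectrum.T,
        rate=signal.rate,
        hop=p.hop,
        win=p.win,
        n_mels=p.n_mels,
        fmin=p.fmin,
        fmax=p.fmax,
    )


def normalize(spec: MelSpec) -> MelSpec:
    """Min-max scale to [0, 1] per spectrogram; constant matrices map to zeros."""
    m = spec.matrix
    lo, hi = m.min(), m.max()
    if hi > lo:
        out = (m - lo) / (hi - lo)
    else:
        out = np.zeros_like(m)
    return replace(spec, matrix=out, normalized=True)


def apply_mask(spec: MelSpec, mask: MaskSpec) -> MelSpec:
    """Zero the masked rows (frequency) or columns (time); everything else untouched."""
    n_rows, n_cols = spec.matrix.shape
    bound = n_cols if mask.axis == "time" else n_rows
    if mask.start + mask.width > bound:
        raise ValueError(f"{mask.axis} mask [{mask.start}, {mask.start + mask.width}) exceeds {bound}")
    out = spec.matrix.copy()
    if mask.axis == "time":
        out[:, mask.start : mask.start + mask.width] = 0.0
    else:
        out[mask.start : mask.start + mask.width, :] = 0.0
    return replace(spec, matrix=out)


def random_mask(
    spec: MelSpec,
    seed: int,
    max_ms: float = DEFAULT_MAX_MASK_MS,
    max_freq_bins: int = DEFAULT_MAX_FREQ_MASK_BINS,
) -> MaskSpec:
    """Draw a random mask: axis uniform, duration uniform in [0, max_ms].

    The millisecond draw converts to frames for a time mask (ceil of
    ms x rate / hop) and, since a frequency band has no time unit, maps
    proportionally onto [0, max_freq_bins] bins for a frequency mask.
    """
    if max_ms < 0:
        raise ValueError("max_ms must be non-negative")
    rng = np.random.default_rng(seed)
    axis = "time" if rng.integers(2) == 0 else "frequency"
    u = rng.uniform(0.0, max_ms)
    if axis == "time":
        width = int(math.ceil(u / 1000.0 * spec.rate / spec.hop))
        bound = spec.matrix.shape[1]
    else:
        width = int(math.ceil(u / max_ms * max_freq_bins)) if max_ms > 0 else 0
        bound = spec.matrix.shape[0]
    width = min(width, bound)
    start = int(rng.integers(bound - width + 1))
    return MaskSpec(axis=axis, start=start, width=width)


def expand_to_four(spec: MelSpec, seed: int, max_ms: float = DEFAULT_MAX_MASK_MS,
                   max_freq_bins: int = DEFAULT_MAX_FREQ_MASK_BINS) -> list:
    """[original, masked1, masked2, masked3] with independent seeded masks."""
    out = [spec]
    for i in range(3):
        mask = random_mask(spec, seed * 4 + i + 1, max_ms, max_freq_bins)
        out.append(apply_mask(spec, mask))
    return out


def expand_group_to_four(specs: dict, seed: int, max_ms: float = DEFAULT_MAX_MASK_MS,
                         max_freq_bins: int = DEFAULT_MAX_FREQ_MASK_BINS) -> list:
    """Expand a 4-channel group into 4 variants, one mask shared per variant.

    Mirrors the audio-augmentation coherence rule: the same mask is
    applied to all four valve channels of a variant.  Returns a list of
    four dicts valve -> MelSpec; element 0 is the unmasked original.
    """
    valves = list(specs)
    out = [dict(specs)]
    reference = specs[valves[0]]
    for i in range(3):
        mask = random_mask(reference, seed * 4 + i + 1, max_ms, max_freq_bins)
        out.append({v: apply_mask(specs[v], mask) for v in valves})
    return out
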