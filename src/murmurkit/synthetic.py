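"""Synthetic four-valve phonocardiogram generator.

Emulates the statistical structure the pipeline assumes from pediatric
heart-sound recordings: ~4 kHz sampling, periodic S1/S2 transients with
beat-to-beat heart-rate jitter, per-valve gain differences (channels
correlated but not identical), an optional systolic murmur rendered as
band-limited Gaussian noise confined to systole, and a white noise
floor.  Channels of one patient share beat times but carry independent
random onset delays (up to 0.5 s), so the synchronization stage has
real work to do.  No claim of clinical realism is made beyond the
label <-> systolic-band-energy association.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import VALVES, AudioSignal, write_wav
from .sync import ValveChannelSet

__all__ = ["SynthParams", "synth_channel", "synth_patient", "synth_dataset"]


@dataclass
class SynthParams:
    """Generator knobs; defaults sketch a pediatric recording.

    rate 4000 Hz; heart_rate 100 bpm; S1/S2 as damped sinusoids at
    60/90 Hz; murmur as 100-400 Hz band noise at amplitude 0.35 of full
    scale (a loud, clearly audible murmur); white noise floor 0.01.
    """

    rate: int = 4000
    duration: float = 20.0
    heart_rate: float = 100.0
    s1_freq: float = 60.0
    s2_freq: float = 90.0
    murmur_band: tuple = (100.0, 400.0)
    murmur_amp: float = 0.35
    valve_gains: tuple = (1.0, 0.9, 0.8, 0.85)
    noise_floor: float = 0.01
    max_onset_delay: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.murmur_band
        if not 0 < lo < hi < self.rate / 2:
            raise ValueError("murmur band must satisfy 0 < low < high < Nyquist")
        if not 40 <= self.heart_rate <= 200:
            raise ValueError("heart_rate must be within [40, 200] bpm")
        if self.murmur_amp < 0 or self.noise_floor < 0:
            raise ValueError("amplitudes must be non-negative")


def _beat_times(params: SynthParams, rng) -> np.ndarray:
    """Beat onsets with ±3% period jitter, starting 0.2 s in.

    A quiet tail of ``max_onset_delay`` is reserved at the end so that
    circular onset delays and the subsequent alignment rotations never
    wrap a beat past the signal boundary.
    """
    period = 60.0 / params.heart_rate
    times, t = [], 0.2
    while t < params.duration - 0.15 - params.max_onset_delay:
        times.append(t)
        t += period * (1.0 + 0.03 * rng.uniform(-1, 1))
    return np.asarray(times)


def _transient(n: int, rate: int, freq: float, decay: float = 0.015) -> np.ndarray:
    t = np.arange(n) / rate
    return np.exp(-t / decay) * np.sin(2 * np.pi * freq * t)


def synth_channel(
    params: SynthParams,
    valve: str,
    murmur: bool,
    beat_times: np.ndarray | None = None,
    rng=None,
) -> AudioSignal:
    """One valve's trace: S1/S2 train, optional systolic murmur, noise floor.

    ``beat_times`` and ``rng`` may be supplied so the four channels of a
    patient share beats while drawing independent noise; reproducible
    from ``params.seed`` otherwise.
    """
    if rng is None:
        rng = np.random.default_rng((params.seed, VALVES.index(valve)))
    gain = params.valve_gains[VALVES.index(valve)]
    if beat_times is None:
        beat_times = _beat_times(params, rng)
    n = int(round(params.duration * params.rate))
    x = np.zeros(n)
    period = 60.0 / params.heart_rate
    systole = 0.35 * period  # S1 -> S2 interval
    tr_len = int(0.08 * params.rate)
    s1 = _transient(tr_len, params.rate, params.s1_freq)
    s2 = 0.7 * _transient(tr_len, params.rate, params.s2_freq)
    for t in beat_times:
        i1 = int(round(t * params.rate))
        i2 = int(round((t + systole) * params.rate))
        if i1 + tr_len <= n:
            x[i1 : i1 + tr_len] += gain * s1
        if i2 + tr_len <= n:
            x[i2 : i2 + tr_len] += gain * s2
    if murmur and params.murmur_amp > 0:
        sos = butter(4, params.murmur_band, btype="bandpass", fs=params.rate, output="sos")
        band = sosfiltfilt(sos, rng.standard_normal(n))
        band /= max(band.std(), 1e-12)
        window = np.zeros(n)
        sys_len = int(systole * params.rate)
        taper = np.hanning(max(sys_len, 2))
        for t in beat_times:
            i1 = int(round((t + 0.02) * params.rate))
            if i1 + sys_len <= n:
                window[i1 : i1 + sys_len] = np.maximum(window[i1 : i1 + sys_len], taper[:sys_len])
        x += params.murmur_amp * gain * band * window
    if params.noise_floor > 0:
        x += params.noise_floor * rng.standard_normal(n)
    peak = np.abs(x).max()
    if peak > 1.0:
        x = x / (peak * 1.01)
    return AudioSignal(x, params.rate)


def synth_patient(params: SynthParams, murmur: bool, patient_id: str = "synth") -> ValveChannelSet:
    """Four channels sharing beat times, each with its own onset delay."""
    rng = np.random.default_rng(params.seed)
    beats = _beat_times(params, rng)
    channels = {}
    for valve in VALVES:
        ch_rng = np.random.default_rng((params.seed, VALVES.index(valve), 7))
        sig = synth_channel(params, valve, murmur, beat_times=beats, rng=ch_rng)
        delay = int(ch_rng.uniform(0, params.max_onset_delay) * params.rate)
        channels[valve] = AudioSignal(np.roll(sig.samples, delay), params.rate)
    return ValveChannelSet(
        channels=channels,
        label="present" if murmur else "absent",
        patient_id=patient_id,
        provenance="original",
        lineage=patient_id,
    )


def synth_dataset(
    n_patients: int,
    prevalence: float = 0.5,
    seed: int = 0,
    params: SynthParams | None = None,
    out_dir=None,
) -> list:
    """A labeled cohort with exactly round(prevalence * n) murmur-positive patients.

    With ``out_dir`` set, writes one WAV per channel plus a patient
    table TSV in the package's metadata dialect, round-trippable through
    the I/O module.
    """
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    base = params or SynthParams()
    n_pos = int(round(prevalence * n_patients))
    flags = np.array([True] * n_pos + [False] * (n_patients - n_pos))
    rng = np.random.default_rng(seed)
    rng.shuffle(flags)
    groups = []
    for i, murmur in enumerate(flags):
        pid = f"p{i:04d}"
        p = replace(base, seed=int(np.random.default_rng((seed, i)).integers(2**31)))
        groups.append(synth_patient(p, bool(murmur), patient_id=pid))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for g in groups:
            for valve, sig in g.channels.items():
                name = f"{g.patient_id}_{valve}.wav"
                write_wav(out_dir / name, sig)
                rows.append((g.patient_id, valve, name, g.label))
        with open(out_dir / "patients.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["patient_id", "valve", "wav_path", "label"])
            writer.writerows(rows)
    return groups
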