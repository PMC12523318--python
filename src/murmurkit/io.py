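"""Reading and writing WAV recordings and patient metadata tables.

A dataset is a directory of mono WAV files (one per auscultation point)
plus a UTF-8 TSV with columns ``patient_id``, ``valve``, ``wav_path``,
``label``.  Valve codes are AV/PV/TV/MV (aortic, pulmonic, tricuspid,
mitral); labels are ``present``/``absent`` (case-insensitive).  A
patient's group label is "present" if a murmur is present at any valve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

VALVES = ("AV", "PV", "TV", "MV")
LABELS = ("present", "absent")

__all__ = [
    "VALVES",
    "LABELS",
    "AudioSignal",
    "PatientRecord",
    "read_wav",
    "write_wav",
    "resample",
    "read_patient_table",
    "filter_complete_patients",
    "convert_circor_metadata",
]


class PcgIOError(ValueError):
    """Raised for malformed audio files or metadata tables."""


@dataclass
class AudioSignal:
    """A mono phonocardiogram trace.

    Parameters
    ----------
    samples : ndarray of float
        Amplitudes, nominal range [-1, 1].
    rate : int
        Sampling rate in Hz, positive.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise PcgIOError("AudioSignal expects a 1-D sample array")
        if len(self.samples) == 0:
            raise PcgIOError("AudioSignal must be non-empty")
        if self.rate <= 0:
            raise PcgIOError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class PatientRecord:
    """One patient's recordings: a mapping valve -> WAV path and a label."""

    patient_id: str
    files: dict = field(default_factory=dict)
    label: str = "absent"

    def is_complete(self) -> bool:
        return set(self.files) == set(VALVES)


_PCM_SCALE = {np.dtype(np.int16): 32768.0, np.dtype(np.int32): 2147483648.0}


def read_wav(path) -> AudioSignal:
    """Read a mono PCM or IEEE-float WAV file, rescaled to [-1, 1].

    Integer PCM is divided by its full scale (e.g. int16 by 32768), so a
    full-scale positive sample maps to 32767/32768.  Multi-channel files
    are rejected: each valve is a single channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise PcgIOError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if len(data) == 0:
        raise PcgIOError(f"{path}: zero-length audio")
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32 / float64
        samples = data.astype(np.float64)
    return AudioSignal(samples, int(rate))


def write_wav(path, signal: AudioSignal) -> None:
    """Write as 16-bit PCM; read_wav(write_wav(x)) agrees within 1 LSB."""
    clipped = np.clip(signal.samples, -1.0, 32767.0 / 32768.0)
    pcm = np.round(clipped * 32768.0).astype(np.int16)
    wavfile.write(str(path), signal.rate, pcm)


def resample(signal: AudioSignal, target_rate: int) -> AudioSignal:
    """Polyphase resampling to ``target_rate`` (identity if rates match)."""
    if target_rate == signal.rate:
        return signal
    g = math.gcd(target_rate, signal.rate)
    out = resample_poly(signal.samples, target_rate // g, signal.rate // g)
    return AudioSignal(out, target_rate)


def read_patient_table(path) -> list[PatientRecord]:
    """Parse the 4-column TSV into one PatientRecord per patient.

    Rows with label "unknown" are dropped with a warning (the task is
    binary).  Duplicate (patient_id, valve) pairs, unknown valve codes,
    and unknown labels are errors.  A patient's label is "present" if
    any of their rows is "present".
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["patient_id", "valve", "wav_path", "label"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise PcgIOError(f"{path}: missing columns {missing}")

    table = table.copy()
    table["label"] = table["label"].str.strip().str.lower()
    unknown_mask = table["label"] == "unknown"
    if unknown_mask.any():
        warnings.warn(
            f"{path}: dropping {int(unknown_mask.sum())} rows with label 'unknown'",
            stacklevel=2,
        )
        table = table[~unknown_mask]

    bad_valve = ~table["valve"].isin(VALVES)
    if bad_valve.any():
        raise PcgIOError(f"{path}: unknown valve codes {sorted(table['valve'][bad_valve].unique())}")
    bad_label = ~table["label"].isin(LABELS)
    if bad_label.any():
        raise PcgIOError(f"{path}: unknown labels {sorted(table['label'][bad_label].unique())}")
    dupes = table.duplicated(subset=["patient_id", "valve"])
    if dupes.any():
        pairs = table.loc[dupes, ["patient_id", "valve"]].values.tolist()
        raise PcgIOError(f"{path}: duplicate (patient, valve) pairs {pairs}")

    records = []
    for pid, sub in table.groupby("patient_id", sort=False):
        files = {row.valve: path.parent / row.wav_path for row in sub.itertuples()}
        label = "present" if (sub["label"] == "present").any() else "absent"
        records.append(PatientRecord(patient_id=str(pid), files=files, label=label))
    return records


def filter_complete_patients(records: list[PatientRecord]) -> list[PatientRecord]:
    """Keep only patients with recordings from all four valves, order preserved."""
    return [r for r in records if r.is_complete()]


def convert_circor_metadata(patient_txt_dir, wav_dir=None) -> pd.DataFrame:
    """Best-effort conversion of CirCor-style patient ``.txt`` headers.

    Expects files whose first line is ``<patient_id> <n_locations> <rate>``,
    followed by one line per location starting with the valve code, and a
    ``#Murmur: <Present|Absent|Unknown>`` comment.  Returns a DataFrame in
    this package's TSV dialect (unknown labels preserved for the reader to
    drop).  Purely optional convenience; untouched by the core pipeline.
    """
    patient_txt_dir = Path(patient_txt_dir)
    wav_dir = Path(wav_dir) if wav_dir is not None else patient_txt_dir
    rows = []
    for txt in sorted(patient_txt_dir.glob("*.txt")):
        lines = txt.read_text().splitlines()
        if not lines:
            continue
        pid = lines[0].split()[0]
        label = "unknown"
        for line in lines:
            if line.lower().startswith("#murmur:"):
                label = line.split(":", 1)[1].strip().lower()
        for line in lines[1:]:
            parts = line.split()
            if parts and parts[0] in VALVES:
                wav = next((p for p in parts[1:] if p.endswith(".wav")), f"{pid}_{parts[0]}.wav")
                rows.append(
                    {"patient_id": pid, "valve": parts[0],
                     "wav_path": str(Path(wav_dir.name) / wav) if wav_dir != patient_txt_dir else wav,
                     "label": label}
                )
    return pd.DataFrame(rows, columns=["patient_id", "valve", "wav_path", "label"])
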