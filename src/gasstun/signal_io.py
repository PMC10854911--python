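"""EEG trace containers, file I/O, band-pass filtering and epoch splitting.

A trace is a uniformly sampled single-channel voltage series in microvolts.
Recordings carry two analysis windows in trace time: a conscious *baseline*
window collected while the bird stands on the lift, followed by the gas
*exposure* window that starts when the lift begins to descend.  All onset
times downstream are reported relative to the start of the exposure window.

Two on-disk formats are supported: a two-column delimited text file
(``time_s,uV`` with ``#``-prefixed metadata header lines) and single-channel
EDF (European Data Format, 16-bit).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EEGTrace",
    "EpochSeries",
    "read_signal",
    "write_signal",
    "bandpass",
    "epoch_split",
]

_UNIT_SCALE = {"uv": 1.0, "µv": 1.0, "mv": 1e3, "v": 1e6}


@dataclass
class EEGTrace:
    """Single-channel EEG voltage series with marked analysis windows.

    Parameters
    ----------
    samples : ndarray
        Voltages in microvolts.
    sampling_rate : float
        Sampling rate in Hz.
    baseline_window, exposure_window : tuple of float
        ``(start, end)`` in trace time (seconds).  Baseline must precede
        exposure and the windows may not overlap.
    """

    samples: np.ndarray
    sampling_rate: float
    baseline_window: tuple[float, float]
    exposure_window: tuple[float, float]
    subject_id: str = "bird"
    treatment_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        b0, b1 = self.baseline_window
        e0, e1 = self.exposure_window
        if not (b0 < b1 <= e0 < e1):
            raise ValueError(
                "baseline window must precede exposure window without overlap"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def window_samples(self, window: tuple[float, float]) -> np.ndarray:
        i0 = int(round(window[0] * self.sampling_rate))
        i1 = int(round(window[1] * self.sampling_rate))
        return self.samples[i0:i1]


@dataclass
class EpochSeries:
    """Contiguous fixed-length analysis epochs cut from a trace.

    Epoch start times are phase-relative: epoch 0 of each phase starts at
    0 s within that phase.  ``phase`` is ``"baseline"`` or ``"exposure"``.
    """

    epochs: list[np.ndarray]
    start_times: list[float]
    phases: list[str]
    epoch_length: float
    sampling_rate: float

    def __len__(self) -> int:
        return len(self.epochs)

    def phase_indices(self, phase: str) -> list[int]:
        return [i for i, p in enumerate(self.phases) if p == phase]


# ---------------------------------------------------------------------------
# text format


def _write_text(trace: EEGTrace, path: Path) -> None:
    header = (
        f"# sampling_rate_hz: {trace.sampling_rate!r}\n"
        f"# unit: uV\n"
        f"# baseline_window_s: {trace.baseline_window[0]!r} {trace.baseline_window[1]!r}\n"
        f"# exposure_window_s: {trace.exposure_window[0]!r} {trace.exposure_window[1]!r}\n"
        f"# subject_id: {trace.subject_id}\n"
        f"# treatment: {trace.treatment_label}\n"
        "time_s,uV\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        t = trace.times
        for ti, vi in zip(t, trace.samples):
            fh.write(f"{ti:.6f},{vi:.6f}\n")


def _read_text(path: Path) -> EEGTrace:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    if "sampling_rate_hz" not in meta:
        raise ValueError(f"{path}: missing sampling_rate_hz metadata")
    if "unit" not in meta:
        raise ValueError(f"{path}: missing unit metadata")
    rate = float(meta["sampling_rate_hz"])
    scale = _UNIT_SCALE.get(meta["unit"].lower())
    if scale is None:
        raise ValueError(f"{path}: unknown unit {meta['unit']!r}")
    t = frame.iloc[:, 0].to_numpy(float)
    if t.size >= 3:
        dt = np.diff(t)
        if np.ptp(dt) > 0.01 / rate:
            raise ValueError(f"{path}: non-uniform sampling detected")
    samples = frame.iloc[:, 1].to_numpy(float) * scale

    def _window(key: str, default: tuple[float, float]) -> tuple[float, float]:
        if key not in meta:
            return default
        a, b = meta[key].split()
        return float(a), float(b)

    n = samples.size
    base = _window("baseline_window_s", (0.0, n / rate / 2))
    expo = _window("exposure_window_s", (n / rate / 2, n / rate))
    return EEGTrace(
        samples,
        rate,
        base,
        expo,
        subject_id=meta.get("subject_id", "bird"),
        treatment_label=meta.get("treatment", ""),
    )


# ---------------------------------------------------------------------------
# EDF format (single channel, 16-bit, contiguous)
#
# Layout: one 256-byte static header, one 256-byte signal header, then data
# records of int16 little-endian samples.  Windows and labels are carried in
# the recording-id field so that a write/read round trip is lossless apart
# from amplitude quantisation.

_EDF_RECORD_SECONDS = 1.0


def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _write_edf(trace: EEGTrace, path: Path) -> None:
    fs = trace.sampling_rate
    spr = int(round(fs * _EDF_RECORD_SECONDS))
    if abs(spr - fs * _EDF_RECORD_SECONDS) > 1e-9:
        raise ValueError("sampling rate must yield integer samples per record")
    n_rec = int(np.ceil(trace.samples.size / spr))
    padded = np.zeros(n_rec * spr)
    padded[: trace.samples.size] = trace.samples
    phys_min = float(min(padded.min(), -1.0))
    phys_max = float(max(padded.max(), 1.0))
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * gain + dig_min).astype("<i2")

    rec_id = (
        f"base={trace.baseline_window[0]:g}:{trace.baseline_window[1]:g} "
        f"exp={trace.exposure_window[0]:g}:{trace.exposure_window[1]:g} "
        f"treat={trace.treatment_label}"
    )
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(trace.subject_id, 80),
            _edf_field(rec_id, 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 + 256), 8),
            _edf_field("", 44),
            _edf_field(str(n_rec), 8),
            _edf_field(f"{_EDF_RECORD_SECONDS:g}", 8),
            _edf_field("1", 4),
        ]
    )
    sig_header = b"".join(
        [
            _edf_field("EEG", 16),
            _edf_field("subdermal needle", 80),
            _edf_field("uV", 8),
            _edf_field(f"{phys_min:.6g}"[:8], 8),
            _edf_field(f"{phys_max:.6g}"[:8], 8),
            _edf_field(str(dig_min), 8),
            _edf_field(str(dig_max), 8),
            _edf_field("", 80),
            _edf_field(str(spr), 8),
            _edf_field("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(digital.tobytes())


def _read_edf(path: Path) -> EEGTrace:
    with open(path, "rb") as fh:
        header = fh.read(512)
        if len(header) < 512:
            raise ValueError(f"{path}: truncated EDF header")
        subject = header[8:88].decode("ascii", "replace").strip()
        rec_id = header[88:168].decode("ascii", "replace").strip()
        n_rec = int(header[236:244])
        rec_dur = float(header[244:252])
        n_sig = int(header[252:256])
        if n_sig != 1:
            raise ValueError(f"{path}: expected a single-channel EDF")
        unit = header[256 + 96 : 256 + 104].decode("ascii").strip()
        phys_min = float(header[256 + 104 : 256 + 112])
        phys_max = float(header[256 + 112 : 256 + 120])
        dig_min = float(header[256 + 120 : 256 + 128])
        dig_max = float(header[256 + 128 : 256 + 136])
        spr = int(header[256 + 216 : 256 + 224])
        payload = fh.read()
    expected = n_rec * spr * 2
    if len(payload) < expected:
        raise ValueError(f"{path}: truncated EDF data records")
    digital = np.frombuffer(payload[:expected], dtype="<i2").astype(np.float64)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    scale = _UNIT_SCALE.get(unit.lower())
    if scale is None:
        raise ValueError(f"{path}: unknown physical unit {unit!r}")
    samples = ((digital - dig_min) * gain + phys_min) * scale
    fs = spr / rec_dur

    meta = dict(
        part.split("=", 1) for part in rec_id.split() if "=" in part
    )
    duration = samples.size / fs

    def _win(key: str, default: tuple[float, float]) -> tuple[float, float]:
        if key in meta:
            a, _, b = meta[key].partition(":")
            return float(a), float(b)
        return default

    base = _win("base", (0.0, duration / 2))
    expo = _win("exp", (duration / 2, duration))
    # drop padding introduced to fill the last record
    n_keep = int(round(expo[1] * fs))
    if 0 < n_keep <= samples.size:
        samples = samples[:n_keep]
    return EEGTrace(
        samples, fs, base, expo,
        subject_id=subject, treatment_label=meta.get("treat", ""),
    )


def write_signal(trace: EEGTrace, path: str | Path, format: str | None = None) -> Path:
    """Write a trace as delimited text (``csv``) or EDF (``edf``)."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "csv":
        _write_text(trace, path)
    elif fmt == "edf":
        _write_edf(trace, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_signal(path: str | Path, format: str | None = None) -> EEGTrace:
    """Read a trace from delimited text or EDF; samples are returned in µV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "csv":
        return _read_text(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# filtering and epoching


def bandpass(trace: EEGTrace, low: float = 1.0, high: float = 30.0) -> EEGTrace:
    """Zero-phase Butterworth band-pass filter.

    A 4th-order Butterworth applied forward and backward (`sosfiltfilt`),
    so the effective magnitude response is 8th order and no group delay is
    introduced — detection latencies downstream are therefore unbiased.
    """
    nyq = trace.sampling_rate / 2
    if not 0 < low < high < nyq:
        raise ValueError(
            f"corner frequencies must satisfy 0 < {low} < {high} < {nyq}"
        )
    sos = sps.butter(4, [low, high], btype="bandpass", fs=trace.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return replace(trace, samples=filtered)


def epoch_split(trace: EEGTrace, epoch_length: float = 1.0) -> EpochSeries:
    """Cut both analysis windows into contiguous non-overlapping epochs.

    Each phase yields ``floor(window / epoch_length)`` epochs; trailing
    samples that do not fill an epoch are discarded.  Start times are
    relative to the start of the phase.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    n_per = int(round(epoch_length * trace.sampling_rate))
    epochs: list[np.ndarray] = []
    starts: list[float] = []
    phases: list[str] = []
    for phase, window in (
        ("baseline", trace.baseline_window),
        ("exposure", trace.exposure_window),
    ):
        block = trace.window_samples(window)
        n_epochs = block.size // n_per
        if n_epochs < 1:
            raise ValueError(
                f"{phase} window shorter than one epoch ({epoch_length} s)"
            )
        for k in range(n_epochs):
            epochs.append(block[k * n_per : (k + 1) * n_per])
            starts.append(k * epoch_length)
            phases.append(phase)
    return EpochSeries(epochs, starts, phases, epoch_length, trace.sampling_rate)
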