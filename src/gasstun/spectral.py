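"""Per-epoch power spectra and spectral features (Ptot, F50, F95, bands).

The estimator mirrors the LabChart convention used for poultry stunning
EEG: 1024-point FFT segments, Hamming windowed, 50% segment overlap, zero
frequency removed.  A 1 s epoch at 1 kHz (1000 samples) holds fewer than
1024 samples and degenerates to a single zero-padded segment.

Powers are in µV² per frequency bin, normalised so that the summed power
over the full spectrum approximates the mean square of the signal
(Welch "density" scaling integrated over bin width).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import EpochSeries

__all__ = [
    "BAND_EDGES",
    "PowerSpectrum",
    "SpectralFeatures",
    "SpectralFeatureSeries",
    "power_spectrum",
    "spectral_features",
    "feature_series",
]

#: EEG band edges in Hz, ``band -> (low, high]``.  Delta power is integrated
#: below 4 Hz (effectively 1–4 Hz after the 1–30 Hz band-pass); Gamma runs
#: to 200 Hz or the Nyquist frequency, whichever is lower.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "Delta": (0.0, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 13.0),
    "Beta": (13.0, 32.0),
    "Gamma": (32.0, 200.0),
}

_NFFT = 1024


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray  # Hz, strictly increasing, zero bin removed
    power: np.ndarray        # µV² per bin
    epoch_start_time: float = 0.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, float)
        self.power = np.asarray(self.power, float)
        if self.frequencies.size and self.frequencies[0] <= 0:
            raise ValueError("zero-frequency bin must be removed")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class SpectralFeatures:
    """Spectral summary of one epoch.

    ``defined`` is False when the epoch carried no power, in which case the
    numeric fields are NaN and must not be compared against thresholds.
    """

    ptot: float
    f50: float
    f95: float
    band_fraction: dict[str, float]
    epoch_start_time: float
    phase: str = ""
    defined: bool = True


@dataclass
class SpectralFeatureSeries:
    features: list[SpectralFeatures]

    def __len__(self) -> int:
        return len(self.features)

    def phase(self, phase: str) -> list[SpectralFeatures]:
        return [f for f in self.features if f.phase == phase]

    def to_frame(self):
        import pandas as pd

        rows = []
        for f in self.features:
            row = {
                "epoch_start_s": f.epoch_start_time,
                "phase": f.phase,
                "ptot_uv2": f.ptot,
                "f50_hz": f.f50,
                "f95_hz": f.f95,
                "defined": f.defined,
            }
            row.update(
                {f"{band.lower()}_frac": frac for band, frac in f.band_fraction.items()}
            )
            rows.append(row)
        return pd.DataFrame(rows)


def power_spectrum(
    samples: np.ndarray,
    sampling_rate: float,
    epoch_start_time: float = 0.0,
) -> PowerSpectrum:
    """Welch power spectrum of one epoch.

    Segments of 1024 samples, Hamming windowed, 50% overlap; an epoch
    shorter than 1024 samples is analysed as a single segment zero-padded
    to 1024 points.  The zero-frequency bin is removed.
    """
    samples = np.asarray(samples, float)
    if samples.size == 0:
        raise ValueError("empty epoch")
    if np.any(~np.isfinite(samples)):
        raise ValueError("epoch contains non-finite samples")
    nperseg = min(samples.size, _NFFT)
    freqs, psd = sps.welch(
        samples,
        fs=sampling_rate,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2 if samples.size > _NFFT else 0,
        nfft=_NFFT,
        detrend=False,
        scaling="density",
    )
    power = psd * (sampling_rate / _NFFT)  # µV² per bin
    return PowerSpectrum(freqs[1:], power[1:], epoch_start_time)


def _quantile_frequency(freqs: np.ndarray, cumulative: np.ndarray, q: float) -> float:
    """Smallest grid frequency at which cumulative power reaches q·total."""
    idx = int(np.searchsorted(cumulative, q * cumulative[-1] - 1e-15))
    return float(freqs[min(idx, freqs.size - 1)])


def spectral_features(
    spectrum: PowerSpectrum,
    band_edges: dict[str, tuple[float, float]] | None = None,
    phase: str = "",
) -> SpectralFeatures:
    """Ptot, F50, F95 and band fractions from one power spectrum.

    F50 (F95) is the smallest grid frequency at which cumulative power
    reaches 50% (95%) of total power — left-continuous, deterministic.
    Band fractions are normalised over the power falling inside the defined
    bands, whose upper edge is capped at the Nyquist frequency, so defined
    fractions always sum to one.
    """
    if band_edges is None:
        band_edges = BAND_EDGES
    freqs, power = spectrum.frequencies, spectrum.power
    ptot = float(power.sum())
    if ptot <= 0.0:
        return SpectralFeatures(
            ptot=0.0,
            f50=np.nan,
            f95=np.nan,
            band_fraction={b: np.nan for b in band_edges},
            epoch_start_time=spectrum.epoch_start_time,
            phase=phase,
            defined=False,
        )
    cumulative = np.cumsum(power)
    f50 = _quantile_frequency(freqs, cumulative, 0.50)
    f95 = _quantile_frequency(freqs, cumulative, 0.95)

    nyquist = freqs[-1]
    band_power: dict[str, float] = {}
    for band, (lo, hi) in band_edges.items():
        hi = min(hi, nyquist)
        mask = (freqs > lo) & (freqs <= hi)
        band_power[band] = float(power[mask].sum())
    in_band_total = sum(band_power.values())
    if in_band_total <= 0:
        fractions = {b: np.nan for b in band_edges}
    else:
        fractions = {b: p / in_band_total for b, p in band_power.items()}
    return SpectralFeatures(
        ptot=ptot,
        f50=f50,
        f95=f95,
        band_fraction=fractions,
        epoch_start_time=spectrum.epoch_start_time,
        phase=phase,
    )


def feature_series(
    epochs: EpochSeries,
    band_edges: dict[str, tuple[float, float]] | None = None,
) -> SpectralFeatureSeries:
    """One SpectralFeatures per epoch, order preserved.

    Epochs whose features are undefined (zero power) are kept in place with
    ``defined=False`` rather than dropped, so downstream run-length logic
    sees every epoch.
    """
    out = []
    for block, start, phase in zip(epochs.epochs, epochs.start_times, epochs.phases):
        spec = power_spectrum(block, epochs.sampling_rate, start)
        out.append(spectral_features(spec, band_edges, phase=phase))
    return SpectralFeatureSeries(out)
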