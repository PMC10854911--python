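import numpy as np
import pytest

from gasstun.spectral import SpectralFeatures, SpectralFeatureSeries
from gasstun.synth import EEGSimSpec, simulate_eeg_trace


def make_features(
    f50_values,
    phase="baseline",
    ptot=100.0,
    delta=0.15,
    gamma=0.001,
    start=0.0,
):
    """Hand-built feature series for rule-level tests."""
    feats = []
    for i, f50 in enumerate(f50_values):
        feats.append(
            SpectralFeatures(
                ptot=ptot,
                f50=f50,
                f95=max(f50, 25.0),
                band_fraction={
                    "Delta": delta,
                    "Theta": 0.2,
                    "Alpha": 0.3,
                    "Beta": 1.0 - delta - 0.2 - 0.3 - gamma,
                    "Gamma": gamma,
                },
                epoch_start_time=start + i,
                phase=phase,
            )
        )
    return feats


def series_from_rows(rows):
    """rows: list of dicts with phase, t, f50, delta, ptot (gamma optional)."""
    feats = []
    for r in rows:
        delta = r.get("delta", 0.15)
        gamma = r.get("gamma", 0.001)
        feats.append(
            SpectralFeatures(
                ptot=r.get("ptot", 100.0),
                f50=r["f50"],
                f95=30.0,
                band_fraction={
                    "Delta": delta,
                    "Theta": 0.2,
                    "Alpha": 0.2,
                    "Beta": max(1.0 - delta - 0.4 - gamma, 0.0),
                    "Gamma": gamma,
                },
                epoch_start_time=r["t"],
                phase=r["phase"],
                defined=r.get("defined", True),
            )
        )
    return SpectralFeatureSeries(feats)


@pytest.fixture(scope="session")
def short_bird():
    """One simulated bird with a short exposure, truth (20, 45)."""
    spec = EEGSimSpec(
        baseline_duration=60.0,
        exposure_duration=90.0,
        t_loc_true=20.0,
        t_death_true=45.0,
        seed=11,
    )
    trace, truth = simulate_eeg_trace(spec)
    return trace, truth


@pytest.fixture(scope="session")
def air_bird():
    """Stationary conscious-like trace (no programmed transition)."""
    spec = EEGSimSpec(
        baseline_duration=60.0,
        exposure_duration=90.0,
        treatment_label="AIR",
        seed=12,
    )
    trace, _ = simulate_eeg_trace(spec)
    return trace
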