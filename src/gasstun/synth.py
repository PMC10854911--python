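"""Synthetic EEG traces, behaviour streams and gas profiles with known truth.

No recordings were released with gas-stunning trials of this design, so the
whole pipeline is exercised on simulated data whose ground truth is known.

The EEG model is a sum of independent band-limited Gaussian noise
components, one per EEG band, each scaled to a target band power (µV²).
Consciousness-to-unconsciousness transition: the band powers cross-fade
linearly from a conscious mix (alpha/beta dominated, F50 well above 8 Hz)
to a Delta-dominated mix over ``transition_width`` seconds starting at the
programmed LOC time.  Brain death: the signal amplitude decays
exponentially (time constant ``death_decay_tau``) from the programmed death
time towards an isoelectric residual — band-limited noise at
``isoelectric_level`` µV RMS.  Movement artifacts are sparse high-amplitude
low-frequency (~1.5 Hz) transients injected into the baseline window, which
is what the baseline artifact-exclusion rule downstream removes.

Exposure time zero is the start of the lift descent; the 90 s baseline
precedes it.  Programmed event times are measured from exposure start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .behaviour import (
    ANCHOR_BEHAVIOURS,
    DEFAULT_ETHOGRAM,
    BehaviourEvent,
    BehaviourRecord,
    Ethogram,
)
from .signal_io import EEGTrace

__all__ = [
    "DEFAULT_BASELINE_BAND_POWERS",
    "DEFAULT_UNCONSCIOUS_BAND_POWERS",
    "EEGSimSpec",
    "CohortSpec",
    "simulate_eeg_trace",
    "simulate_cohort",
    "simulate_behaviour_cohort",
    "truncated_normal",
]

#: Conscious-state band powers, µV².  Alpha/beta dominated: F50 ≈ 11 Hz,
#: Delta fraction ≈ 0.15.
DEFAULT_BASELINE_BAND_POWERS: dict[str, float] = {
    "Delta": 15.0,
    "Theta": 15.0,
    "Alpha": 32.0,
    "Beta": 38.0,
}
#: Unconscious-state band powers, µV².  Strongly Delta dominated (deep
#: hypoxic/hypercapnic EEG): F50 ≈ 3 Hz, Delta fraction ≈ 0.90.  The strong
#: dominance gives the per-epoch Delta estimate — which has only a handful
#: of effective degrees of freedom in a 1 s Hamming-windowed epoch — enough
#: margin over the detection thresholds that qualifying runs are not broken
#: by estimation noise.
DEFAULT_UNCONSCIOUS_BAND_POWERS: dict[str, float] = {
    "Delta": 90.0,
    "Theta": 7.0,
    "Alpha": 2.0,
    "Beta": 1.0,
}

# Synthesis bands are clipped to the 1-30 Hz analysis pass-band so that the
# programmed band powers survive the pipeline's digital filter.
_SYNTH_BANDS: dict[str, tuple[float, float]] = {
    "Delta": (1.0, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 13.0),
    "Beta": (13.0, 30.0),
}


@dataclass
class EEGSimSpec:
    """Parameters of one simulated EEG trace.

    Times are seconds from exposure start; ``t_loc_true`` / ``t_death_true``
    may be None for a stationary conscious-like trace (air control).
    """

    sampling_rate: float = 1000.0
    baseline_duration: float = 90.0
    exposure_duration: float = 240.0
    t_loc_true: float | None = None
    t_death_true: float | None = None
    transition_width: float = 3.0
    baseline_band_powers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_BAND_POWERS)
    )
    unconscious_band_powers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UNCONSCIOUS_BAND_POWERS)
    )
    isoelectric_level: float = 1.0  # µV RMS of the residual after death
    death_decay_tau: float = 1.0  # s, amplitude e-folding after death
    artifact_rate: float = 2.0  # events/min in the baseline window
    artifact_amplitude: float = 300.0  # µV
    subject_id: str = "bird"
    treatment_label: str = ""
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.baseline_duration <= 0 or self.exposure_duration <= 0:
            raise ValueError("durations must be positive")
        for name, powers in (
            ("baseline", self.baseline_band_powers),
            ("unconscious", self.unconscious_band_powers),
        ):
            if any(p < 0 for p in powers.values()):
                raise ValueError(f"{name} band powers must be non-negative")
            unknown = set(powers) - set(_SYNTH_BANDS)
            if unknown:
                raise ValueError(f"unknown {name} bands: {sorted(unknown)}")
        if self.transition_width < 0:
            raise ValueError("transition_width must be non-negative")
        if self.isoelectric_level < 0 or self.artifact_rate < 0:
            raise ValueError("levels and rates must be non-negative")
        t_loc, t_death = self.t_loc_true, self.t_death_true
        if t_loc is not None and not 0 < t_loc < self.exposure_duration:
            raise ValueError("t_loc_true must lie inside the exposure window")
        if t_death is not None:
            if not 0 < t_death < self.exposure_duration:
                raise ValueError("t_death_true must lie inside the exposure window")
            if t_loc is not None and t_death <= t_loc:
                raise ValueError("t_death_true must exceed t_loc_true")


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (Hz)."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    return x / x.std()


def simulate_eeg_trace(spec: EEGSimSpec) -> tuple[EEGTrace, dict[str, float | None]]:
    """Synthesise one EEG trace; returns the trace and its ground truth.

    Identical specs (including seed) give bit-identical sample arrays.
    """
    spec.validate()
    fs = spec.sampling_rate
    n_base = int(round(spec.baseline_duration * fs))
    n_exp = int(round(spec.exposure_duration * fs))
    n = n_base + n_exp
    rng = np.random.default_rng(spec.seed)

    # time from exposure start, negative during baseline
    t = (np.arange(n) - n_base) / fs

    # per-band linear cross-fade of power starting at the LOC time
    if spec.t_loc_true is None:
        mix = np.zeros(n)
    else:
        width = max(spec.transition_width, 1e-9)
        mix = np.clip((t - spec.t_loc_true) / width, 0.0, 1.0)

    x = np.zeros(n)
    for band, edges in _SYNTH_BANDS.items():
        p0 = spec.baseline_band_powers.get(band, 0.0)
        p1 = spec.unconscious_band_powers.get(band, 0.0)
        power_t = p0 + (p1 - p0) * mix
        x += np.sqrt(power_t) * _band_noise(rng, n, fs, edges)

    # exponential amplitude decay to the isoelectric residual after death
    if spec.t_death_true is not None:
        decay = np.ones(n)
        after = t >= spec.t_death_true
        decay[after] = np.exp(-(t[after] - spec.t_death_true) / spec.death_decay_tau)
        x *= decay
    if spec.isoelectric_level > 0:
        x += spec.isoelectric_level * _band_noise(rng, n, fs, (1.0, 30.0))

    # sparse low-frequency movement artifacts in the baseline window
    n_art = rng.poisson(spec.artifact_rate * spec.baseline_duration / 60.0)
    art_dur = 0.8
    for _ in range(n_art):
        start = rng.uniform(0.0, spec.baseline_duration - art_dur)
        i0 = int(start * fs)
        m = int(art_dur * fs)
        tt = np.arange(m) / fs
        pulse = (
            spec.artifact_amplitude
            * np.hanning(m)
            * np.sin(2 * np.pi * 1.5 * tt + rng.uniform(0, 2 * np.pi))
        )
        x[i0 : i0 + m] += pulse

    trace = EEGTrace(
        samples=x,
        sampling_rate=fs,
        baseline_window=(0.0, spec.baseline_duration),
        exposure_window=(spec.baseline_duration, spec.baseline_duration + spec.exposure_duration),
        subject_id=spec.subject_id,
        treatment_label=spec.treatment_label,
    )
    truth = {"t_loc_true": spec.t_loc_true, "t_death_true": spec.t_death_true}
    return trace, truth


# ---------------------------------------------------------------------------
# cohorts


def truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size: int
) -> np.ndarray:
    """Truncated normal draws on (low, high] via scipy's truncnorm."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        if not low < mean <= high:
            raise ValueError("degenerate distribution outside truncation bounds")
        return np.full(size, float(mean))
    a, b = (low - mean) / sd, (high - mean) / sd
    return spstats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


@dataclass
class CohortSpec:
    """A treatment group of simulated birds.

    ``behaviour_rate_table`` maps phase ("pre_lop" / "post_lop") to
    ``{behaviour: (events_per_min, mean_duration_s)}``; point behaviours
    take ``mean_duration_s = 0``.
    """

    n_birds: int
    treatment_label: str = "40C60N"
    loc_time_distribution: tuple[float, float] = (25.7, 7.0)
    death_time_distribution: tuple[float, float] = (65.8, 14.1)
    behaviour_rate_table: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    exposure_duration: float = 240.0
    seed: int = 0

    def validate(self, ethogram: Ethogram = DEFAULT_ETHOGRAM) -> None:
        if self.n_birds < 1:
            raise ValueError("n_birds must be at least 1")
        for dist_name, (mean, sd) in (
            ("loc", self.loc_time_distribution),
            ("death", self.death_time_distribution),
        ):
            if sd < 0:
                raise ValueError(f"{dist_name} time sd must be non-negative")
        if self.death_time_distribution[0] <= self.loc_time_distribution[0]:
            raise ValueError("mean death time must exceed mean LOC time")
        for phase, table in self.behaviour_rate_table.items():
            if phase not in ("pre_lop", "post_lop"):
                raise ValueError(f"unknown phase {phase!r}")
            for name, (rate, dur) in table.items():
                if name not in ethogram.point + ethogram.state:
                    raise ValueError(f"unknown behaviour {name!r} in rate table")
                if rate < 0 or dur < 0:
                    raise ValueError("rates and durations must be non-negative")


def simulate_cohort(
    cohort: CohortSpec, **eeg_kwargs
) -> tuple[list[tuple[EEGTrace, dict]], pd.DataFrame]:
    """Simulate EEG traces for a cohort; truth times are truncated-normal.

    Per-bird LOC and death times are drawn from the cohort distributions
    truncated to (0, exposure]; a bird whose death draw does not exceed its
    LOC draw is redrawn.  Returns the traces with per-bird truth and a
    truth table (one row per bird).
    """
    cohort.validate()
    if "exposure_duration" in eeg_kwargs:
        raise ValueError("set exposure_duration on the CohortSpec, not per trace")
    rng = np.random.default_rng(cohort.seed)
    loc_mean, loc_sd = cohort.loc_time_distribution
    death_mean, death_sd = cohort.death_time_distribution
    expo = cohort.exposure_duration

    # unconsciousness precedes brain death by a physiological margin: gas
    # trials report death onsets well over ten seconds after LOC, so each
    # bird's death time is drawn conditionally on (its LOC + min_gap, expo)
    min_gap = 8.0
    if expo <= min_gap + 2.0:
        raise ValueError("exposure too short for distinct LOC and death onsets")
    t_loc = truncated_normal(
        rng, loc_mean, loc_sd, 0.0, expo - min_gap - 1.0, cohort.n_birds
    )
    t_death = np.array(
        [
            truncated_normal(
                rng, death_mean, death_sd, t_loc[i] + min_gap, expo - 1e-6, 1
            )[0]
            for i in range(cohort.n_birds)
        ]
    )

    bird_seeds = rng.integers(0, 2**31 - 1, size=cohort.n_birds)
    out = []
    rows = []
    for i in range(cohort.n_birds):
        subject = f"{cohort.treatment_label}_{i:03d}"
        spec = EEGSimSpec(
            t_loc_true=float(t_loc[i]),
            t_death_true=float(t_death[i]),
            exposure_duration=expo,
            subject_id=subject,
            treatment_label=cohort.treatment_label,
            seed=int(bird_seeds[i]),
            **eeg_kwargs,
        )
        out.append(simulate_eeg_trace(spec))
        rows.append(
            {
                "subject": subject,
                "treatment": cohort.treatment_label,
                "t_loc_true_s": float(t_loc[i]),
                "t_death_true_s": float(t_death[i]),
            }
        )
    return out, pd.DataFrame(rows)


def simulate_behaviour_cohort(
    cohort: CohortSpec, ethogram: Ethogram = DEFAULT_ETHOGRAM
) -> list[BehaviourRecord]:
    """Simulate per-bird ethogram event streams.

    Each bird gets exactly one LOP and one motionless anchor
    (LOP < motionless <= exposure end, drawn from the cohort's LOC/death
    distributions).  Event counts per behaviour and phase are Poisson with
    the configured rate over the phase duration; point events occur at
    uniform times within the phase, state events start uniformly and last
    an exponential time with the configured mean (clipped at the phase
    end).
    """
    cohort.validate(ethogram)
    rng = np.random.default_rng(cohort.seed)
    expo = cohort.exposure_duration
    loc_mean, loc_sd = cohort.loc_time_distribution
    death_mean, death_sd = cohort.death_time_distribution

    t_lop = truncated_normal(rng, loc_mean, loc_sd, 0.0, expo, cohort.n_birds)
    t_mot = truncated_normal(rng, death_mean, death_sd, 0.0, expo, cohort.n_birds)
    records = []
    for i in range(cohort.n_birds):
        lop = float(t_lop[i])
        mot = float(max(t_mot[i], lop + 1e-3))
        events: list[BehaviourEvent] = []
        for phase, (lo, hi) in (("pre_lop", (0.0, lop)), ("post_lop", (lop, mot))):
            table = cohort.behaviour_rate_table.get(phase, {})
            span = hi - lo
            for name, (rate, mean_dur) in table.items():
                count = rng.poisson(rate * span / 60.0)
                starts = np.sort(rng.uniform(lo, hi, size=count))
                for s in starts:
                    if ethogram.kind(name) == "POINT":
                        events.append(BehaviourEvent(name, float(s), float(s)))
                    else:
                        dur = rng.exponential(mean_dur) if mean_dur > 0 else 0.0
                        stop = float(min(s + max(dur, 1e-3), hi))
                        events.append(BehaviourEvent(name, float(s), stop))
        events.sort(key=lambda e: (e.start, e.behaviour))
        records.append(
            BehaviourRecord(
                subject_id=f"{cohort.treatment_label}_beh_{i:03d}",
                treatment_label=cohort.treatment_label,
                events=events,
                t_lop=lop,
                t_motionless=mot,
                cycle_id=f"cycle_{i // 3:02d}",  # three behaviour birds per dip
            )
        )
    return records
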