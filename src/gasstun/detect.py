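"""Onset-of-unconsciousness and brain-death detection from spectral features.

The procedure works on per-epoch spectral features of a 1-30 Hz band-passed
trace.  Per bird:

1. *Baseline*: medians of Ptot, F50 and the Delta fraction over the
   baseline epochs, after discarding epochs whose F50 falls below 4 Hz
   (low-frequency movement artifacts).
2. *Loss of consciousness (LOC)*: the first run of at least ``persistence``
   (default 4) consecutive exposure epochs in which F50 has dropped below
   50% of the baseline median and/or the Delta fraction has risen at least
   65% above the baseline median; the onset is the start time of that run.
3. *Brain death, spectral*: same run logic on Ptot dropping by 90% of the
   baseline median.
4. *Brain death, isoelectric*: first run of epochs with Ptot below an
   absolute 2.5 µV² level — the spectral surrogate of the visually flat
   trace; independent of the baseline.
5. *Signal quality*: the Gamma band (32-200 Hz) holds instrument and muscle
   noise; traces whose maximum per-epoch Gamma fraction reaches 2% are
   flagged.

Epochs with undefined features (zero power) break qualifying runs rather
than extending them: detection is conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import EEGTrace, bandpass, epoch_split
from .spectral import SpectralFeatureSeries, feature_series

__all__ = [
    "DetectionConfig",
    "BaselineSummary",
    "DetectionResult",
    "NoBaselineError",
    "compute_baseline",
    "detect_loc",
    "detect_death_spectral",
    "detect_isoelectric",
    "gamma_quality",
    "analyze_bird",
]


class NoBaselineError(ValueError):
    """Raised when every baseline epoch is rejected as artifact."""


@dataclass
class DetectionConfig:
    """Thresholds of the detection rules.

    ``f50_ratio_threshold``: LOC criterion A — epoch F50 below this fraction
    of the baseline median.
    ``delta_increase_threshold``: LOC criterion B — epoch Delta fraction
    above (1 + threshold) x the baseline median (a 65% relative increase by
    default).  ``delta_mode='absolute'`` switches B to an absolute Delta
    fraction threshold instead.
    ``loc_rule_combiner``: 'both' requires A and B in the same epoch
    (default), 'either' accepts A or B.
    ``ptot_drop_threshold``: death criterion — epoch Ptot below
    (1 − threshold) x the baseline median.
    ``isoelectric_ptot_level``: absolute Ptot level (µV²) of the
    isoelectric rule.
    Each rule needs ``persistence`` consecutive qualifying epochs.
    """

    f50_ratio_threshold: float = 0.50
    delta_increase_threshold: float = 0.65
    ptot_drop_threshold: float = 0.90
    persistence: int = 4
    isoelectric_ptot_level: float = 2.5
    isoelectric_persistence: int = 4
    loc_rule_combiner: str = "both"
    delta_mode: str = "relative"
    baseline_f50_artifact_floor: float = 4.0
    high_gamma_fraction: float = 0.02

    def validate(self) -> None:
        for name in ("f50_ratio_threshold", "ptot_drop_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.delta_increase_threshold <= 0:
            raise ValueError("delta_increase_threshold must be positive")
        if self.persistence < 1 or self.isoelectric_persistence < 1:
            raise ValueError("persistence must be at least 1")
        if self.loc_rule_combiner not in ("either", "both"):
            raise ValueError("loc_rule_combiner must be 'either' or 'both'")
        if self.delta_mode not in ("relative", "absolute"):
            raise ValueError("delta_mode must be 'relative' or 'absolute'")


@dataclass
class BaselineSummary:
    median_ptot: float
    median_f50: float
    median_delta_fraction: float
    n_epochs_used: int
    n_epochs_excluded: int


@dataclass
class DetectionResult:
    subject_id: str
    treatment_label: str
    t_loc: float | None
    t_death_spectral: float | None
    t_death_isoelectric: float | None
    gamma_max_fraction: float
    gamma_mean_fraction: float
    qc_flags: set[str] = field(default_factory=set)
    baseline: BaselineSummary | None = None


def compute_baseline(
    series: SpectralFeatureSeries, config: DetectionConfig | None = None
) -> BaselineSummary:
    """Artifact-cleaned per-bird baseline medians.

    Baseline epochs with F50 below the artifact floor (default 4 Hz) are
    movement artifacts and are excluded, as are epochs with undefined
    features.  Raises :class:`NoBaselineError` when nothing remains.
    """
    config = config or DetectionConfig()
    base = series.phase("baseline")
    if not base:
        raise NoBaselineError("series contains no baseline epochs")
    kept = [
        f for f in base if f.defined and f.f50 >= config.baseline_f50_artifact_floor
    ]
    if not kept:
        raise NoBaselineError("all baseline epochs rejected as artifact")
    return BaselineSummary(
        median_ptot=float(np.median([f.ptot for f in kept])),
        median_f50=float(np.median([f.f50 for f in kept])),
        median_delta_fraction=float(np.median([f.band_fraction["Delta"] for f in kept])),
        n_epochs_used=len(kept),
        n_epochs_excluded=len(base) - len(kept),
    )


def _first_run_start(
    times: list[float], qualifies: list[bool], persistence: int
) -> float | None:
    """Start time of the first run of >= persistence qualifying epochs."""
    run = 0
    for i, ok in enumerate(qualifies):
        run = run + 1 if ok else 0
        if run >= persistence:
            return times[i - persistence + 1]
    return None


def detect_loc(
    series: SpectralFeatureSeries,
    baseline: BaselineSummary,
    config: DetectionConfig | None = None,
) -> float | None:
    """Onset of loss of consciousness, or None if undetected."""
    config = config or DetectionConfig()
    config.validate()
    expo = series.phase("exposure")
    f50_thr = config.f50_ratio_threshold * baseline.median_f50
    if config.delta_mode == "relative":
        delta_thr = (1.0 + config.delta_increase_threshold) * baseline.median_delta_fraction
    else:
        delta_thr = config.delta_increase_threshold
    qualifies = []
    for f in expo:
        if not f.defined:
            qualifies.append(False)
            continue
        crit_a = f.f50 < f50_thr
        crit_b = f.band_fraction["Delta"] > delta_thr
        qualifies.append(
            (crit_a and crit_b) if config.loc_rule_combiner == "both" else (crit_a or crit_b)
        )
    return _first_run_start(
        [f.epoch_start_time for f in expo], qualifies, config.persistence
    )


def detect_death_spectral(
    series: SpectralFeatureSeries,
    baseline: BaselineSummary,
    config: DetectionConfig | None = None,
) -> float | None:
    """Onset of brain death by total-power collapse, or None."""
    config = config or DetectionConfig()
    config.validate()
    expo = series.phase("exposure")
    thr = (1.0 - config.ptot_drop_threshold) * baseline.median_ptot
    qualifies = [f.defined and f.ptot < thr for f in expo]
    return _first_run_start(
        [f.epoch_start_time for f in expo], qualifies, config.persistence
    )


def detect_isoelectric(
    series: SpectralFeatureSeries, config: DetectionConfig | None = None
) -> float | None:
    """Onset of the isoelectric (near-flat) pattern, or None.

    Uses an absolute Ptot level, so no baseline is needed; epochs with
    undefined features (identically zero power) do qualify — a flat zero
    trace is the extreme isoelectric case.
    """
    config = config or DetectionConfig()
    expo = series.phase("exposure")
    qualifies = [(not f.defined) or f.ptot < config.isoelectric_ptot_level for f in expo]
    return _first_run_start(
        [f.epoch_start_time for f in expo],
        qualifies,
        config.isoelectric_persistence,
    )


def gamma_quality(
    series: SpectralFeatureSeries, config: DetectionConfig | None = None
) -> tuple[float, float, bool]:
    """(max, mean) Gamma-band fraction over all epochs and the quality flag.

    The flag is raised when the maximum reaches the 2% bound, or when any
    epoch has undefined features (no power at all is itself suspicious in a
    raw recording).
    """
    config = config or DetectionConfig()
    if not series.features:
        raise ValueError("empty feature series")
    fracs = [f.band_fraction["Gamma"] for f in series.features if f.defined]
    any_undefined = any(not f.defined for f in series.features)
    if not fracs:
        return float("nan"), float("nan"), True
    gmax, gmean = float(np.max(fracs)), float(np.mean(fracs))
    return gmax, gmean, gmax >= config.high_gamma_fraction or any_undefined


def analyze_bird(
    trace: EEGTrace,
    config: DetectionConfig | None = None,
    band: tuple[float, float] = (1.0, 30.0),
    epoch_length: float = 1.0,
) -> DetectionResult:
    """Full per-bird procedure: filter, epoch, features, baseline, detect.

    Detection failures turn into qc flags rather than exceptions, so a
    cohort run always yields one result row per bird.
    """
    config = config or DetectionConfig()
    config.validate()
    filtered = bandpass(trace, *band)
    series = feature_series(epoch_split(filtered, epoch_length))
    flags: set[str] = set()
    t_loc = t_death = None
    baseline = None
    try:
        baseline = compute_baseline(series, config)
    except NoBaselineError:
        flags.add("no_baseline")
    if baseline is not None:
        t_loc = detect_loc(series, baseline, config)
        t_death = detect_death_spectral(series, baseline, config)
    t_iso = detect_isoelectric(series, config)
    gmax, gmean, bad_gamma = gamma_quality(series, config)
    if bad_gamma:
        flags.add("high_gamma")
    if t_loc is None:
        flags.add("undetected_loc")
    if t_death is None:
        flags.add("undetected_death")
    if t_loc is not None and t_death is not None and t_death < t_loc:
        flags.add("death_before_loc")
    return DetectionResult(
        subject_id=trace.subject_id,
        treatment_label=trace.treatment_label,
        t_loc=t_loc,
        t_death_spectral=t_death,
        t_death_isoelectric=t_iso,
        gamma_max_fraction=gmax,
        gamma_mean_fraction=gmean,
        qc_flags=flags,
        baseline=baseline,
    )
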