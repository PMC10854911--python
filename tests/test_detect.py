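import numpy as np
import pytest

from gasstun.detect import (
    BaselineSummary,
    DetectionConfig,
    NoBaselineError,
    analyze_bird,
    compute_baseline,
    detect_death_spectral,
    detect_isoelectric,
    detect_loc,
    gamma_quality,
)
from gasstun.signal_io import bandpass, epoch_split
from gasstun.spectral import feature_series
from gasstun.synth import CohortSpec, EEGSimSpec, simulate_cohort, simulate_eeg_trace

from conftest import series_from_rows


def baseline_rows(f50=20.0, delta=0.20, ptot=200.0, n=10):
    return [
        {"phase": "baseline", "t": float(i), "f50": f50, "delta": delta, "ptot": ptot}
        for i in range(n)
    ]


class TestBaseline:
    def test_low_f50_epochs_excluded(self):
        rows = [
            {"phase": "baseline", "t": t, "f50": f}
            for t, f in enumerate([20.0, 3.5, 18.0, 22.0])
        ]
        summary = compute_baseline(series_from_rows(rows))
        assert summary.n_epochs_excluded == 1
        assert summary.n_epochs_used == 3
        assert summary.median_f50 == 20.0

    def test_clean_baseline_keeps_everything(self):
        summary = compute_baseline(series_from_rows(baseline_rows()))
        assert summary.n_epochs_excluded == 0
        assert summary.median_ptot == 200.0
        assert summary.median_delta_fraction == 0.20

    def test_all_artifact_raises(self):
        rows = [{"phase": "baseline", "t": t, "f50": 2.0} for t in range(5)]
        with pytest.raises(NoBaselineError):
            compute_baseline(series_from_rows(rows))

    def test_no_baseline_phase_raises(self):
        rows = [{"phase": "exposure", "t": 0.0, "f50": 20.0}]
        with pytest.raises(NoBaselineError):
            compute_baseline(series_from_rows(rows))


def loc_series(
    n_pre=15, n_post=10, pre=None, post=None
):
    pre = pre or {"f50": 18.0, "delta": 0.22}
    post = post or {"f50": 8.0, "delta": 0.50}
    rows = baseline_rows()
    for i in range(n_pre):
        rows.append({"phase": "exposure", "t": float(i), **pre})
    for i in range(n_pre, n_pre + n_post):
        rows.append({"phase": "exposure", "t": float(i), **post})
    return series_from_rows(rows)


class TestLocRule:
    @pytest.mark.parametrize("combiner", ["either", "both"])
    def test_forced_onset_at_15s(self, combiner):
        series = loc_series()
        baseline = compute_baseline(series)
        cfg = DetectionConfig(loc_rule_combiner=combiner)
        assert detect_loc(series, baseline, cfg) == 15.0

    def test_run_shorter_than_persistence_undetected(self):
        series = loc_series(n_post=3)
        baseline = compute_baseline(series)
        assert detect_loc(series, baseline, DetectionConfig()) is None

    def test_undefined_epoch_breaks_run(self):
        rows = baseline_rows()
        for i in range(8):
            rows.append(
                {
                    "phase": "exposure",
                    "t": float(i),
                    "f50": 8.0,
                    "delta": 0.50,
                    "defined": i != 2,  # gap inside the first qualifying run
                }
            )
        series = series_from_rows(rows)
        baseline = compute_baseline(series)
        assert detect_loc(series, baseline, DetectionConfig()) == 3.0

    def test_absolute_delta_mode(self):
        series = loc_series(post={"f50": 8.0, "delta": 0.70})
        baseline = compute_baseline(series)
        cfg = DetectionConfig(delta_mode="absolute", delta_increase_threshold=0.65)
        assert detect_loc(series, baseline, cfg) == 15.0

    def test_both_never_earlier_than_either(self):
        # delta rises three epochs before F50 falls
        rows = baseline_rows()
        for i in range(12):
            f50 = 18.0 if i < 8 else 8.0
            delta = 0.50 if i >= 5 else 0.22
            rows.append({"phase": "exposure", "t": float(i), "f50": f50, "delta": delta})
        series = series_from_rows(rows)
        baseline = compute_baseline(series)
        t_either = detect_loc(series, baseline, DetectionConfig(loc_rule_combiner="either"))
        t_both = detect_loc(series, baseline, DetectionConfig(loc_rule_combiner="both"))
        assert t_either == 5.0
        assert t_both == 8.0
        assert t_both >= t_either

    def test_persistence_monotonicity(self):
        series = loc_series()
        baseline = compute_baseline(series)
        times = [
            detect_loc(series, baseline, DetectionConfig(persistence=p))
            for p in (1, 2, 4, 6)
        ]
        assert all(a <= b for a, b in zip(times, times[1:]))

    def test_f50_threshold_monotonicity(self):
        # lowering the F50 ratio threshold never yields an earlier onset
        rows = baseline_rows()
        for i in range(20):
            rows.append(
                {"phase": "exposure", "t": float(i), "f50": 18.0 - 0.8 * i, "delta": 0.1}
            )
        series = series_from_rows(rows)
        baseline = compute_baseline(series)
        prev = None
        for thr in (0.8, 0.6, 0.5, 0.3):
            cfg = DetectionConfig(
                f50_ratio_threshold=thr, loc_rule_combiner="either"
            )
            t = detect_loc(series, baseline, cfg)
            if prev is not None and t is not None:
                assert t >= prev
            prev = t if t is not None else prev


class TestDeathRules:
    def test_ptot_collapse_at_60s(self):
        rows = baseline_rows()
        for i in range(80):
            rows.append(
                {"phase": "exposure", "t": float(i), "f50": 10.0,
                 "ptot": 150.0 if i < 60 else 15.0}
            )
        series = series_from_rows(rows)
        baseline = compute_baseline(series)
        assert detect_death_spectral(series, baseline, DetectionConfig()) == 60.0

    def test_oscillating_ptot_undetected(self):
        rows = baseline_rows()
        for i in range(40):
            rows.append(
                {"phase": "exposure", "t": float(i), "f50": 10.0,
                 "ptot": 25.0 if i % 2 else 15.0}
            )
        series = series_from_rows(rows)
        baseline = compute_baseline(series)
        assert detect_death_spectral(series, baseline, DetectionConfig()) is None

    def test_isoelectric_tail_at_70s(self):
        rows = baseline_rows()
        for i in range(90):
            rows.append(
                {"phase": "exposure", "t": float(i), "f50": 5.0,
                 "ptot": 100.0 if i < 70 else 2.0}
            )
        assert detect_isoelectric(series_from_rows(rows), DetectionConfig()) == 70.0

    def test_isoelectric_never_low_undetected(self):
        rows = baseline_rows()
        for i in range(90):
            rows.append({"phase": "exposure", "t": float(i), "f50": 5.0, "ptot": 30.0})
        assert detect_isoelectric(series_from_rows(rows), DetectionConfig()) is None

    def test_simulated_isoelectric_decay_detected_promptly(self):
        spec = EEGSimSpec(t_loc_true=25.0, t_death_true=66.0, seed=9)
        trace, _ = simulate_eeg_trace(spec)
        series = feature_series(epoch_split(bandpass(trace)))
        t = detect_isoelectric(series, DetectionConfig())
        assert t is not None and 66.0 <= t <= 72.0

    def test_isoelectric_not_before_spectral_death_on_decay(self):
        # the 90% relative drop fires before the absolute 2.5 µV² level
        # whenever baseline power is well above 25 µV²
        for seed in (1, 2, 3):
            spec = EEGSimSpec(t_loc_true=20.0, t_death_true=50.0,
                              exposure_duration=90.0, seed=seed)
            trace, _ = simulate_eeg_trace(spec)
            series = feature_series(epoch_split(bandpass(trace)))
            baseline = compute_baseline(series)
            assert baseline.median_ptot > 25.0
            t_spec = detect_death_spectral(series, baseline, DetectionConfig())
            t_iso = detect_isoelectric(series, DetectionConfig())
            assert t_spec is not None and t_iso is not None
            assert t_iso >= t_spec


class TestGammaQuality:
    def test_filtered_synthetic_trace_is_clean(self, short_bird):
        trace, _ = short_bird
        series = feature_series(epoch_split(bandpass(trace)))
        gmax, gmean, flagged = gamma_quality(series)
        assert gmax < 0.02
        assert gmean <= gmax
        assert not flagged

    def test_unfiltered_high_frequency_tone_flagged(self):
        spec = EEGSimSpec(baseline_duration=10.0, exposure_duration=10.0, seed=4,
                          artifact_rate=0.0)
        trace, _ = simulate_eeg_trace(spec)
        t = trace.times
        noisy = trace.samples + 8.0 * np.sin(2 * np.pi * 60.0 * t)
        trace.samples = noisy
        series = feature_series(epoch_split(trace))  # no band-pass applied
        gmax, _, flagged = gamma_quality(series)
        assert flagged and gmax >= 0.02

    def test_zero_trace_flagged_undefined(self):
        rows = [
            {"phase": "exposure", "t": float(i), "f50": np.nan, "ptot": 0.0,
             "defined": False}
            for i in range(5)
        ]
        gmax, gmean, flagged = gamma_quality(series_from_rows(rows))
        assert np.isnan(gmax) and flagged


class TestAnalyzeBird:
    def test_programmed_truth_recovered(self):
        spec = EEGSimSpec(t_loc_true=20.0, t_death_true=65.0, seed=6)
        trace, _ = simulate_eeg_trace(spec)
        result = analyze_bird(trace)
        assert 20.0 <= result.t_loc <= 24.0
        assert 65.0 <= result.t_death_spectral <= 71.0
        assert result.t_death_isoelectric >= result.t_death_spectral
        assert "high_gamma" not in result.qc_flags

    def test_air_trace_undetected_and_clean(self, air_bird):
        result = analyze_bird(air_bird)
        assert result.t_loc is None
        assert result.t_death_spectral is None
        assert result.t_death_isoelectric is None
        assert result.qc_flags <= {"undetected_loc", "undetected_death"}

    def test_all_artifact_baseline_flagged(self):
        # baseline power entirely in Delta: every baseline epoch has F50 < 4
        spec = EEGSimSpec(
            baseline_band_powers={"Delta": 100.0, "Theta": 0.0, "Alpha": 0.0, "Beta": 0.0},
            t_loc_true=20.0,
            baseline_duration=20.0,
            exposure_duration=40.0,
            artifact_rate=0.0,
            seed=7,
        )
        trace, _ = simulate_eeg_trace(spec)
        result = analyze_bird(trace)
        assert "no_baseline" in result.qc_flags
        assert result.t_loc is None and result.t_death_spectral is None

    def test_determinism(self, short_bird):
        trace, _ = short_bird
        a = analyze_bird(trace)
        b = analyze_bird(trace)
        assert (a.t_loc, a.t_death_spectral, a.t_death_isoelectric) == (
            b.t_loc, b.t_death_spectral, b.t_death_isoelectric,
        )

    def test_parameter_recovery_small_cohort(self):
        cohort = CohortSpec(n_birds=30, seed=17)
        pairs, _ = simulate_cohort(cohort)
        errors = []
        cfg = DetectionConfig()
        for trace, truth in pairs:
            r = analyze_bird(trace, cfg)
            assert r.t_loc is not None
            errors.append(r.t_loc - truth["t_loc_true"])
        errors = np.array(errors)
        assert 0.0 <= errors.mean() <= cfg.persistence
        assert errors.std() <= 3.0 + 2.0  # transition width + 2 s

    def test_invalid_config_rejected(self, short_bird):
        with pytest.raises(ValueError):
            analyze_bird(short_bird[0], DetectionConfig(f50_ratio_threshold=1.5))
        with pytest.raises(ValueError):
            analyze_bird(short_bird[0], DetectionConfig(persistence=0))
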