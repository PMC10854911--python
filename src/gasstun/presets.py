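"""Study parameterisation of the three gas treatments (plus an air control).

Onset-time distributions and behaviour rates below encode the published
group summaries of a pit-type controlled-atmosphere stunning trial in
broiler chickens: EEG-derived loss-of-consciousness and brain-death times
(mean ± sd, seconds from lift-descent start), behavioural loss-of-posture /
motionlessness times, and per-behaviour event counts and state durations
before and after loss of posture.  Event counts are converted to rates per
minute using the mean phase duration; state durations to a mean seconds per
event.

For 40C90C no usable EEG was obtained in the source trial, so its EEG
distributions fall back on the behavioural proxies (LOP for LOC,
motionlessness for death).  For 20C80N the spectral death estimate was
inflated by signal degradation at low power, so the generator's death time
uses the visually identified isoelectric onset (66.3 ± 8.1 s) instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["TreatmentPreset", "TREATMENT_PRESETS"]


def _rates(phase_duration_s: float, counts: dict[str, float],
           durations: dict[str, float]) -> dict[str, tuple[float, float]]:
    """events/bird and total state seconds/bird -> (events/min, s/event)."""
    out = {}
    for name, n in counts.items():
        per_min = n / (phase_duration_s / 60.0)
        mean_dur = durations.get(name, 0.0) / n if n > 0 else 0.0
        out[name] = (per_min, mean_dur)
    return out


@dataclass(frozen=True)
class TreatmentPreset:
    label: str
    loc_time: tuple[float, float]        # EEG LOC mean, sd (s)
    death_time: tuple[float, float]      # EEG death mean, sd (s)
    lop_time: tuple[float, float]        # behavioural LOP mean, sd (s)
    motionless_time: tuple[float, float]
    n_eeg: int = 0                       # usable EEG traces in the source trial
    n_behaviour: int = 0
    behaviour_rates: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)


TREATMENT_PRESETS: dict[str, TreatmentPreset] = {
    "40C90C": TreatmentPreset(
        label="40C90C",
        # no usable EEG in the source trial: behavioural proxies stand in
        loc_time=(59.2, 21.9),
        death_time=(168.8, 27.2),
        lop_time=(59.2, 21.9),
        motionless_time=(168.8, 27.2),
        n_eeg=0,
        n_behaviour=76,
        behaviour_rates={
            "pre_lop": _rates(
                59.2,
                {
                    "head_shaking": 5.4, "deep_inhalation": 9.4, "HPV": 2.9,
                    "gasping": 0.7, "sitting": 2.1, "standing": 2.0,
                    "walking": 1.2, "ataxia": 1.5, "wing_flapping": 0.4,
                },
                {
                    "sitting": 35.9, "standing": 13.4, "walking": 2.6,
                    "ataxia": 4.6, "wing_flapping": 0.7,
                },
            ),
            "post_lop": _rates(
                168.8 - 59.2,
                {
                    "gasping": 2.5, "jumping": 0.1, "leg_paddling": 3.9,
                    "wing_flapping": 1.5, "HPV": 1.8,
                },
                {"leg_paddling": 14.3, "wing_flapping": 0.7},
            ),
        },
    ),
    "40C60N": TreatmentPreset(
        label="40C60N",
        loc_time=(25.7, 7.0),
        death_time=(65.8, 14.1),
        lop_time=(19.8, 4.5),
        motionless_time=(66.1, 10.3),
        n_eeg=14,
        n_behaviour=63,
        behaviour_rates={
            "pre_lop": _rates(
                19.8,
                {
                    "head_shaking": 4.8, "deep_inhalation": 3.9, "HPV": 2.0,
                    "sitting": 1.3, "standing": 1.1, "walking": 0.6,
                    "ataxia": 1.0, "wing_flapping": 0.6,
                },
                {
                    "sitting": 7.4, "standing": 7.5, "walking": 1.5,
                    "ataxia": 2.7, "wing_flapping": 1.1,
                },
            ),
            "post_lop": _rates(
                66.1 - 19.8,
                {
                    "gasping": 0.4, "jumping": 0.2, "leg_paddling": 4.3,
                    "wing_flapping": 2.4, "HPV": 1.5,
                },
                {"leg_paddling": 18.2, "wing_flapping": 1.1},
            ),
        },
    ),
    "20C80N": TreatmentPreset(
        label="20C80N",
        loc_time=(20.7, 6.6),
        # visual isoelectric onset; the spectral estimate was degraded
        death_time=(66.3, 8.1),
        lop_time=(22.3, 4.5),
        motionless_time=(70.4, 10.3),
        n_eeg=9,
        n_behaviour=54,
        behaviour_rates={
            "pre_lop": _rates(
                22.3,
                {
                    "head_shaking": 5.1, "deep_inhalation": 4.8, "HPV": 3.3,
                    "sitting": 1.6, "standing": 1.3, "walking": 0.7,
                    "ataxia": 1.0, "wing_flapping": 1.0,
                },
                {
                    "sitting": 6.9, "standing": 8.5, "walking": 1.5,
                    "ataxia": 3.6, "wing_flapping": 2.3,
                },
            ),
            "post_lop": _rates(
                70.4 - 22.3,
                {
                    "gasping": 0.3, "jumping": 0.4, "leg_paddling": 4.6,
                    "wing_flapping": 3.1, "HPV": 1.8,
                },
                {"leg_paddling": 19.0, "wing_flapping": 2.3},
            ),
        },
    ),
}
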