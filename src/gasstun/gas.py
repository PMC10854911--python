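"""Gas-concentration profiles: simulation and compliance checking.

Treatments are defined as a sequence of phases, each with target CO2 and O2
percentages and compliance constraints.  The two-phase CO2 treatment
(40C90C) holds CO2 under 40% for the first two minutes and above 90%
(with residual O2 under 2%) for the second two; the CO2/N2 mixtures
(40C60N, 20C80N) hold a single anoxic phase (<2% O2) for the full four
minutes.  An atmospheric-air control (AIR) is available for baseline
behaviour runs.

The pit is pre-filled, so the bird sees target concentrations only after
the lift has descended; ``fill_latency`` models that descent (23 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GasPhase",
    "GasCycleSpec",
    "TREATMENT_GAS",
    "simulate_gas_profile",
    "check_gas_compliance",
]


@dataclass(frozen=True)
class GasPhase:
    """One phase of a stunning cycle, with targets and compliance bounds."""

    start: float
    end: float
    co2_target: float  # % by volume
    o2_target: float   # % by volume
    co2_max: float | None = None  # compliance: phase mean CO2 must stay below
    co2_min: float | None = None  # compliance: phase mean CO2 must stay above
    o2_max: float | None = None   # compliance: phase mean O2 must stay below


@dataclass
class GasCycleSpec:
    treatment_label: str
    phases: list[GasPhase]
    noise_sd: float = 0.3  # % by volume
    fill_latency: float = 23.0  # s for the lift to descend
    sample_interval: float = 1.0  # s
    seed: int = 0

    def validate(self) -> None:
        if not self.phases:
            raise ValueError("at least one phase required")
        prev_end = 0.0
        for ph in self.phases:
            if ph.start != prev_end:
                raise ValueError("phases must tile the exposure window")
            if ph.end <= ph.start:
                raise ValueError("phase end must exceed start")
            for v in (ph.co2_target, ph.o2_target):
                if not 0 <= v <= 100:
                    raise ValueError("percentages must lie in [0, 100]")
            prev_end = ph.end
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


#: Study treatment definitions.  Phase-1 of 40C90C ran at 38.1% CO2
#: (constraint: below 40%), phase 2 at 92.2% CO2 / 1.0% O2; the mixtures
#: ran at 36.3% CO2 / 1.6% O2 (40C60N) and 18.0% CO2 / 1.9% O2 (20C80N).
TREATMENT_GAS: dict[str, list[GasPhase]] = {
    "40C90C": [
        GasPhase(0, 120, co2_target=38.1, o2_target=13.0, co2_max=40.0),
        GasPhase(120, 240, co2_target=92.2, o2_target=1.0, co2_min=90.0, o2_max=2.0),
    ],
    "40C60N": [
        GasPhase(0, 240, co2_target=36.3, o2_target=1.6, co2_max=40.0, o2_max=2.0),
    ],
    "20C80N": [
        GasPhase(0, 240, co2_target=18.0, o2_target=1.9, co2_max=22.0, o2_max=2.0),
    ],
    "AIR": [
        GasPhase(0, 240, co2_target=0.04, o2_target=20.9),
    ],
}


def simulate_gas_profile(spec: GasCycleSpec) -> pd.DataFrame:
    """Piecewise-constant targets plus Gaussian sensor noise.

    During the first ``fill_latency`` seconds the concentrations ramp
    linearly from atmospheric air to the phase-1 targets (the lift is
    descending into the pre-filled pit).  Returns a frame with columns
    ``time_s, co2_pct, o2_pct``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    end = spec.phases[-1].end
    t = np.arange(0.0, end, spec.sample_interval)
    co2 = np.empty_like(t)
    o2 = np.empty_like(t)
    for ph in spec.phases:
        m = (t >= ph.start) & (t < ph.end)
        co2[m] = ph.co2_target
        o2[m] = ph.o2_target
    if spec.fill_latency > 0:
        m = t < spec.fill_latency
        frac = t[m] / spec.fill_latency
        co2[m] = 0.04 + (co2[m] - 0.04) * frac
        o2[m] = 20.9 + (o2[m] - 20.9) * frac
    if spec.noise_sd > 0:
        co2 = co2 + rng.normal(0, spec.noise_sd, t.size)
        o2 = o2 + rng.normal(0, spec.noise_sd, t.size)
    return pd.DataFrame(
        {"time_s": t, "co2_pct": np.clip(co2, 0, 100), "o2_pct": np.clip(o2, 0, 100)}
    )


def check_gas_compliance(
    profile: pd.DataFrame,
    phases: list[GasPhase],
    fill_latency: float = 23.0,
) -> pd.DataFrame:
    """Phase means vs treatment constraints -> per-phase pass/fail report.

    Phase means exclude the lift-descent window (``fill_latency``), during
    which the atmosphere is still mixing towards the target.  The profile
    must cover every phase.
    """
    t = profile["time_s"].to_numpy(float)
    rows = []
    for i, ph in enumerate(phases):
        lo = max(ph.start, fill_latency) if i == 0 else ph.start
        m = (t >= lo) & (t < ph.end)
        if not m.any():
            raise ValueError(f"profile has no samples in phase {i + 1}")
        co2_mean = float(profile.loc[m, "co2_pct"].mean())
        o2_mean = float(profile.loc[m, "o2_pct"].mean())
        ok = True
        if ph.co2_max is not None and co2_mean >= ph.co2_max:
            ok = False
        if ph.co2_min is not None and co2_mean <= ph.co2_min:
            ok = False
        if ph.o2_max is not None and o2_mean >= ph.o2_max:
            ok = False
        rows.append(
            {
                "phase": i + 1,
                "start_s": ph.start,
                "end_s": ph.end,
                "co2_mean_pct": co2_mean,
                "o2_mean_pct": o2_mean,
                "passed": ok,
            }
        )
    return pd.DataFrame(rows)
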