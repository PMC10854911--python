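#!/usr/bin/env python
"""Simulate the desk-scale study: EEG cohorts, behaviour streams, gas cycles.

Generates, for each gas treatment (40C90C, 40C60N, 20C80N), a small EEG
cohort with known LOC/death ground truth, a behaviour cohort at the study's
group sizes (76/63/54 birds), and one gas-concentration cycle.  Raw EEG
traces go to scratch/sim_eeg/ (they are bulky); ground truth, behaviour
events and gas profiles go to results/.
"""

from pathlib import Path

import pandas as pd

from gasstun.behaviour import write_events
from gasstun.gas import TREATMENT_GAS, GasCycleSpec, simulate_gas_profile
from gasstun.presets import TREATMENT_PRESETS
from gasstun.signal_io import write_signal
from gasstun.synth import CohortSpec, simulate_behaviour_cohort, simulate_cohort

SEED = 20240201
N_EEG = 6
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
TRACE_DIR = ROOT / "scratch" / "sim_eeg"
EVENTS = ROOT / "scratch" / "behaviour_events.csv"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    TRACE_DIR.mkdir(parents=True, exist_ok=True)

    truth_frames = []
    records = []
    for i, (label, preset) in enumerate(sorted(TREATMENT_PRESETS.items())):
        eeg = CohortSpec(
            n_birds=N_EEG,
            treatment_label=label,
            loc_time_distribution=preset.loc_time,
            death_time_distribution=preset.death_time,
            seed=SEED + 10 * i,
        )
        pairs, truth = simulate_cohort(eeg)
        for trace, _ in pairs:
            write_signal(trace, TRACE_DIR / f"{trace.subject_id}.edf", "edf")
        truth_frames.append(truth)

        beh = CohortSpec(
            n_birds=preset.n_behaviour,
            treatment_label=label,
            loc_time_distribution=preset.lop_time,
            death_time_distribution=preset.motionless_time,
            behaviour_rate_table=preset.behaviour_rates,
            seed=SEED + 10 * i + 1,
        )
        records.extend(simulate_behaviour_cohort(beh))

        gas = GasCycleSpec(label, TREATMENT_GAS[label], seed=SEED + 10 * i + 2)
        simulate_gas_profile(gas).to_csv(
            RESULTS / f"gas_{label}.csv", index=False, float_format="%.4f"
        )

    truth = pd.concat(truth_frames, ignore_index=True)
    truth.to_csv(RESULTS / "eeg_truth.csv", index=False, float_format="%.6f")
    write_events(records, EVENTS)

    print(f"EEG traces      : {3 * N_EEG} birds -> {TRACE_DIR}")
    print(f"ground truth    : {len(truth)} rows -> {RESULTS / 'eeg_truth.csv'}")
    print(f"behaviour birds : {len(records)} -> {EVENTS}")
    print(f"gas profiles    : 3 cycles -> {RESULTS}/gas_<treatment>.csv")


if __name__ == "__main__":
    main()
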