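#!/usr/bin/env python
"""Check the simulated gas cycles against each treatment's constraints.

Phase-mean CO2 and O2 concentrations (excluding the 23 s lift descent) are
compared with the treatment definitions: <40% CO2 then >90% CO2 with <2% O2
for the two-phase treatment; near-target CO2 with <2% O2 for the CO2/N2
mixtures.  Writes results/gas_compliance.csv.
"""

from pathlib import Path

import pandas as pd

from gasstun.gas import TREATMENT_GAS, check_gas_compliance

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    frames = []
    for label in sorted(TREATMENT_GAS):
        path = RESULTS / f"gas_{label}.csv"
        if not path.exists():
            continue
        report = check_gas_compliance(pd.read_csv(path), TREATMENT_GAS[label])
        report.insert(0, "treatment", label)
        frames.append(report)
    if not frames:
        raise SystemExit("no gas profiles found; run 01_simulate_cohorts.py first")
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(RESULTS / "gas_compliance.csv", index=False, float_format="%.4f")
    print(out.to_string(index=False))
    status = "PASS" if bool(out["passed"].all()) else "FAIL"
    print(f"\noverall compliance: {status} -> {RESULTS / 'gas_compliance.csv'}")


if __name__ == "__main__":
    main()
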