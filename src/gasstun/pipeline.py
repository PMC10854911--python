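"""End-to-end study pipeline: simulate -> detect -> summarise -> report.

`run_pipeline` reproduces a full desk-scale stunning trial from a single
seed: per-treatment EEG cohorts analysed for LOC/death onsets, behaviour
cohorts summarised into ethogram tables with group statistics, gas-profile
compliance checks, and a manifest with a checksum of every output so reruns
can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behaviour import (
    DEFAULT_ETHOGRAM,
    chi_square_proportions,
    cohort_tables,
    read_events,
    two_sample_t,
    write_events,
)
from .detect import DetectionConfig, analyze_bird
from .gas import TREATMENT_GAS, GasCycleSpec, check_gas_compliance, simulate_gas_profile
from .presets import TREATMENT_PRESETS
from .synth import CohortSpec, simulate_behaviour_cohort, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "detection_table"]

_FLOAT_FMT = "%.6f"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "results/run"
    seed: int = 0
    treatments: list[str] = field(default_factory=lambda: ["40C90C", "40C60N", "20C80N"])
    n_eeg_birds: int = 4          # EEG birds per treatment (desk scale)
    n_behaviour_birds: int = 12   # behaviour birds per treatment (desk scale)
    exposure_duration: float = 240.0
    detection: DetectionConfig = field(default_factory=DetectionConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        det = DetectionConfig(**raw.pop("detection", {}))
        cfg = cls(**raw, detection=det)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def detection_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "subject": r.subject_id,
                "treatment": r.treatment_label,
                "t_loc_s": r.t_loc,
                "t_death_spectral_s": r.t_death_spectral,
                "t_death_isoelectric_s": r.t_death_isoelectric,
                "gamma_max_frac": r.gamma_max_fraction,
                "qc_flags": ";".join(sorted(r.qc_flags)),
            }
        )
    return pd.DataFrame(rows)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest dictionary.

    Outputs under ``config.outdir``:

    * ``detection.csv`` — one row per EEG bird (onsets, gamma QC, flags)
      plus the generator truth columns;
    * ``behaviour_events.csv`` / ``behaviour_anchors.csv`` /
      ``behaviour_summary.csv`` / ``behaviour_tests.csv`` — event streams,
      LOP/motionless summaries, per-behaviour tables, chi-squared and t
      comparisons across treatments;
    * ``gas_compliance.csv`` — phase means vs treatment constraints;
    * ``manifest.json`` — config echo, seed, version, file checksums.

    The run is fully deterministic: identical config and seed give
    byte-identical outputs.
    """
    unknown = [t for t in config.treatments if t not in TREATMENT_PRESETS]
    if unknown:
        raise ValueError(f"unknown treatments: {unknown}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    # one deterministic child seed per (treatment, purpose)
    seeds = {}
    for i, label in enumerate(config.treatments):
        eeg_seed, beh_seed, gas_seed = (
            int(s.generate_state(1)[0] % (2**31 - 1))
            for s in np.random.SeedSequence((config.seed, i)).spawn(3)
        )
        seeds[label] = (eeg_seed, beh_seed, gas_seed)

    # --- EEG cohorts -> detection table ---------------------------------
    all_results = []
    truth_frames = []
    for label in config.treatments:
        preset = TREATMENT_PRESETS[label]
        cohort = CohortSpec(
            n_birds=config.n_eeg_birds,
            treatment_label=label,
            loc_time_distribution=preset.loc_time,
            death_time_distribution=preset.death_time,
            exposure_duration=config.exposure_duration,
            seed=seeds[label][0],
        )
        pairs, truth = simulate_cohort(cohort)
        all_results.extend(analyze_bird(trace, config.detection) for trace, _ in pairs)
        truth_frames.append(truth)
    detection_csv = outdir / "detection.csv"
    frame = detection_table(all_results).merge(
        pd.concat(truth_frames, ignore_index=True), on=["subject", "treatment"], how="left"
    )
    _write_csv(frame, detection_csv)

    # --- behaviour cohorts -> tables and tests --------------------------
    all_records = []
    for label in config.treatments:
        preset = TREATMENT_PRESETS[label]
        cohort = CohortSpec(
            n_birds=config.n_behaviour_birds,
            treatment_label=label,
            loc_time_distribution=preset.lop_time,
            death_time_distribution=preset.motionless_time,
            behaviour_rate_table=preset.behaviour_rates,
            exposure_duration=config.exposure_duration,
            seed=seeds[label][1],
        )
        all_records.extend(simulate_behaviour_cohort(cohort))
    events_csv = outdir / "behaviour_events.csv"
    write_events(all_records, events_csv)
    records = read_events(events_csv)

    anchors, summary = cohort_tables(records)
    _write_csv(anchors, outdir / "behaviour_anchors.csv")
    _write_csv(summary, outdir / "behaviour_summary.csv")

    # chi-squared across treatments on the proportion of birds expressing
    # each behaviour, per phase; t test on anchor times between treatments
    test_rows = []
    for (phase, behaviour), grp in summary.groupby(["phase", "behaviour"], sort=True):
        if len(grp) < 2:
            continue
        stat, df, p = chi_square_proportions(
            grp["n_birds_shown"].to_numpy(), grp["n_birds"].to_numpy()
        )
        test_rows.append(
            {
                "test": "chi_square_proportion",
                "phase": phase,
                "behaviour": behaviour,
                "statistic": stat,
                "df": df,
                "p_value": p,
            }
        )
    labels = sorted({r.treatment_label for r in records})
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = [r.t_lop for r in records if r.treatment_label == labels[i]]
            b = [r.t_lop for r in records if r.treatment_label == labels[j]]
            if len(a) < 2 or len(b) < 2:
                continue
            t, df, p = two_sample_t(
                float(np.mean(a)), float(np.std(a, ddof=1)), len(a),
                float(np.mean(b)), float(np.std(b, ddof=1)), len(b),
            )
            test_rows.append(
                {
                    "test": f"t_lop:{labels[i]}_vs_{labels[j]}",
                    "phase": "",
                    "behaviour": "loss_of_posture",
                    "statistic": t,
                    "df": df,
                    "p_value": p,
                }
            )
    _write_csv(pd.DataFrame(test_rows), outdir / "behaviour_tests.csv")

    # --- gas profiles -> compliance report ------------------------------
    gas_rows = []
    for label in config.treatments:
        spec = GasCycleSpec(
            treatment_label=label,
            phases=TREATMENT_GAS[label],
            seed=seeds[label][2],
        )
        profile = simulate_gas_profile(spec)
        _write_csv(profile, outdir / f"gas_{label}.csv")
        report = check_gas_compliance(profile, spec.phases, spec.fill_latency)
        report.insert(0, "treatment", label)
        gas_rows.append(report)
    _write_csv(pd.concat(gas_rows, ignore_index=True), outdir / "gas_compliance.csv")

    # --- manifest --------------------------------------------------------
    files = sorted(p for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "gasstun_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
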