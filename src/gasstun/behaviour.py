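"""Ethogram event analysis for gas-stunning trials.

Birds observed during controlled-atmosphere stunning are scored against a
fixed ethogram.  Two anchor events structure each record: loss of posture
(LOP, the behavioural proxy of loss of consciousness) and motionlessness
(the behavioural proxy of brain death).  Every other behaviour is either a
*point* event (instantaneous, counted) or a *state* event (with a duration),
and is analysed separately before and after LOP: pre-LOP events reflect
aversion experienced while conscious, post-LOP events reflect convulsions.

Group comparisons use Pearson's chi-squared test on proportions of birds
expressing a behaviour and Student's t test (pooled or Welch) on means.
Mixed models with the stunning cycle as a random effect are out of scope
here; tables are produced at bird level and per cycle, with the caveat that
bird-level tests ignore the cycle grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "POINT_BEHAVIOURS",
    "STATE_BEHAVIOURS",
    "ANCHOR_BEHAVIOURS",
    "Ethogram",
    "BehaviourEvent",
    "BehaviourRecord",
    "read_events",
    "write_events",
    "partition_by_lop",
    "summarize_bird",
    "cohort_tables",
    "first_occurrence_order",
    "chi_square_proportions",
    "two_sample_t",
]

#: Instantaneous behaviours: counted, zero duration.
POINT_BEHAVIOURS = (
    "head_shaking",
    "deep_inhalation",
    "gasping",
    "jumping",
    "HPV",
)
#: Behaviours with a duration (start < stop).
STATE_BEHAVIOURS = (
    "sitting",
    "standing",
    "walking",
    "ataxia",
    "wing_flapping",
    "leg_paddling",
)
#: One occurrence per bird, anchoring the pre/post-LOP partition.
ANCHOR_BEHAVIOURS = ("loss_of_posture", "motionless")


@dataclass(frozen=True)
class Ethogram:
    """Catalogue of behaviour labels with their event kind."""

    point: tuple[str, ...] = POINT_BEHAVIOURS
    state: tuple[str, ...] = STATE_BEHAVIOURS
    anchors: tuple[str, ...] = ANCHOR_BEHAVIOURS

    @property
    def labels(self) -> tuple[str, ...]:
        return self.point + self.state + self.anchors

    def kind(self, behaviour: str) -> str:
        if behaviour in self.point:
            return "POINT"
        if behaviour in self.state:
            return "STATE"
        if behaviour in self.anchors:
            return "POINT"
        raise KeyError(f"behaviour {behaviour!r} not in ethogram")


DEFAULT_ETHOGRAM = Ethogram()


@dataclass
class BehaviourEvent:
    behaviour: str
    start: float
    stop: float

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass
class BehaviourRecord:
    """Timed ethogram events for one bird, with LOP/motionless anchors."""

    subject_id: str
    treatment_label: str
    events: list[BehaviourEvent]
    t_lop: float | None
    t_motionless: float | None
    cycle_id: str = ""

    @property
    def usable(self) -> bool:
        return self.t_lop is not None and self.t_motionless is not None


# ---------------------------------------------------------------------------
# I/O (BORIS-style tabular export)

_COLUMNS = ["subject", "behavior", "behavior_type", "start_s", "stop_s", "cycle", "treatment"]


def write_events(records: list[BehaviourRecord], path: str | Path,
                 ethogram: Ethogram = DEFAULT_ETHOGRAM) -> Path:
    rows = []
    for rec in records:
        all_events = list(rec.events)
        if rec.t_lop is not None:
            all_events.append(BehaviourEvent("loss_of_posture", rec.t_lop, rec.t_lop))
        if rec.t_motionless is not None:
            all_events.append(BehaviourEvent("motionless", rec.t_motionless, rec.t_motionless))
        for ev in sorted(all_events, key=lambda e: (e.start, e.behaviour)):
            rows.append(
                {
                    "subject": rec.subject_id,
                    "behavior": ev.behaviour,
                    "behavior_type": ethogram.kind(ev.behaviour),
                    "start_s": round(ev.start, 6),
                    "stop_s": round(ev.stop, 6),
                    "cycle": rec.cycle_id,
                    "treatment": rec.treatment_label,
                }
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_events(path: str | Path, ethogram: Ethogram = DEFAULT_ETHOGRAM) -> list[BehaviourRecord]:
    """Parse a BORIS-style CSV export into per-bird records.

    Unknown behaviour labels are rejected; point events are forced to zero
    duration; a record missing either anchor is returned with the missing
    anchor set to None (``usable`` is False).
    """
    frame = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in ("subject", "behavior", "start_s", "stop_s") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for subject, grp in frame.groupby("subject", sort=True):
        events: list[BehaviourEvent] = []
        t_lop = t_motionless = None
        for row in grp.itertuples():
            name = row.behavior
            if name not in ethogram.labels:
                raise ValueError(f"{path}: unknown behaviour label {name!r}")
            start, stop = float(row.start_s), float(row.stop_s)
            if stop < start:
                raise ValueError(
                    f"{path}: event {name!r} for {subject!r} has stop < start"
                )
            if name == "loss_of_posture":
                t_lop = start
            elif name == "motionless":
                t_motionless = start
            else:
                if ethogram.kind(name) == "POINT":
                    stop = start
                events.append(BehaviourEvent(name, start, stop))
        records.append(
            BehaviourRecord(
                subject_id=str(subject),
                treatment_label=str(grp["treatment"].iloc[0]) if "treatment" in grp else "",
                events=events,
                t_lop=t_lop,
                t_motionless=t_motionless,
                cycle_id=str(grp["cycle"].iloc[0]) if "cycle" in grp else "",
            )
        )
    return records


# ---------------------------------------------------------------------------
# partition and summaries


def partition_by_lop(
    record: BehaviourRecord,
) -> tuple[list[BehaviourEvent], list[BehaviourEvent]]:
    """Split events into (pre-LOP, post-LOP) at the bird's LOP time.

    Point events go to the side their timestamp falls on (events exactly at
    LOP count as post).  A state event spanning LOP is split at LOP into two
    sub-events, so total counts increase by one per spanning event while
    total duration is conserved exactly.
    """
    if record.t_lop is None:
        raise ValueError(f"record {record.subject_id!r} has no LOP anchor")
    t = record.t_lop
    pre: list[BehaviourEvent] = []
    post: list[BehaviourEvent] = []
    for ev in record.events:
        if ev.stop <= t and not (ev.start == ev.stop == t):
            pre.append(ev)
        elif ev.start >= t:
            post.append(ev)
        else:
            pre.append(BehaviourEvent(ev.behaviour, ev.start, t))
            post.append(BehaviourEvent(ev.behaviour, t, ev.stop))
    return pre, post


def summarize_bird(
    record: BehaviourRecord, ethogram: Ethogram = DEFAULT_ETHOGRAM
) -> pd.DataFrame:
    """Per-behaviour event counts and state durations, by phase.

    Returns one row per (phase, behaviour) for every non-anchor behaviour in
    the ethogram; behaviours the bird never expressed appear with zeros.
    """
    pre, post = partition_by_lop(record)
    rows = []
    for phase, events in (("pre_lop", pre), ("post_lop", post)):
        for name in ethogram.point + ethogram.state:
            hits = [e for e in events if e.behaviour == name]
            rows.append(
                {
                    "subject": record.subject_id,
                    "phase": phase,
                    "behaviour": name,
                    "n_events": len(hits),
                    "total_duration_s": (
                        float(sum(e.duration for e in hits))
                        if ethogram.kind(name) == "STATE"
                        else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)


def cohort_tables(
    records: list[BehaviourRecord], ethogram: Ethogram = DEFAULT_ETHOGRAM
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treatment-level summary tables.

    Returns ``(anchor_table, behaviour_table)``:

    * anchor_table — per treatment: n, mean, min, max of time to LOP and to
      motionlessness;
    * behaviour_table — per treatment x phase x behaviour: proportion of
      birds expressing it (k/n), events per bird (mean, min, max) and, for
      state behaviours, total duration per bird (mean, min, max).
    """
    if not records:
        raise ValueError("no records")
    usable = [r for r in records if r.usable]
    if not usable:
        raise ValueError("no usable records (missing anchors)")

    anchor_rows = []
    frames = []
    for treatment in sorted({r.treatment_label for r in usable}):
        grp = [r for r in usable if r.treatment_label == treatment]
        lop = np.array([r.t_lop for r in grp])
        mot = np.array([r.t_motionless for r in grp])
        for name, arr in (("loss_of_posture", lop), ("motionless", mot)):
            anchor_rows.append(
                {
                    "treatment": treatment,
                    "anchor": name,
                    "n": len(grp),
                    "mean_s": arr.mean(),
                    "min_s": arr.min(),
                    "max_s": arr.max(),
                }
            )
        per_bird = pd.concat([summarize_bird(r, ethogram) for r in grp])
        agg = (
            per_bird.groupby(["phase", "behaviour"], sort=False)
            .agg(
                n_birds_shown=("n_events", lambda s: int((s > 0).sum())),
                n_birds=("n_events", "size"),
                events_mean=("n_events", "mean"),
                events_min=("n_events", "min"),
                events_max=("n_events", "max"),
                duration_mean_s=("total_duration_s", "mean"),
                duration_min_s=("total_duration_s", "min"),
                duration_max_s=("total_duration_s", "max"),
            )
            .reset_index()
        )
        agg.insert(0, "treatment", treatment)
        agg["proportion"] = agg["n_birds_shown"] / agg["n_birds"]
        is_state = agg["behaviour"].isin(ethogram.state)
        agg.loc[~is_state, ["duration_mean_s", "duration_min_s", "duration_max_s"]] = np.nan
        frames.append(agg)
    return pd.DataFrame(anchor_rows), pd.concat(frames, ignore_index=True)


def first_occurrence_order(record: BehaviourRecord) -> list[tuple[str, float]]:
    """Behaviours ordered by first onset before LOP.

    Ties keep catalogue order so the result is deterministic; tied onsets
    share the same time value, which callers can use to report the tie.
    """
    pre, _ = partition_by_lop(record)
    firsts: dict[str, float] = {}
    for ev in pre:
        if ev.behaviour not in firsts or ev.start < firsts[ev.behaviour]:
            firsts[ev.behaviour] = ev.start
    catalogue = DEFAULT_ETHOGRAM.point + DEFAULT_ETHOGRAM.state
    order = {name: i for i, name in enumerate(catalogue)}
    return sorted(firsts.items(), key=lambda kv: (kv[1], order.get(kv[0], len(order))))


# ---------------------------------------------------------------------------
# statistics


def chi_square_proportions(
    shown: "np.ndarray | list[int]", totals: "np.ndarray | list[int]"
) -> tuple[float, int, float]:
    """Pearson chi-squared test that proportions k_i/n_i are equal.

    Builds the 2 x g shown/not-shown contingency table and computes
    X² = Σ (O−E)²/E with expected counts from the margins;
    df = g − 1; the p-value comes from the chi-squared distribution.
    """
    k = np.asarray(shown, dtype=float)
    n = np.asarray(totals, dtype=float)
    if k.size < 2:
        raise ValueError("need at least two groups")
    if np.any(n <= 0):
        raise ValueError("all group sizes must be positive")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("shown counts must lie in [0, n]")
    observed = np.vstack([k, n - k])
    row_tot = observed.sum(axis=1, keepdims=True)
    col_tot = observed.sum(axis=0, keepdims=True)
    expected = row_tot * col_tot / observed.sum()
    if np.any(expected == 0):
        # a margin is empty: all or none shown everywhere -> no evidence
        return 0.0, int(k.size - 1), 1.0
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = int(k.size - 1)
    p = float(spstats.chi2.sf(stat, df))
    return stat, df, p


def two_sample_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t test from summary statistics.

    ``variant='pooled'`` is the classical Student test with a pooled
    variance and df = n1 + n2 − 2; ``variant='welch'`` uses the
    Welch–Satterthwaite approximation.  Returns (t, df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1**2, sd2**2
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    elif variant == "welch":
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = float((mean1 - mean2) / se)
    p = float(2 * spstats.t.sf(abs(t), df))
    return t, float(df), p
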