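"""Cohort construction: exclusion criteria, record classes and data splits.

Raw tables pass through six exclusion criteria, applied in order so that a
record violating several is attributed to the first:

1. vancomycin injections of less than 10 mg per administration (flushes /
   data errors);
2. events with a missing patient ID;
3. patients with no weight information;
4. trough measurements drawn outside 5-28 h after their closest prior
   injection;
5. a configurable trough-timing predicate (pass-through by default);
6. records whose target daily dose is missing or invalid.

Counts are reported in each criterion's natural unit: injection events for
1, events for 2, patients for 3, trough matches for 4-5 and labeled records
for 6.  The stage consumes *raw* tables (DataFrames) rather than the typed
records layer precisely so that defective rows — blank IDs, flush doses —
can flow in and be counted instead of failing validation upstream.

Splitting is by patient, never by record: every record of a patient lands in
the same one of train/validation/test, so the test set contains only unseen
patients.  Patients are ordered by a seeded hash of their ID and the ordered
list is cut at the requested fractions — deterministic for a given seed,
independent of record order, and within one patient of the target fractions.
"""

from __future__ import annotations

import hashlib
import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd

from .labeling import (
    DoseRecord,
    EmptyWindowError,
    LabeledRecord,
    TherapeuticWindow,
    TroughMatch,
    aggregate_daily_dose,
    derive_targets,
    match_trough,
)
from .records_io import InjectionEvent, TroughMeasurement

CRITERIA = {
    1: "injection dose < 10 mg",
    2: "missing patient ID",
    3: "missing weight",
    4: "trough-injection gap outside 5-28 h",
    5: "trough timing outside specified interval",
    6: "missing or invalid target daily dose",
}

SPLITS = ("train", "validation", "test")
DEFAULT_FRACTIONS = (0.64, 0.16, 0.20)


@dataclass
class CohortReport:
    """Bookkeeping for one cohort build."""

    removed: dict[int, int] = field(default_factory=lambda: {k: 0 for k in CRITERIA})
    input_injections: int = 0
    input_troughs: int = 0
    patients_remaining: int = 0
    records_remaining: int = 0

    def to_dict(self) -> dict:
        return {
            "removed_per_criterion": {
                str(k): {"count": v, "description": CRITERIA[k]}
                for k, v in self.removed.items()
            },
            "input_injections": self.input_injections,
            "input_troughs": self.input_troughs,
            "patients_remaining": self.patients_remaining,
            "records_remaining": self.records_remaining,
        }


def _blank(pid) -> bool:
    return pid is None or (isinstance(pid, float) and math.isnan(pid)) or not str(pid).strip()


def apply_exclusions(
    injections: pd.DataFrame,
    troughs: pd.DataFrame,
    demographics: pd.DataFrame,
    window: TherapeuticWindow = TherapeuticWindow(),
    timing_predicate: Callable[[TroughMatch], bool] | None = None,
) -> tuple[list[LabeledRecord], CohortReport]:
    """Run the six exclusion criteria and return the surviving labeled records.

    ``injections`` (``patient_id, time, dose_mg``), ``troughs``
    (``patient_id, time, concentration``) and ``demographics``
    (``patient_id, weight_kg``, NaN weight excludes under criterion 3) are
    raw tables.  ``timing_predicate`` is the criterion-5 hook: a function of
    a :class:`~vancodose.labeling.TroughMatch` returning False to exclude;
    the default keeps everything.
    """
    report = CohortReport()
    report.input_injections = len(injections)
    report.input_troughs = len(troughs)

    inj = injections.copy()
    tr = troughs.copy()
    inj["time"] = pd.to_datetime(inj["time"]) if len(inj) else inj.get("time")
    tr["time"] = pd.to_datetime(tr["time"]) if len(tr) else tr.get("time")

    # 1) sub-10 mg injections
    low = inj["dose_mg"].astype(float) < 10 if len(inj) else pd.Series(dtype=bool)
    report.removed[1] = int(low.sum()) if len(inj) else 0
    inj = inj[~low] if len(inj) else inj

    # 2) missing patient IDs (injections and troughs)
    if len(inj):
        blank_i = inj["patient_id"].map(_blank)
        report.removed[2] += int(blank_i.sum())
        inj = inj[~blank_i]
    if len(tr):
        blank_t = tr["patient_id"].map(_blank)
        report.removed[2] += int(blank_t.sum())
        tr = tr[~blank_t]

    # 3) patients with no weight information
    known: set[str] = set()
    if len(demographics):
        for pid, w in zip(demographics["patient_id"], demographics["weight_kg"]):
            try:
                if not _blank(pid) and float(w) > 0:
                    known.add(str(pid))
            except (TypeError, ValueError):
                continue
    cohort_pids = set(map(str, inj["patient_id"])) | set(map(str, tr["patient_id"]))
    no_weight = cohort_pids - known
    report.removed[3] = len(no_weight)
    inj = inj[~inj["patient_id"].astype(str).isin(no_weight)]
    tr = tr[~tr["patient_id"].astype(str).isin(no_weight)]

    kept_inj = [
        InjectionEvent(str(r.patient_id), r.time, float(r.dose_mg))
        for r in inj.itertuples(index=False)
    ]
    kept_tr = [
        TroughMeasurement(str(r.patient_id), r.time, float(r.concentration))
        for r in tr.itertuples(index=False)
    ]

    # 4) trough-injection gap outside 5-28 h; 5) timing hook
    matches = match_trough(kept_inj, kept_tr)
    kept_matches = []
    for m in matches:
        if not m.matched or not m.gap_in_range:
            report.removed[4] += 1
            continue
        if timing_predicate is not None and not timing_predicate(m):
            report.removed[5] += 1
            continue
        kept_matches.append(m)

    # assemble dose records for the surviving matches
    by_patient_inj: dict[str, list[InjectionEvent]] = {}
    for e in kept_inj:
        by_patient_inj.setdefault(e.patient_id, []).append(e)
    for evs in by_patient_inj.values():
        evs.sort(key=lambda e: e.time)
    trough_times: dict[str, list[pd.Timestamp]] = {}
    for t in kept_tr:
        trough_times.setdefault(t.patient_id, []).append(t.time)
    for ts in trough_times.values():
        ts.sort()

    drafts: list[DoseRecord] = []
    for m in kept_matches:
        evs = by_patient_inj[m.trough.patient_id]
        try:
            daily = aggregate_daily_dose(evs, m.anchor, m.trough.time)
        except EmptyWindowError:
            report.removed[4] += 1
            continue
        times = [e.time for e in evs]
        i = times.index(m.anchor.time)
        hsli = (m.anchor.time - times[i - 1]) / pd.Timedelta(hours=1) if i > 0 else None
        prior = trough_times.get(m.trough.patient_id, [])
        is_initial = bisect_left(prior, m.anchor.time) == 0
        drafts.append(
            DoseRecord(
                patient_id=m.trough.patient_id,
                anchor_time=m.anchor.time,
                daily_dose=daily,
                trough_time=m.trough.time,
                trough=m.trough.concentration,
                hours_since_last_injection=hsli,
                is_initial=is_initial,
            )
        )

    # 6) missing or invalid target
    labeled = derive_targets(drafts, window)
    kept_records = [r for r in labeled if r.label_status.valid]
    report.removed[6] = len(labeled) - len(kept_records)

    report.records_remaining = len(kept_records)
    report.patients_remaining = len({r.patient_id for r in kept_records})
    return kept_records, report


def classify_record(record: DoseRecord, trough_history: Sequence[pd.Timestamp]) -> str:
    """``"initial"`` when the patient has no vancomycin lab test before the
    anchor (prior injections do not matter), else ``"subsequent"``."""
    prior = sorted(pd.Timestamp(t) for t in trough_history)
    return "initial" if bisect_left(prior, record.anchor_time) == 0 else "subsequent"


def split_by_patient(
    patient_ids: Sequence[str],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> dict[str, str]:
    """Patient-disjoint train/validation/test assignment.

    Patients are ordered by ``blake2b(f"{seed}:{patient_id}")`` and the
    ordered list is cut at the cumulative fractions, so realized set sizes
    are within one patient of the targets, the assignment is deterministic
    given the seed, and record order is irrelevant.
    """
    fractions = tuple(fractions)
    if len(fractions) != len(SPLITS):
        raise ValueError(f"need {len(SPLITS)} fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    pids = sorted(set(patient_ids))
    if len(pids) < len(SPLITS):
        raise ValueError("need at least 3 patients to split")

    def key(pid: str) -> str:
        return hashlib.blake2b(f"{seed}:{pid}".encode(), digest_size=8).hexdigest()

    ordered = sorted(pids, key=key)
    n = len(ordered)
    cuts = [round(sum(fractions[: i + 1]) * n) for i in range(len(fractions))]
    assignment: dict[str, str] = {}
    start = 0
    for split, stop in zip(SPLITS, cuts):
        for pid in ordered[start:stop]:
            assignment[pid] = split
        start = stop
    return assignment
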