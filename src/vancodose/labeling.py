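"""Target-daily-dose label derivation from injection/trough sequences.

The label a dose recommender needs — the daily dose that would put *this*
patient's trough into the therapeutic window *now* — is not recorded anywhere
in an EHR.  It is derived here from the observed titration sequence:

1. convert each administration to a daily dose by summing doses over the
   20 h ending at the anchoring injection, excluding anything more than 30 h
   before the corresponding trough measurement;
2. pair each trough with its closest prior injection (gaps outside 5–28 h are
   flagged for exclusion downstream);
3. if the trough is inside the therapeutic window (14–20 mcg/mL by default),
   the record's target is its own daily dose; otherwise it is the daily dose
   of the earliest later record of the same patient whose trough landed in
   the window — the dose the titration eventually proved to work;
4. targets moving in the wrong direction relative to the measured trough
   (larger dose after a high trough, smaller dose after a low trough) are
   marked invalid.

Each target also carries an acceptable daily-dose range, the hull of ±15 %
and ±250 mg around the target, used by the percentage-in-acceptable-range
(PAR) evaluation metric.

All window boundaries (trough window, 20 h / 30 h aggregation, 5–28 h
matching) are inclusive on both ends.
"""

from __future__ import annotations

import enum
from bisect import bisect_left
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .records_io import InjectionEvent, TroughMeasurement

HOURS = pd.Timedelta(hours=1)

#: daily-dose aggregation: sum doses in the AGG_WINDOW_H hours up to and
#: including the anchor injection ...
AGG_WINDOW_H = 20.0
#: ... but drop anything more than TROUGH_CUTOFF_H hours before the trough.
TROUGH_CUTOFF_H = 30.0
#: a trough reflects an injection only when drawn 5-28 h after it.
MATCH_GAP_H = (5.0, 28.0)


@dataclass(frozen=True)
class TherapeuticWindow:
    """Desired vancomycin trough range, mcg/mL (inclusive bounds)."""

    low: float = 14.0
    high: float = 20.0

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"require 0 < low < high, got [{self.low}, {self.high}]")

    def __contains__(self, trough: float) -> bool:
        return self.low <= trough <= self.high


class LabelStatus(enum.Enum):
    """How (or whether) a record's target daily dose was derived."""

    IN_RANGE_SELF = "in_range_self"  # rule 1: own trough in window
    FROM_FUTURE = "from_future"      # rule 2: later in-window record
    MISSING = "missing"              # rule 2 found no in-window successor
    INVALID_HIGH = "invalid_high"    # target > dose although trough was high
    INVALID_LOW = "invalid_low"      # target < dose although trough was low

    @property
    def valid(self) -> bool:
        return self in (LabelStatus.IN_RANGE_SELF, LabelStatus.FROM_FUTURE)


@dataclass(frozen=True)
class DoseRecord:
    """One injection anchor with its aggregated daily dose and matched trough.

    ``is_initial`` is True when the patient has no vancomycin lab test before
    ``anchor_time`` (they may still have prior injections).
    """

    patient_id: str
    anchor_time: pd.Timestamp
    daily_dose: float
    trough_time: pd.Timestamp | None = None
    trough: float | None = None
    hours_since_last_injection: float | None = None
    is_initial: bool = False

    def __post_init__(self):
        if self.daily_dose <= 0:
            raise ValueError("daily_dose must be > 0")
        if self.trough is not None and self.trough_time is not None:
            if not self.trough_time > self.anchor_time:
                raise ValueError("trough_time must follow anchor_time")


@dataclass(frozen=True)
class LabeledRecord(DoseRecord):
    """DoseRecord plus derived target, validity status and acceptable range."""

    target_daily_dose: float | None = None
    label_status: LabelStatus = LabelStatus.MISSING
    acceptable_low: float | None = None
    acceptable_high: float | None = None


class EmptyWindowError(ValueError):
    """The anchor injection lies more than 30 h before its trough."""


def acceptable_range(target: float) -> tuple[float, float]:
    """Acceptable daily-dose interval around a target (mg/day).

    The hull of the relative band [85 %, 115 %] and the absolute band
    ±250 mg: ``low = min(0.85·t, t − 250)``, ``high = max(1.15·t, t + 250)``.
    Below about 1667 mg/day the absolute band is the wider one.
    """
    if target <= 0:
        raise ValueError("target must be > 0")
    return min(0.85 * target, target - 250.0), max(1.15 * target, target + 250.0)


def aggregate_daily_dose(
    injections: Sequence[InjectionEvent],
    anchor: InjectionEvent,
    trough_time: pd.Timestamp,
) -> float:
    """Daily dose (mg/day) anchored at one injection.

    Sums ``dose_mg`` over the patient's injections in the 20 h up to and
    including the anchor, excluding any dose more than 30 h before
    ``trough_time``.  The anchor itself always contributes as long as it is
    within 30 h of the trough; otherwise the aggregation window is empty and
    :class:`EmptyWindowError` is raised (such records are excluded later).
    """
    trough_time = pd.Timestamp(trough_time)
    if (trough_time - anchor.time) / HOURS > TROUGH_CUTOFF_H:
        raise EmptyWindowError(
            f"anchor at {anchor.time} is more than {TROUGH_CUTOFF_H:g} h "
            f"before trough at {trough_time}"
        )
    lo = anchor.time - AGG_WINDOW_H * HOURS
    cutoff = trough_time - TROUGH_CUTOFF_H * HOURS
    total = 0.0
    for e in injections:
        if lo <= e.time <= anchor.time and e.time >= cutoff:
            total += e.dose_mg
    return total


@dataclass(frozen=True)
class TroughMatch:
    """A trough paired with its closest prior injection."""

    trough: TroughMeasurement
    anchor: InjectionEvent | None
    gap_hours: float | None

    @property
    def matched(self) -> bool:
        return self.anchor is not None

    @property
    def gap_in_range(self) -> bool:
        return (
            self.gap_hours is not None
            and MATCH_GAP_H[0] <= self.gap_hours <= MATCH_GAP_H[1]
        )


def match_trough(
    injections: Sequence[InjectionEvent],
    troughs: Sequence[TroughMeasurement],
) -> list[TroughMatch]:
    """Pair each trough with the latest injection strictly before it.

    Works per patient on time-sorted events.  Every trough yields one
    :class:`TroughMatch`; troughs with no prior injection are unmatched.
    When several in-gap troughs share an anchor only the earliest one keeps
    it (``anchor`` is cleared on the later ones), so each injection anchors
    at most one dose record.
    """
    by_patient_inj: dict[str, list[InjectionEvent]] = {}
    for e in injections:
        by_patient_inj.setdefault(e.patient_id, []).append(e)
    for evs in by_patient_inj.values():
        evs.sort(key=lambda e: e.time)

    matches: list[TroughMatch] = []
    anchor_taken: set[tuple[str, pd.Timestamp]] = set()
    for t in sorted(troughs, key=lambda t: (t.patient_id, t.time)):
        evs = by_patient_inj.get(t.patient_id, [])
        times = [e.time for e in evs]
        i = bisect_left(times, t.time)  # first injection at/after the trough
        if i == 0:
            matches.append(TroughMatch(t, None, None))
            continue
        anchor = evs[i - 1]
        gap = (t.time - anchor.time) / HOURS
        m = TroughMatch(t, anchor, gap)
        key = (t.patient_id, anchor.time)
        if m.gap_in_range:
            if key in anchor_taken:
                m = TroughMatch(t, None, gap)  # anchor already paired
            else:
                anchor_taken.add(key)
        matches.append(m)
    return matches


def build_dose_records(
    injections: Sequence[InjectionEvent],
    troughs: Sequence[TroughMeasurement],
    *,
    keep_out_of_gap: bool = False,
) -> list[DoseRecord]:
    """Assemble :class:`DoseRecord` drafts from raw events.

    One record per kept trough/anchor pair, with the aggregated daily dose,
    the gap to the previous injection and the initial/subsequent flag.
    Pairs whose trough-to-injection gap lies outside 5-28 h are dropped
    unless ``keep_out_of_gap`` (they are counted by the cohort module).
    """
    by_patient_inj: dict[str, list[InjectionEvent]] = {}
    for e in injections:
        by_patient_inj.setdefault(e.patient_id, []).append(e)
    for evs in by_patient_inj.values():
        evs.sort(key=lambda e: e.time)
    trough_times: dict[str, list[pd.Timestamp]] = {}
    for t in troughs:
        trough_times.setdefault(t.patient_id, []).append(t.time)
    for ts in trough_times.values():
        ts.sort()

    records = []
    for m in match_trough(injections, troughs):
        if not m.matched or not (m.gap_in_range or keep_out_of_gap):
            continue
        evs = by_patient_inj[m.trough.patient_id]
        try:
            daily = aggregate_daily_dose(evs, m.anchor, m.trough.time)
        except EmptyWindowError:
            continue
        times = [e.time for e in evs]
        i = times.index(m.anchor.time)
        hsli = (m.anchor.time - times[i - 1]) / HOURS if i > 0 else None
        prior_troughs = trough_times.get(m.trough.patient_id, [])
        is_initial = bisect_left(prior_troughs, m.anchor.time) == 0
        records.append(
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
    records.sort(key=lambda r: (r.patient_id, r.anchor_time))
    return records


def validate_target(record: LabeledRecord) -> LabelStatus:
    """Flag targets that move the dose the wrong way.

    A target *larger* than the current daily dose while the trough was
    already above the window, or *smaller* while the trough was below it,
    cannot be a credible titration endpoint and is marked invalid.
    """
    if record.target_daily_dose is None:
        return record.label_status
    if record.target_daily_dose > record.daily_dose and record.trough > 20:
        return LabelStatus.INVALID_HIGH
    if record.target_daily_dose < record.daily_dose and record.trough < 14:
        return LabelStatus.INVALID_LOW
    return record.label_status


def derive_targets(
    records: Sequence[DoseRecord],
    window: TherapeuticWindow = TherapeuticWindow(),
) -> list[LabeledRecord]:
    """Apply the two-rule target derivation to per-patient record sequences.

    Rule 1: a record whose trough is inside ``window`` is its own target.
    Rule 2: otherwise the target is the daily dose of the earliest subsequent
    record of the same patient whose trough is in the window (ties on
    identical anchor times broken toward the larger daily dose); if none
    exists the label is missing.  Invalid-direction targets are then flagged
    by :func:`validate_target`, and the acceptable range is attached.

    Records may be passed in any order; derivation keys on anchor time
    within each patient.
    """
    by_patient: dict[str, list[DoseRecord]] = {}
    for r in records:
        if r.trough is None:
            raise ValueError("derive_targets requires records with troughs")
        by_patient.setdefault(r.patient_id, []).append(r)

    out: list[LabeledRecord] = []
    for recs in by_patient.values():
        recs = sorted(recs, key=lambda r: (r.anchor_time, -r.daily_dose))
        in_window = [r.trough in window for r in recs]
        for i, r in enumerate(recs):
            if in_window[i]:
                target, status = r.daily_dose, LabelStatus.IN_RANGE_SELF
            else:
                target, status = None, LabelStatus.MISSING
                for j in range(i + 1, len(recs)):
                    if in_window[j]:
                        target, status = recs[j].daily_dose, LabelStatus.FROM_FUTURE
                        break
            labeled = LabeledRecord(
                **{f: getattr(r, f) for f in (
                    "patient_id", "anchor_time", "daily_dose", "trough_time",
                    "trough", "hours_since_last_injection", "is_initial")},
                target_daily_dose=target,
                label_status=status,
            )
            status = validate_target(labeled)
            low = high = None
            if target is not None:
                low, high = acceptable_range(target)
            out.append(replace(labeled, label_status=status,
                               acceptable_low=low, acceptable_high=high))
    out.sort(key=lambda r: (r.patient_id, r.anchor_time))
    return out


def labeled_to_frame(records: Sequence[LabeledRecord]) -> pd.DataFrame:
    """LabeledRecords as the documented ``labeled_records.csv`` layout."""
    cols = [
        "patient_id", "anchor_time", "daily_dose", "trough",
        "target_daily_dose", "label_status", "acceptable_low",
        "acceptable_high", "is_initial", "hours_since_last_injection",
    ]
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in cols}
        row["label_status"] = r.label_status.value
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)
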