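"""Model-input features for the dose recommenders.

Every feature is computed strictly from information available *before* the
record's anchor time (the moment the dose is decided): demographics, renal
function, dialysis status, one-year ATC level-1 dispensing counts, the latest
chemistry labs within a one-year lookback, and the patient's own
injection/trough history.  History features come in two flavours:

``*_no_filter``
    computed over all raw events, including those the cohort exclusion
    criteria later discard;
``*_with_filter``
    computed only over records that survived cohort exclusion (and whose
    trough had already been measured by the anchor time).

Missing values stay missing (NaN) — the boosted-tree models route them
natively — and are never imputed to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .labeling import AGG_WINDOW_H, LabeledRecord
from .records_io import ATC_LEVEL1

HOURS = pd.Timedelta(hours=1)
DAY_H = 24.0
LOOKBACK_DAYS = 365.0

#: non-dialysis vancomycin clearance per mL/min of creatinine clearance
VANCO_CL_PER_CRCL = 0.06  # L/h per mL/min
VANCO_CL_FLOOR = 0.3      # L/h, anuric non-dialysis floor
VANCO_CL_HD = 0.48        # L/h, fixed under intermittent hemodialysis

#: a patient counts as "on hemodialysis" at an anchor when a session is
#: recorded within this many days before it
HD_LOOKBACK_DAYS = 7.0

INITIAL_FEATURES = [
    "weight_kg", "age_years", "is_female", "hemodialysis",
    "latest_serum_creatinine", "latest_albumin", "latest_egfr",
    "creatinine_clearance", "continuous_infusion_vanco_clearance",
    "atc_A_count_1y", "atc_B_count_1y", "atc_C_count_1y",
    "daily_injection_frequency", "last_daily_dose_no_filter",
    "hours_since_last_injection",
]

SUBSEQUENT_FEATURES = [
    "weight_kg", "age_years", "is_female", "hemodialysis",
    "latest_serum_creatinine", "creatinine_clearance",
    "continuous_infusion_vanco_clearance",
    "atc_A_count_1y", "atc_B_count_1y", "atc_C_count_1y",
    "daily_injection_frequency",
    "last_daily_dose_no_filter", "last_daily_dose_with_filter",
    "last_trough_no_filter", "last_trough_with_filter",
    "hours_since_last_injection", "hours_since_last_trough",
]

DEFAULT_MANIFESTS = {"initial": INITIAL_FEATURES, "subsequent": SUBSEQUENT_FEATURES}


def creatinine_clearance(
    age_years: float, weight_kg: float, is_female: bool,
    serum_creatinine_umol_l: float | None,
) -> float | None:
    """Cockcroft–Gault creatinine clearance, mL/min.

    ``CrCl = (140 − age) · weight / (72 · SCr[mg/dL])``, times 0.85 for
    women; serum creatinine converts as 1 mg/dL = 88.4 µmol/L.  Returns
    None when creatinine is missing.
    """
    if serum_creatinine_umol_l is None or (
        isinstance(serum_creatinine_umol_l, float) and np.isnan(serum_creatinine_umol_l)
    ):
        return None
    if serum_creatinine_umol_l <= 0:
        raise ValueError("serum creatinine must be > 0")
    scr_mg_dl = serum_creatinine_umol_l / 88.4
    crcl = (140.0 - age_years) * weight_kg / (72.0 * scr_mg_dl)
    if is_female:
        crcl *= 0.85
    return max(crcl, 0.0)


def vanco_clearance(
    creatinine_clearance_ml_min: float | None, hemodialysis: bool
) -> float | None:
    """Continuous-infusion vancomycin clearance estimate, L/h.

    Linear in creatinine clearance (0.06 L/h per mL/min) with a 0.3 L/h
    floor for anuric non-dialysis patients; a fixed 0.48 L/h under
    hemodialysis.  Missing CrCl gives None unless on dialysis.
    """
    if hemodialysis:
        return VANCO_CL_HD
    if creatinine_clearance_ml_min is None or (
        isinstance(creatinine_clearance_ml_min, float)
        and np.isnan(creatinine_clearance_ml_min)
    ):
        return None
    if creatinine_clearance_ml_min < 0:
        raise ValueError("creatinine clearance must be >= 0")
    return max(VANCO_CL_PER_CRCL * creatinine_clearance_ml_min, VANCO_CL_FLOOR)


def group_dispensing(dispensing: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pre-grouped dispensing index: patient → (times, level-1 letters)."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if len(dispensing) == 0:
        return out
    df = dispensing.assign(time=pd.to_datetime(dispensing["time"]))
    for pid, g in df.groupby("patient_id", sort=False):
        out[str(pid)] = (
            g["time"].to_numpy(),
            g["atc_code"].astype(str).str[0].to_numpy(),
        )
    return out


def atc_counts(
    dispensing, patient_id: str, anchor_time: pd.Timestamp
) -> dict[str, int]:
    """Dispensing counts per ATC level-1 letter over the year before the anchor.

    The lookback is the open interval ``(anchor − 365 d, anchor)``: an event
    exactly one year before, or at the anchor itself, does not count.
    Patients with no dispensing rows get all-zero counts (count features are
    never missing).  ``dispensing`` may be the raw table or a
    :func:`group_dispensing` index.
    """
    if isinstance(dispensing, pd.DataFrame):
        dispensing = group_dispensing(dispensing)
    anchor = np.datetime64(pd.Timestamp(anchor_time), "ns")
    counts = {letter: 0 for letter in sorted(ATC_LEVEL1)}
    if patient_id not in dispensing:
        return counts
    times, letters = dispensing[patient_id]
    lo = anchor - np.timedelta64(int(LOOKBACK_DAYS * 24 * 3600), "s")
    mask = (times > lo) & (times < anchor)
    for letter in letters[mask]:
        counts[letter] += 1
    return counts


def group_labs(labs: pd.DataFrame) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Pre-grouped lab index: (patient, analyte) → time-sorted (times, values)."""
    out: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    if len(labs) == 0:
        return out
    df = labs.assign(time=pd.to_datetime(labs["time"])).sort_values("time")
    for (pid, analyte), g in df.groupby(["patient_id", "analyte"], sort=False):
        out[(str(pid), str(analyte))] = (
            g["time"].to_numpy(), g["value"].to_numpy(dtype=float)
        )
    return out


def latest_lab(
    labs, patient_id: str, analyte: str, anchor_time: pd.Timestamp
) -> float | None:
    """Most recent lab value strictly before the anchor and within one year.

    ``labs`` may be the raw table or a :func:`group_labs` index.
    """
    if isinstance(labs, pd.DataFrame):
        labs = group_labs(labs)
    key = (patient_id, analyte)
    if key not in labs:
        return None
    times, values = labs[key]
    anchor = np.datetime64(pd.Timestamp(anchor_time), "ns")
    lo = anchor - np.timedelta64(int(LOOKBACK_DAYS * 24 * 3600), "s")
    i = int(np.searchsorted(times, anchor, side="left"))
    if i == 0 or not times[i - 1] > lo:
        return None
    return float(values[i - 1])


@dataclass
class _PatientEvents:
    """Per-patient sorted raw event arrays for fast lookback."""

    inj_times: np.ndarray   # datetime64[ns]
    inj_doses: np.ndarray
    trough_times: np.ndarray
    trough_values: np.ndarray


def _index_events(injections: pd.DataFrame, troughs: pd.DataFrame) -> dict[str, _PatientEvents]:
    out: dict[str, _PatientEvents] = {}
    inj = injections.assign(time=pd.to_datetime(injections["time"])).sort_values("time")
    tr = troughs.assign(time=pd.to_datetime(troughs["time"])).sort_values("time")
    for pid, g in inj.groupby("patient_id", sort=False):
        out[str(pid)] = _PatientEvents(
            g["time"].to_numpy(), g["dose_mg"].to_numpy(dtype=float),
            np.array([], dtype="datetime64[ns]"), np.array([]),
        )
    for pid, g in tr.groupby("patient_id", sort=False):
        pe = out.setdefault(
            str(pid),
            _PatientEvents(np.array([], dtype="datetime64[ns]"), np.array([]),
                           np.array([], dtype="datetime64[ns]"), np.array([])),
        )
        pe.trough_times = g["time"].to_numpy()
        pe.trough_values = g["concentration"].to_numpy(dtype=float)
    return out


def history_features(
    record: LabeledRecord,
    events: _PatientEvents,
    filtered_history: Sequence[LabeledRecord],
) -> dict[str, float | None]:
    """Injection/trough history features at one record's anchor.

    ``filtered_history`` is the patient's cohort-surviving records;
    with-filter features only use those whose trough was already measured
    by the anchor time.  No-filter features scan all raw events strictly
    before the anchor.
    """
    anchor = np.datetime64(pd.Timestamp(record.anchor_time), "ns")
    out: dict[str, float | None] = {
        "last_daily_dose_no_filter": None,
        "last_trough_no_filter": None,
        "hours_since_last_injection": None,
        "hours_since_last_trough": None,
        "last_daily_dose_with_filter": None,
        "last_trough_with_filter": None,
        "daily_injection_frequency": 0.0,
    }
    # --- raw (no-filter) side
    i = int(np.searchsorted(events.inj_times, anchor, side="left"))
    if i > 0:
        prev_t = events.inj_times[i - 1]
        out["hours_since_last_injection"] = float((anchor - prev_t) / np.timedelta64(1, "h"))
        lo = prev_t - np.timedelta64(int(AGG_WINDOW_H * 3600), "s")
        mask = (events.inj_times >= lo) & (events.inj_times <= prev_t)
        out["last_daily_dose_no_filter"] = float(events.inj_doses[mask].sum())
    j = int(np.searchsorted(events.trough_times, anchor, side="left"))
    if j > 0:
        out["hours_since_last_trough"] = float(
            (anchor - events.trough_times[j - 1]) / np.timedelta64(1, "h")
        )
        out["last_trough_no_filter"] = float(events.trough_values[j - 1])
    lo24 = anchor - np.timedelta64(24, "h")
    out["daily_injection_frequency"] = float(
        ((events.inj_times > lo24) & (events.inj_times <= anchor)).sum()
    )
    # --- cohort-filtered side
    best = None
    for r in filtered_history:
        if r.trough_time is not None and pd.Timestamp(r.trough_time) < record.anchor_time:
            if best is None or r.anchor_time > best.anchor_time:
                best = r
    if best is not None:
        out["last_daily_dose_with_filter"] = float(best.daily_dose)
        out["last_trough_with_filter"] = float(best.trough)
    return out


@dataclass
class FeatureMatrix:
    """Aligned feature matrix, labels and provenance for one model mode."""

    X: pd.DataFrame
    y: pd.Series
    manifest: list[str]
    mode: str
    records: list[LabeledRecord]

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        df = self.X.copy()
        df["target_daily_dose"] = self.y.to_numpy()
        df.insert(0, "patient_id", [r.patient_id for r in self.records])
        df.to_csv(f"{prefix}.csv", index=False)
        with open(f"{prefix}.manifest.json", "w") as fh:
            json.dump({"mode": self.mode, "columns": self.manifest}, fh, indent=1)


def build_matrix(
    records: Sequence[LabeledRecord],
    tables: Mapping[str, pd.DataFrame],
    mode: str,
    manifest: Sequence[str] | None = None,
    history_records: Sequence[LabeledRecord] | None = None,
) -> FeatureMatrix:
    """Assemble the feature matrix for one model mode.

    ``records`` must all be of the requested mode (``is_initial`` matching
    ``mode == "initial"``) and carry a target; ``tables`` holds the raw
    tables keyed ``injections, troughs, labs, dispensing, demographics,
    hemodialysis``.  ``history_records`` supplies the cohort-surviving
    records that with-filter history features may draw on — normally the
    *full* labeled cohort, so that e.g. a patient's initial record feeds the
    history of their subsequent records; it defaults to ``records``.  Only a
    patient's own past feeds their features, so the cohort split stays
    leak-free.  Column order follows the manifest and is persisted with the
    matrix.
    """
    if mode not in DEFAULT_MANIFESTS:
        raise ValueError(f"mode must be initial|subsequent, got {mode!r}")
    manifest = list(manifest) if manifest is not None else list(DEFAULT_MANIFESTS[mode])
    for r in records:
        if r.is_initial != (mode == "initial"):
            raise ValueError(
                f"record {r.patient_id}@{r.anchor_time} is not a {mode}-mode record"
            )
    demo = tables["demographics"].set_index(tables["demographics"]["patient_id"].astype(str))
    labs = group_labs(tables["labs"])
    disp = group_dispensing(tables["dispensing"])
    hd = tables["hemodialysis"]
    hd_times: dict[str, np.ndarray] = {}
    if len(hd):
        hdf = hd.assign(time=pd.to_datetime(hd["time"])).sort_values("time")
        for pid, g in hdf.groupby("patient_id", sort=False):
            hd_times[str(pid)] = g["time"].to_numpy()
    events = _index_events(tables["injections"], tables["troughs"])
    empty = _PatientEvents(
        np.array([], dtype="datetime64[ns]"), np.array([]),
        np.array([], dtype="datetime64[ns]"), np.array([]),
    )
    by_patient: dict[str, list[LabeledRecord]] = {}
    for r in (history_records if history_records is not None else records):
        by_patient.setdefault(r.patient_id, []).append(r)

    rows = []
    for r in records:
        d = demo.loc[r.patient_id]
        anchor = np.datetime64(pd.Timestamp(r.anchor_time), "ns")
        on_hd = False
        if r.patient_id in hd_times:
            lo = anchor - np.timedelta64(int(HD_LOOKBACK_DAYS * 24), "h")
            t = hd_times[r.patient_id]
            on_hd = bool(((t > lo) & (t < anchor)).any())
        scr = latest_lab(labs, r.patient_id, "serum_creatinine", r.anchor_time)
        crcl = creatinine_clearance(
            float(d["age_years"]), float(d["weight_kg"]), bool(int(d["is_female"])), scr
        )
        row: dict[str, float | None] = {
            "weight_kg": float(d["weight_kg"]),
            "age_years": float(d["age_years"]),
            "is_female": float(int(d["is_female"])),
            "hemodialysis": float(on_hd),
            "latest_serum_creatinine": scr,
            "latest_albumin": latest_lab(labs, r.patient_id, "albumin", r.anchor_time),
            "latest_egfr": latest_lab(labs, r.patient_id, "egfr", r.anchor_time),
            "creatinine_clearance": crcl,
            "continuous_infusion_vanco_clearance": vanco_clearance(crcl, on_hd),
        }
        for letter, n in atc_counts(disp, r.patient_id, r.anchor_time).items():
            row[f"atc_{letter}_count_1y"] = float(n)
        row.update(
            history_features(r, events.get(r.patient_id, empty),
                             by_patient.get(r.patient_id, []))
        )
        rows.append([row.get(name) for name in manifest])

    X = pd.DataFrame(rows, columns=manifest, dtype=float)
    y = pd.Series([r.target_daily_dose for r in records], name="target_daily_dose", dtype=float)
    if y.isna().any():
        raise ValueError("all records must carry a target daily dose")
    return FeatureMatrix(X=X, y=y, manifest=manifest, mode=mode, records=list(records))
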