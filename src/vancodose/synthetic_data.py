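"""EHR-style synthetic cohort generator for trough-guided vancomycin dosing.

The generator emulates the tables the pipeline expects — administrations,
trough measurements, chemistry labs, ATC-coded dispensing, demographics and
hemodialysis sessions — with the statistical structure the analysis assumes:

* population one-compartment intermittent-infusion pharmacokinetics with
  covariate-driven clearance (0.06 L/h per mL/min Cockcroft–Gault, lognormal
  between-subject variability) and lognormal residual error on measured
  troughs;
* a stylized, deliberately imperfect physician titration policy: a
  weight-based starting dose, then proportional-to-trough adjustment with
  probability ``p_titrate`` and a random perturbation otherwise, so a
  realistic share of troughs misses the 14–20 mcg/mL window and rule-2
  labels are exercised;
* configurable data-quality defects mirroring the cohort exclusion
  criteria, planted with ground-truth labels so tests can check recovery.

A hidden per-patient truth table (true clearance, volume, and the oracle
daily dose whose steady-state trough is exactly on target) is emitted for
tests only; the pipeline never reads it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import VANCO_CL_FLOOR, VANCO_CL_HD, VANCO_CL_PER_CRCL, creatinine_clearance

HOUR = pd.Timedelta(hours=1)
BASE_DATE = pd.Timestamp("2019-01-01 08:00")

TABLE_KEYS = ("injections", "troughs", "labs", "dispensing", "demographics", "hemodialysis")


def steady_state_trough(
    daily_dose: float, interval_h: float, cl_l_h: float, v_l: float,
    t_inf_h: float = 1.0,
) -> float:
    """Steady-state trough (mcg/mL) of an intermittent 1-compartment regimen.

    ``Cmin = (D/(t_inf·CL)) · (1−e^(−k·t_inf)) · e^(−k·(τ−t_inf)) / (1−e^(−k·τ))``
    with per-dose amount ``D = daily_dose·τ/24`` and ``k = CL/V``.  Linear in
    the daily dose.
    """
    if min(daily_dose, interval_h, cl_l_h, v_l, t_inf_h) <= 0:
        raise ValueError("all PK inputs must be positive")
    k = cl_l_h / v_l
    dose = daily_dose * interval_h / 24.0
    peak_factor = (1.0 - math.exp(-k * t_inf_h)) / (t_inf_h * cl_l_h)
    return dose * peak_factor * math.exp(-k * (interval_h - t_inf_h)) / (
        1.0 - math.exp(-k * interval_h)
    )


def oracle_dose(
    cl_l_h: float, v_l: float, interval_h: float, target_trough: float = 17.0,
    t_inf_h: float = 1.0,
) -> float:
    """Daily dose (mg/day) whose steady-state trough equals ``target_trough``.

    Exact inversion of :func:`steady_state_trough` through its linearity in
    the daily dose.
    """
    ref = steady_state_trough(1.0, interval_h, cl_l_h, v_l, t_inf_h)
    return target_trough / ref


@dataclass(frozen=True)
class SimParams:
    """Study-condition parameters of the synthetic cohort."""

    n_patients: int = 200
    seed: int = 0
    # demographics
    age_mean: float = 63.1
    age_sd: float = 14.3
    weight_mean: float = 64.7
    weight_sd: float = 17.2
    female_fraction: float = 0.3
    hemodialysis_fraction: float = 0.1
    # pharmacokinetics
    volume_per_kg: float = 0.7           # L/kg
    cl_per_crcl: float = VANCO_CL_PER_CRCL  # L/h per mL/min
    bsv_cl_sd: float = 0.3               # lognormal between-subject SD
    residual_sd: float = 0.15            # lognormal residual SD on troughs
    infusion_h: float = 1.0
    # physician policy
    initial_mg_per_kg: tuple[float, float] = (15.0, 20.0)  # per dose, uniform
    p_titrate: float = 0.8
    target_trough: float = 17.0
    # data quality / coverage
    lab_coverage: float = 0.61           # fraction with labs in the past year
    trough_coverage: float = 0.9         # fraction of trough draws performed
    defect_rates: dict = field(default_factory=dict)
    # course
    min_days: int = 3
    max_days: int = 14

    def __post_init__(self):
        for name in ("female_fraction", "hemodialysis_fraction", "p_titrate",
                     "lab_coverage", "trough_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("volume_per_kg", "cl_per_crcl", "target_trough", "infusion_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _round_dose(dose_mg: float) -> float:
    """Administrable amounts: multiples of 250 mg, at least 250."""
    return max(250.0, 250.0 * round(dose_mg / 250.0))


def _interval_for(crcl: float | None, hd: bool, rng: np.random.Generator) -> float:
    if hd:
        return 48.0
    if crcl is None or crcl < 30:
        return 24.0
    if crcl < 90:
        return 12.0
    return 8.0 if rng.random() < 0.5 else 12.0


def simulate_cohort(params: SimParams) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate the six raw tables plus the hidden truth table.

    Per patient: demographics, a 3–14 day dosing course with administrations
    every 8/12/24 h (48 h under hemodialysis), trough draws shortly before a
    dose at the configured coverage, proportional-to-trough titration with
    probability ``p_titrate``, chemistry labs for a ``lab_coverage`` share of
    patients, and Poisson ATC dispensing histories.  Deterministic given
    ``params.seed`` (one child random stream per patient).
    """
    root = np.random.SeedSequence(params.seed)
    patient_seeds = root.spawn(max(params.n_patients, 1))

    inj_rows, trough_rows, lab_rows, disp_rows = [], [], [], []
    demo_rows, hd_rows, truth_rows = [], [], []

    for i in range(params.n_patients):
        rng = np.random.default_rng(patient_seeds[i])
        pid = f"P{i:05d}"
        age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 18, 95))
        weight = float(np.clip(rng.normal(params.weight_mean, params.weight_sd), 35, 130))
        female = bool(rng.random() < params.female_fraction)
        hd = bool(rng.random() < params.hemodialysis_fraction)
        demo_rows.append(
            {"patient_id": pid, "age_years": round(age, 1),
             "is_female": int(female), "weight_kg": round(weight, 1)}
        )

        scr = float(np.clip(rng.lognormal(math.log(75.0), 0.45), 30, 600))
        if hd:
            scr = float(min(scr * 3.0, 900.0))
        crcl = creatinine_clearance(age, weight, female, scr)
        egfr = float(np.clip(crcl * rng.lognormal(0, 0.1), 5, 200))
        albumin = float(np.clip(rng.normal(28.7, 5.6), 12, 50))

        # true PK
        if hd:
            cl = float(VANCO_CL_HD * rng.lognormal(0, 0.2))
        else:
            cl = float(max(params.cl_per_crcl * crcl, VANCO_CL_FLOOR)
                       * rng.lognormal(0, params.bsv_cl_sd))
        v = float(params.volume_per_kg * weight * rng.lognormal(0, 0.1))
        tau = _interval_for(crcl, hd, rng)

        start = BASE_DATE + int(rng.integers(0, 300)) * 24 * HOUR + \
            int(rng.integers(0, 24)) * HOUR
        course_h = float(rng.integers(params.min_days, params.max_days + 1) * 24)
        truth_rows.append(
            {"patient_id": pid, "cl_l_h": cl, "v_l": v, "interval_h": tau,
             "oracle_daily_dose": oracle_dose(cl, v, tau, params.target_trough,
                                              params.infusion_h)}
        )

        # chemistry labs: recent panel for covered patients, stale otherwise
        lab_time = start - float(rng.uniform(24, 300 * 24)) * HOUR \
            if rng.random() < params.lab_coverage \
            else start - float(rng.uniform(400 * 24, 700 * 24)) * HOUR
        for analyte, value in (
            ("serum_creatinine", round(scr, 1)),
            ("albumin", round(albumin, 1)),
            ("egfr", round(egfr, 1)),
        ):
            lab_rows.append({"patient_id": pid, "time": lab_time,
                             "analyte": analyte, "value": value})

        # dispensing history over the previous year
        for letter, lam in (("A", 8.0), ("B", 3.0), ("C", 5.0), ("J", 2.0), ("N", 3.0)):
            for _ in range(int(rng.poisson(lam))):
                disp_rows.append(
                    {"patient_id": pid,
                     "time": start - float(rng.uniform(1, 364 * 24)) * HOUR,
                     "atc_code": letter + "01AA01"}
                )

        if hd:
            t = start
            while t < start + course_h * HOUR:
                hd_rows.append({"patient_id": pid, "time": t})
                t += 48 * HOUR

        # dosing course
        if hd:
            per_dose = _round_dose(20.0 * weight)
        else:
            # policy states mg/kg per 12 h; scale to the chosen interval
            per_dose = _round_dose(
                float(rng.uniform(*params.initial_mg_per_kg)) * weight * tau / 12.0
            )
        t = 0.0
        next_trough_h = tau * max(1.0, round(36.0 / tau))  # ~steady-ish state
        while t < course_h:
            inj_rows.append(
                {"patient_id": pid, "time": start + t * HOUR, "dose_mg": per_dose}
            )
            next_dose_h = t + tau
            if next_dose_h >= next_trough_h and next_dose_h < course_h:
                gap = min(tau, 28.0) - 2.0 + float(rng.uniform(-1, 1))
                trough_time = t + gap
                daily = per_dose * 24.0 / tau
                c = steady_state_trough(daily, tau, cl, v, params.infusion_h)
                c *= float(rng.lognormal(0, params.residual_sd))
                measured = rng.random() < params.trough_coverage
                if measured:
                    trough_rows.append(
                        {"patient_id": pid, "time": start + trough_time * HOUR,
                         "concentration": round(max(c, 0.1), 1)}
                    )
                    # physician reacts to the measured trough
                    if rng.random() < params.p_titrate:
                        per_dose = _round_dose(per_dose * params.target_trough / max(c, 1.0))
                    else:
                        per_dose = _round_dose(per_dose * float(rng.uniform(0.7, 1.3)))
                next_trough_h = trough_time + 48.0
            t = next_dose_h

    def frame(rows, cols):
        df = pd.DataFrame(rows, columns=cols)
        if "time" in cols and len(df):
            df["time"] = pd.to_datetime(df["time"]).dt.floor("min")
        return df

    tables = {
        "injections": frame(inj_rows, ["patient_id", "time", "dose_mg"]),
        "troughs": frame(trough_rows, ["patient_id", "time", "concentration"]),
        "labs": frame(lab_rows, ["patient_id", "time", "analyte", "value"]),
        "dispensing": frame(disp_rows, ["patient_id", "time", "atc_code"]),
        "demographics": frame(
            demo_rows, ["patient_id", "age_years", "is_female", "weight_kg"]
        ),
        "hemodialysis": frame(hd_rows, ["patient_id", "time"]),
    }
    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "cl_l_h", "v_l", "interval_h",
                             "oracle_daily_dose"]
    )
    return tables, truth


@dataclass
class DefectLabels:
    """Ground truth of planted data-quality defects (by criterion)."""

    low_dose_rows: int = 0          # criterion 1: added sub-10 mg injections
    blank_id_rows: int = 0          # criterion 2: added blank-ID events
    missing_weight_patients: list[str] = field(default_factory=list)  # criterion 3
    mistimed_troughs: int = 0       # criterion 4: troughs moved to 2 h gaps
    never_in_range_patients: list[str] = field(default_factory=list)  # criterion 6


def plant_defects(
    tables: dict[str, pd.DataFrame], params: SimParams
) -> tuple[dict[str, pd.DataFrame], DefectLabels]:
    """Inject labeled data-quality violations at ``params.defect_rates``.

    Recognized rates (all default 0): ``low_dose`` and ``blank_id`` (new bad
    rows per existing injection), ``missing_weight`` and ``never_in_range``
    (fraction of patients), ``mistimed_trough`` (fraction of troughs moved
    to 2 h after their prior injection).  Rates of zero leave the tables
    unchanged.  Returns modified copies plus the ground-truth labels.
    """
    rates = dict(params.defect_rates)
    labels = DefectLabels()
    out = {k: v.copy() for k, v in tables.items()}
    if not rates:
        return out, labels
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0].spawn(1)[0])
    inj = out["injections"]
    pids = sorted(out["demographics"]["patient_id"].astype(str))

    n_low = int(round(rates.get("low_dose", 0.0) * len(inj)))
    if n_low:
        last = pd.to_datetime(inj["time"]).max()
        rows = [
            {"patient_id": str(rng.choice(pids)),
             "time": last + (100 + 8 * j) * HOUR,
             "dose_mg": float(rng.uniform(1, 9))}
            for j in range(n_low)
        ]
        out["injections"] = pd.concat([inj, pd.DataFrame(rows)], ignore_index=True)
        labels.low_dose_rows = n_low

    n_blank = int(round(rates.get("blank_id", 0.0) * len(inj)))
    if n_blank:
        last = pd.to_datetime(out["injections"]["time"]).max()
        rows = [
            {"patient_id": "", "time": last + (100 + 8 * j) * HOUR,
             "dose_mg": 1000.0}
            for j in range(n_blank)
        ]
        out["injections"] = pd.concat(
            [out["injections"], pd.DataFrame(rows)], ignore_index=True
        )
        labels.blank_id_rows = n_blank

    n_w = int(round(rates.get("missing_weight", 0.0) * len(pids)))
    if n_w:
        chosen = list(rng.choice(pids, size=n_w, replace=False))
        demo = out["demographics"]
        mask = demo["patient_id"].astype(str).isin(chosen)
        demo.loc[mask, "weight_kg"] = np.nan
        labels.missing_weight_patients = sorted(chosen)

    n_mist = int(round(rates.get("mistimed_trough", 0.0) * len(out["troughs"])))
    if n_mist:
        tr = out["troughs"]
        idx = rng.choice(len(tr), size=n_mist, replace=False)
        inj_by_pid = {
            pid: g.sort_values("time")["time"].to_numpy()
            for pid, g in out["injections"]
            .assign(time=pd.to_datetime(out["injections"]["time"]))
            .groupby(out["injections"]["patient_id"].astype(str))
        }
        times = pd.to_datetime(tr["time"]).to_numpy()
        for j in idx:
            pid = str(tr.iloc[j]["patient_id"])
            prior = inj_by_pid.get(pid)
            if prior is None:
                continue
            k = int(np.searchsorted(prior, times[j], side="left"))
            if k == 0:
                continue
            times[j] = prior[k - 1] + np.timedelta64(2, "h")
            labels.mistimed_troughs += 1
        tr["time"] = times

    n_nir = int(round(rates.get("never_in_range", 0.0) * len(pids)))
    if n_nir:
        avoid = set(labels.missing_weight_patients)
        candidates = [p for p in pids if p not in avoid]
        chosen = list(rng.choice(candidates, size=min(n_nir, len(candidates)),
                                 replace=False))
        tr = out["troughs"]
        mask = tr["patient_id"].astype(str).isin(chosen)
        tr.loc[mask, "concentration"] = 25.0  # permanently supra-therapeutic
        labels.never_in_range_patients = sorted(chosen)

    return out, labels


def write_tables(tables: dict[str, pd.DataFrame], out_dir) -> None:
    """Write the raw tables as the conventional CSVs (ISO-8601 minutes)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for kind, df in tables.items():
        df = df.copy()
        if "time" in df.columns and len(df):
            df["time"] = pd.to_datetime(df["time"]).dt.strftime("%Y-%m-%dT%H:%M")
        df.to_csv(out / f"{kind}.csv", index=False)


def simulate_to_dir(params: SimParams, out_dir) -> None:
    """Simulate and write the six CSVs plus ``truth.csv`` (test-only)."""
    from pathlib import Path

    tables, truth = simulate_cohort(params)
    if params.defect_rates:
        tables, _ = plant_defects(tables, params)
    write_tables(tables, out_dir)
    truth.to_csv(Path(out_dir) / "truth.csv", index=False)
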