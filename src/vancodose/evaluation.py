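"""Evaluation metrics and recommender comparison.

Two metrics:

MAE
    mean absolute deviation of the suggested from the target daily dose,
    ``(1/N) Σ |y_i − ŷ_i|`` in mg/day;
PAR
    percentage in acceptable range, ``(1/N) Σ f(r_i, ŷ_i)`` with
    ``f(r, ŷ) = 1`` iff the suggestion lies inside the record's acceptable
    daily-dose range (bounds inclusive).  PAR credits a suggestion that
    misses the target number but would still have produced a therapeutic
    trough — the clinically relevant question.

:func:`evaluate` scores any named set of suggestion vectors (trained models,
the PK baseline, "current practice" — the record's own daily dose) overall
and stratified by patient weight.  Note that current-practice performance on
a labeled cohort is optimistic: records without a derivable target were
excluded, which preferentially removes failed titrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .labeling import LabeledRecord, acceptable_range

DEFAULT_WEIGHT_BINS = list(range(30, 120, 10))  # 10 kg bins over [30, 110+]


def mae(pairs: Sequence[tuple[float, float]]) -> float:
    """Mean absolute error between target and suggested doses, mg/day."""
    if len(pairs) == 0:
        raise ValueError("mae of an empty list")
    arr = np.asarray(pairs, dtype=float)
    return float(np.abs(arr[:, 0] - arr[:, 1]).mean())


def par(pairs: Sequence[tuple[float, float]]) -> float:
    """Fraction of suggestions inside their target's acceptable range.

    Boundaries are inclusive; the range is always the hull of ±15 % and
    ±250 mg around the target (no further tolerance is applied here).
    """
    if len(pairs) == 0:
        raise ValueError("par of an empty list")
    hits = 0
    for target, suggested in pairs:
        low, high = acceptable_range(target)
        hits += low <= suggested <= high
    return hits / len(pairs)


@dataclass
class StratumScores:
    """MAE/PAR of every recommender on one subset of records."""

    n: int
    mae: dict[str, float]
    par: dict[str, float]

    def to_dict(self) -> dict:
        return {"n": self.n, "mae_mg_day": self.mae, "par": self.par}


@dataclass
class EvaluationReport:
    """Overall and weight-stratified comparison of recommenders."""

    mode: str
    overall: StratumScores
    by_weight: dict[str, StratumScores] = field(default_factory=dict)
    notes: str = (
        "current_practice scores on a labeled cohort are optimistic: records "
        "without a derivable target were excluded before evaluation"
    )

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "overall": self.overall.to_dict(),
            "by_weight_kg": {k: v.to_dict() for k, v in self.by_weight.items()},
            "notes": self.notes,
        }


def _score(targets: np.ndarray, suggestions: Mapping[str, np.ndarray],
           mask: np.ndarray) -> StratumScores:
    n = int(mask.sum())
    maes, pars = {}, {}
    for name, sugg in suggestions.items():
        pairs = list(zip(targets[mask], np.asarray(sugg, dtype=float)[mask]))
        maes[name] = mae(pairs) if n else float("nan")
        pars[name] = par(pairs) if n else float("nan")
    return StratumScores(n=n, mae=maes, par=pars)


def evaluate(
    records: Sequence[LabeledRecord],
    suggestions: Mapping[str, Sequence[float]],
    weights_kg: Sequence[float],
    mode: str,
    weight_bins: Sequence[float] = DEFAULT_WEIGHT_BINS,
    include_current_practice: bool = True,
) -> EvaluationReport:
    """Score recommenders against the records' target daily doses.

    ``suggestions`` maps recommender name to an aligned vector of suggested
    daily doses; ``weights_kg`` is aligned patient weight for stratification.
    Current practice (each record's own aggregated daily dose as the
    suggestion) is added automatically.  The weight bins partition all
    records: values below the first edge join the first bin, values at or
    above the last edge form the open-ended top bin.
    """
    targets = np.array([r.target_daily_dose for r in records], dtype=float)
    if np.isnan(targets).any():
        raise ValueError("all records must have targets")
    sugg = {k: np.asarray(v, dtype=float) for k, v in suggestions.items()}
    for name, v in sugg.items():
        if len(v) != len(records):
            raise ValueError(f"suggestion vector {name!r} is misaligned")
    if include_current_practice:
        sugg = {"current_practice": np.array([r.daily_dose for r in records]), **sugg}
    weights = np.asarray(weights_kg, dtype=float)

    all_mask = np.ones(len(records), dtype=bool)
    report = EvaluationReport(mode=mode, overall=_score(targets, sugg, all_mask))

    edges = list(weight_bins)
    for i, lo in enumerate(edges):
        hi = edges[i + 1] if i + 1 < len(edges) else None
        if hi is None:
            mask = weights >= lo
            label = f"[{lo}, inf)"
        else:
            mask = (weights >= lo) & (weights < hi)
            if i == 0:
                mask |= weights < lo  # underweight tail joins the first bin
                label = f"(-inf, {hi})"
            else:
                label = f"[{lo}, {hi})"
        if mask.any():
            report.by_weight[label] = _score(targets, sugg, mask)
    return report


def scatter_export(
    targets: Sequence[float], suggestions: Sequence[float], mode: str,
    bin_mg: float = 250.0,
) -> pd.DataFrame:
    """Plot-ready table: target, suggestion, in-range flag, 250 mg bins.

    The in-range flag applies the acceptable-range formula per record, so
    its mean equals :func:`par` on the same pairs.
    """
    targets = np.asarray(targets, dtype=float)
    suggestions = np.asarray(suggestions, dtype=float)
    if targets.shape != suggestions.shape:
        raise ValueError("targets and suggestions must align")
    in_range = []
    for t, s in zip(targets, suggestions):
        low, high = acceptable_range(t)
        in_range.append(bool(low <= s <= high))
    return pd.DataFrame(
        {
            "target": targets,
            "suggestion": suggestions,
            "in_range": in_range,
            "target_bin_mg": np.floor(targets / bin_mg) * bin_mg,
            "suggestion_bin_mg": np.floor(suggestions / bin_mg) * bin_mg,
            "mode": mode,
        }
    )
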