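"""Control-based quality control: sensitivity, specificity, control variability.

Each plate carries known positive controls (a reference inhibitor expected to
score below the hit threshold) and negative vehicle controls (expected not
to).  Treating the threshold as a diagnostic test of the controls gives the
per-plate operating characteristics:

    sensitivity = 100 * TP / (TP + FN)     over positive controls
    specificity = 100 * TN / (TN + FP)     over negative controls

where a positive control scoring strictly below the threshold is a true
positive and a negative control scoring at or above it is a true negative.
Tightening the threshold (e.g. -0.5 -> -1.0) can only lower sensitivity and
raise specificity on a fixed plate.  Screen-level QC reports the mean +/- SD
of both metrics across plates, per replicate and per threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .plate_model import (
    AnalysisConfig,
    PlateScreenError,
    ScreenDataset,
    WellRole,
)
from .scoring import PlateScores, ScreenScores


class QCError(PlateScreenError):
    pass


@dataclass
class PlateQC:
    """Control contingency counts and operating characteristics of one plate."""

    plate_id: str
    replicate: int
    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: Optional[float]  # percent; None when no positive control scored
    specificity: Optional[float]  # percent; None when no negative control scored
    flags: list[str] = field(default_factory=list)


def sensitivity_from_counts(tp: int, fn: int) -> Optional[float]:
    """100 * TP / (TP + FN); None when no positives were scored."""
    if tp + fn == 0:
        return None
    return 100.0 * tp / (tp + fn)


def specificity_from_counts(tn: int, fp: int) -> Optional[float]:
    """100 * TN / (TN + FP); None when no negatives were scored."""
    if tn + fp == 0:
        return None
    return 100.0 * tn / (tn + fp)


def plate_sensitivity_specificity(
    plate: PlateScores, threshold: float
) -> PlateQC:
    """Score the plate's controls against an inhibitor threshold.

    Strict inequality: a control exactly at the threshold is not a hit, so a
    negative control at the threshold counts as a true negative.
    """
    pos = plate.scores_for_role(WellRole.POSITIVE_CONTROL)
    neg = plate.scores_for_role(WellRole.NEGATIVE_CONTROL)
    tp = int(np.sum(pos < threshold))
    fn = int(pos.size - tp)
    fp = int(np.sum(neg < threshold))
    tn = int(neg.size - fp)
    flags = []
    if pos.size == 0:
        flags.append("no scored positive controls; sensitivity undefined")
    if neg.size == 0:
        flags.append("no scored negative controls; specificity undefined")
    return PlateQC(
        plate_id=plate.plate_id,
        replicate=plate.replicate,
        threshold=threshold,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=sensitivity_from_counts(tp, fn),
        specificity=specificity_from_counts(tn, fp),
        flags=flags,
    )


@dataclass
class ScreenQC:
    """Per-plate QC plus screen-level mean +/- SD per replicate and threshold."""

    plates: list[PlateQC]
    summary: pd.DataFrame  # replicate, threshold, metric means/SDs, n_plates

    def to_plate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "plate_id": q.plate_id,
                    "replicate": q.replicate,
                    "threshold": q.threshold,
                    "tp": q.tp,
                    "fn": q.fn,
                    "tn": q.tn,
                    "fp": q.fp,
                    "sensitivity": q.sensitivity,
                    "specificity": q.specificity,
                    "flags": "; ".join(q.flags),
                }
                for q in self.plates
            ]
        )


def _mean_sd(values: list[float]) -> tuple[Optional[float], Optional[float]]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(np.mean(arr)), sd


def screen_qc_summary(
    scores: ScreenScores, thresholds: Sequence[float]
) -> ScreenQC:
    """Evaluate every plate at every threshold and summarise across plates.

    Screen means are taken only over plates where the metric is defined
    (at least one scored control of that type).
    """
    if not scores.plates:
        raise QCError("no scored plates to summarise")
    plate_qcs: list[PlateQC] = []
    for plate in scores.plates:
        for thr in thresholds:
            plate_qcs.append(plate_sensitivity_specificity(plate, thr))
    rows = []
    reps = sorted({q.replicate for q in plate_qcs})
    for rep in reps:
        for thr in thresholds:
            group = [q for q in plate_qcs if q.replicate == rep and q.threshold == thr]
            sens = [q.sensitivity for q in group if q.sensitivity is not None]
            spec = [q.specificity for q in group if q.specificity is not None]
            sens_mean, sens_sd = _mean_sd(sens)
            spec_mean, spec_sd = _mean_sd(spec)
            rows.append(
                {
                    "replicate": rep,
                    "threshold": thr,
                    "n_plates": len(group),
                    "sensitivity_mean": sens_mean,
                    "sensitivity_sd": sens_sd,
                    "specificity_mean": spec_mean,
                    "specificity_sd": spec_sd,
                }
            )
    return ScreenQC(plates=plate_qcs, summary=pd.DataFrame(rows))


def _cv_percent(values: np.ndarray) -> float:
    mean = float(np.mean(values))
    if mean == 0:
        return float("nan")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return 100.0 * sd / mean


def control_variability(dataset: ScreenDataset) -> pd.DataFrame:
    """Within- and between-plate variability of raw control fluorescence.

    For each control type (and each day, when day labels exist) reports the
    mean within-plate CV of readings and the between-plate CV of plate control
    means, in percent.  CVs use the sample (n-1) standard deviation.
    """
    rows = []
    control_roles = (WellRole.POSITIVE_CONTROL, WellRole.NEGATIVE_CONTROL)
    for role in control_roles:
        per_plate: dict[tuple[str, int], list[float]] = {}
        day_of_plate: dict[tuple[str, int], Optional[str]] = {}
        for w in dataset.wells:
            if w.role is role and w.is_scored:
                key = (w.plate_id, w.replicate)
                per_plate.setdefault(key, []).append(w.fluorescence)
                day_of_plate.setdefault(key, w.day)
        if not per_plate:
            continue

        def summarise(keys: list[tuple[str, int]], day_label: str) -> None:
            within = [
                _cv_percent(np.asarray(per_plate[k], dtype=float))
                for k in keys
                if len(per_plate[k]) >= 2
            ]
            plate_means = np.asarray(
                [float(np.mean(per_plate[k])) for k in keys], dtype=float
            )
            rows.append(
                {
                    "role": role.value,
                    "day": day_label,
                    "n_plates": len(keys),
                    "within_plate_cv_mean": float(np.mean(within)) if within else float("nan"),
                    "between_plate_cv": _cv_percent(plate_means)
                    if plate_means.size >= 2
                    else float("nan"),
                }
            )

        summarise(sorted(per_plate), "all")
        days = sorted({d for d in day_of_plate.values() if d is not None})
        for day in days:
            keys = [k for k in sorted(per_plate) if day_of_plate[k] == day]
            if keys:
                summarise(keys, day)
    return pd.DataFrame(
        rows,
        columns=["role", "day", "n_plates", "within_plate_cv_mean", "between_plate_cv"],
    )


def plate_pass_fail(
    qc: PlateQC, config: AnalysisConfig, degenerate_reference: bool = False
) -> tuple[bool, list[str]]:
    """Advisory per-plate pass/fail from control behaviour.

    A plate fails when no positive control shows activity (scores below the
    inhibitor threshold) or when its reference was degenerate.  Advisory only:
    no data are deleted.
    """
    reasons = []
    if degenerate_reference:
        reasons.append("degenerate reference (robust scale zero)")
    if qc.sensitivity is not None and qc.tp == 0:
        reasons.append("positive controls show no activity")
    if qc.sensitivity is None:
        reasons.append("no scored positive controls")
    return (not reasons), reasons
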