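"""Per-well SSMD* scoring and control-based effect-size statistics.

Single-well screens cannot estimate a per-compound variance, so each well is
scored against its own plate's test-well population under the assumption that
the large majority of test compounds are inert.  The per-well score (the
screen's "B value") is

    score_i = (X_i - median(reference)) / (c * 1.4826 * MAD(reference))

with c = sqrt(2) by default, accounting for the variance of the difference
between one well and the reference population.  The robust location/scale pair
(median, 1.4826*MAD) keeps genuine hits from inflating the reference.

``ssmd_controls`` implements the replicate-free SSMD between two control
groups: the median of all pairwise differences divided by their sample
standard deviation.  Conventional assay-window metrics (Z', S/N, S/B) are
provided only for side-by-side comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .plate_model import (
    AnalysisConfig,
    PlateScreenError,
    WellRecord,
    WellRole,
)

MAD_TO_SD = 1.4826  # consistency factor: 1/Phi^-1(3/4), MAD -> SD under normality


class ScoringError(PlateScreenError):
    """Raised when a plate cannot be scored (degenerate or tiny reference)."""


@dataclass(frozen=True)
class RobustReference:
    """Robust location/scale of a plate's reference wells."""

    location: float
    scale: float  # 1.4826 * MAD, fluorescence units
    n_reference: int


@dataclass
class PlateScores:
    """Per-well scores for one plate in one replicate.

    ``frame`` holds one row per well with columns well, role, compound_id,
    dose_um, status, fluorescence and ssmd_star; the score is NaN for non-ok
    wells, which are never scored.
    """

    plate_id: str
    replicate: int
    reference: RobustReference
    frame: pd.DataFrame

    def scores_for_role(self, role: WellRole) -> np.ndarray:
        sub = self.frame[(self.frame["role"] == role.value) & self.frame["ssmd_star"].notna()]
        return sub["ssmd_star"].to_numpy(dtype=float)


def _median_mad(values: np.ndarray) -> tuple[float, float]:
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, MAD_TO_SD * mad


def ssmd_star(wells: Sequence[WellRecord], config: AnalysisConfig) -> PlateScores:
    """Score every ok well of one plate-replicate against the plate reference.

    The reference population is chosen by ``config.reference_policy``; by
    default it is all ok test wells of the plate (including the scored well —
    the median is insensitive to one well).  Controls are scored against the
    same reference.
    """
    if not wells:
        raise ScoringError("no wells supplied")
    plate_ids = {w.plate_id for w in wells}
    reps = {w.replicate for w in wells}
    if len(plate_ids) != 1 or len(reps) != 1:
        raise ScoringError(
            f"ssmd_star expects a single plate-replicate, got plates {plate_ids} "
            f"replicates {reps}"
        )
    plate_id = wells[0].plate_id
    replicate = wells[0].replicate

    ok_test = [w for w in wells if w.is_scored and w.role is WellRole.TEST]
    ref_wells = list(ok_test)
    if config.reference_policy == "test_and_negative":
        ref_wells += [
            w for w in wells if w.is_scored and w.role is WellRole.NEGATIVE_CONTROL
        ]
    ref_values = np.asarray([w.fluorescence for w in ref_wells], dtype=float)
    if len(ok_test) < config.min_reference_size:
        raise ScoringError(
            f"plate {plate_id} replicate {replicate}: only {len(ok_test)} ok test "
            f"wells, below minimum reference size {config.min_reference_size}"
        )

    loo = config.reference_policy == "test_loo"
    location, scale = _median_mad(ref_values)
    if not loo and scale == 0.0:
        raise ScoringError(
            f"plate {plate_id} replicate {replicate}: degenerate reference "
            "(robust scale is zero; all reference readings identical)"
        )

    ref_ids = {id(w) for w in ref_wells}
    rows = []
    for w in sorted(wells, key=lambda w: w.address):
        score = np.nan
        if w.is_scored:
            x = float(w.fluorescence)
            if loo and id(w) in ref_ids:
                others = ref_values[[id(r) != id(w) for r in ref_wells]]
                if len(others) < config.min_reference_size - 1:
                    raise ScoringError(
                        f"plate {plate_id}: leave-one-out reference too small"
                    )
                loc_i, scale_i = _median_mad(others)
            else:
                loc_i, scale_i = location, scale
            if scale_i == 0.0:
                raise ScoringError(
                    f"plate {plate_id} replicate {replicate}: degenerate reference"
                )
            score = (x - loc_i) / (config.denominator_factor * scale_i)
        rows.append(
            {
                "plate_id": plate_id,
                "replicate": replicate,
                "well": str(w.address),
                "role": w.role.value,
                "compound_id": w.compound_id,
                "dose_um": w.dose_um,
                "status": w.status.value if w.status else None,
                "fluorescence": w.fluorescence,
                "ssmd_star": score,
            }
        )
    frame = pd.DataFrame(rows)
    return PlateScores(
        plate_id=plate_id,
        replicate=replicate,
        reference=RobustReference(location, scale, len(ref_wells)),
        frame=frame,
    )


@dataclass
class ScreenScores:
    """Scores for every plate-replicate of a screen, plus scoring failures."""

    plates: list[PlateScores]
    failures: list[tuple[str, int, str]]  # (plate_id, replicate, reason)

    def to_frame(self) -> pd.DataFrame:
        if not self.plates:
            return pd.DataFrame(
                columns=[
                    "plate_id",
                    "replicate",
                    "well",
                    "role",
                    "compound_id",
                    "dose_um",
                    "status",
                    "fluorescence",
                    "ssmd_star",
                ]
            )
        return pd.concat([p.frame for p in self.plates], ignore_index=True)


def score_screen(dataset, config: AnalysisConfig) -> ScreenScores:
    """Score every plate-replicate; failures are recorded, not raised."""
    plates: list[PlateScores] = []
    failures: list[tuple[str, int, str]] = []
    for pid, rep, wells in dataset.plate_replicates():
        try:
            plates.append(ssmd_star(wells, config))
        except ScoringError as exc:
            failures.append((pid, rep, str(exc)))
    return ScreenScores(plates, failures)


# ---------------------------------------------------------------------------
# Control-group statistics

def ssmd_controls(
    positive: Sequence[float], negative: Sequence[float]
) -> float:
    """SSMD between two unpaired control groups.

    Forms all pairwise differences positive_j - negative_k and returns their
    median divided by their sample (n-1) standard deviation.  An inhibitory
    positive control (lower signal than vehicle) yields a negative SSMD.
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ScoringError("ssmd_controls requires >= 2 readings per group")
    diffs = np.subtract.outer(pos, neg).ravel()
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        raise ScoringError("degenerate control groups: differences have zero SD")
    return float(np.median(diffs) / sd)


def percent_reduction(
    treated: Sequence[float],
    control: Sequence[float],
    use_median: bool = False,
) -> float:
    """Percent reduction of treated signal relative to control.

    Returns 100 * (1 - center(treated)/center(control)); negative values mean
    activation.  Group means are used by default (matching the usual
    mean +/- SD presentation); set ``use_median`` for a robust variant.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 1 or c.size < 1:
        raise ScoringError("percent_reduction requires >= 1 reading per group")
    center = np.median if use_median else np.mean
    c0 = float(center(c))
    if c0 <= 0:
        raise ScoringError(f"control center {c0} is not positive")
    return float(100.0 * (1.0 - float(center(t)) / c0))


@dataclass(frozen=True)
class ComparisonMetrics:
    """Conventional assay-window statistics; None marks an undefined metric."""

    z_score_separation: Optional[float]
    signal_to_noise: Optional[float]
    signal_to_background: Optional[float]
    z_prime: Optional[float]


def comparison_metrics(
    positive: Sequence[float], negative: Sequence[float]
) -> ComparisonMetrics:
    """Z-score separation, S/N, S/B and Z' between control groups.

    S/B = mean_pos/mean_neg; S/N = (mean_pos - mean_neg)/sd_neg;
    Z' = 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|.  A zero denominator
    makes that metric undefined (None) rather than raising.
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ScoringError("comparison_metrics requires >= 2 readings per group")
    mp, mn = float(np.mean(pos)), float(np.mean(neg))
    sp, sn = float(np.std(pos, ddof=1)), float(np.std(neg, ddof=1))
    sb = mp / mn if mn != 0 else None
    s2n = (mp - mn) / sn if sn != 0 else None
    zsep = (mp - mn) / np.hypot(sp, sn) if (sp or sn) else None
    zprime = 1.0 - 3.0 * (sp + sn) / abs(mp - mn) if mp != mn else None
    return ComparisonMetrics(
        z_score_separation=zsep,
        signal_to_noise=s2n,
        signal_to_background=sb,
        z_prime=zprime,
    )
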