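"""Dose-series summaries and a permutation test for dose-dependent reduction.

Per-dose n in embryo assays is small (typically 12 wells per concentration),
so inference about a dose-dependent trend is rank-based and exact-style:
the trend statistic is the Spearman rank correlation between dose and the
per-well reading (negative = fluorescence falls with dose), and its one-sided
significance level comes from a seeded permutation of readings across wells.
No sigmoid/IC50 curve is fitted; the claim being tested is monotone
dose-dependent reduction, not a potency estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .plate_model import PlateScreenError
from .scoring import percent_reduction


class DoseResponseError(PlateScreenError):
    pass


@dataclass
class DoseSeries:
    """Readings grouped by dose; dose 0 is the vehicle group."""

    compound_id: str
    groups: dict[float, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[float, np.ndarray] = {}
        for dose, values in sorted(self.groups.items()):
            if dose < 0:
                raise DoseResponseError(f"negative dose {dose}")
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                raise DoseResponseError(f"empty group at dose {dose}")
            clean[float(dose)] = arr
        if 0.0 not in clean:
            raise DoseResponseError("dose series requires a vehicle (dose 0) group")
        self.groups = clean

    @property
    def doses(self) -> list[float]:
        return sorted(self.groups)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, compound_id: str = "") -> "DoseSeries":
        if not {"dose_um", "fluorescence"} <= set(df.columns):
            raise DoseResponseError(
                "dose series needs columns dose_um and fluorescence"
            )
        groups = {
            float(dose): sub["fluorescence"].to_numpy(dtype=float)
            for dose, sub in df.groupby("dose_um")
        }
        if not compound_id and "compound_id" in df.columns and len(df):
            compound_id = str(df["compound_id"].iloc[0])
        return cls(compound_id=compound_id, groups=groups)


@dataclass
class TrendResult:
    statistic: Optional[float]  # Spearman rho, negative = reduction with dose
    p_permutation: Optional[float]  # one-sided, lower tail
    n_permutations: int
    seed: int


@dataclass
class DoseReport:
    compound_id: str
    per_dose: pd.DataFrame  # dose_um, n, mean, sd, pct_reduction
    trend: TrendResult


def _permutation_trend(
    doses: np.ndarray, readings: np.ndarray, n_permutations: int, seed: int
) -> TrendResult:
    rho = stats.spearmanr(doses, readings).statistic
    if not np.isfinite(rho):
        return TrendResult(None, None, n_permutations, seed)
    # Spearman rho is a Pearson correlation of ranks; with the dose ranks fixed
    # the permutation distribution only needs the reading ranks reshuffled.
    rng = np.random.default_rng(seed)
    dr = stats.rankdata(doses).astype(float)
    rr = stats.rankdata(readings).astype(float)
    dr -= dr.mean()
    denom_d = np.sqrt(np.sum(dr**2))
    perm = np.empty(n_permutations)
    for b in range(n_permutations):
        shuffled = rng.permutation(rr)
        shuffled = shuffled - shuffled.mean()
        perm[b] = float(dr @ shuffled) / (denom_d * np.sqrt(np.sum(shuffled**2)))
    p = (1.0 + float(np.sum(perm <= rho))) / (n_permutations + 1.0)
    return TrendResult(float(rho), p, n_permutations, seed)


def dose_summary(
    series: DoseSeries, n_permutations: int = 1000, seed: int = 0
) -> DoseReport:
    """Per-dose summary plus a seeded permutation test for a negative trend.

    Percent reduction at each dose is measured against the vehicle group.
    The trend statistic pools all wells (vehicle included); with fewer than
    two distinct non-vehicle doses the trend is undefined but the per-dose
    summary is still returned.
    """
    vehicle = series.groups[0.0]
    if float(np.mean(vehicle)) <= 0:
        raise DoseResponseError("vehicle group mean must be positive")
    rows = []
    for dose in series.doses:
        values = series.groups[dose]
        rows.append(
            {
                "dose_um": dose,
                "n": int(values.size),
                "mean": float(np.mean(values)),
                "sd": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
                "pct_reduction": percent_reduction(values, vehicle),
            }
        )
    per_dose = pd.DataFrame(rows)

    nonzero = [d for d in series.doses if d > 0]
    if len(nonzero) < 2:
        trend = TrendResult(None, None, n_permutations, seed)
    else:
        doses = np.concatenate(
            [np.full(series.groups[d].size, d) for d in series.doses]
        )
        readings = np.concatenate([series.groups[d] for d in series.doses])
        trend = _permutation_trend(doses, readings, n_permutations, seed)
    return DoseReport(compound_id=series.compound_id, per_dose=per_dose, trend=trend)
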