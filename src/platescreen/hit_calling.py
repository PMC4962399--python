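"""Well classification, two-replicate concordance and the screen hit summary.

A compound is a hit only if it shows the same effect class in both screen
replicates.  Strong inhibition (score < -1.0) implies inhibition at the -0.5
level, so a (strong_inhibitor, inhibitor) pair is concordant at -0.5 and the
final call is inhibitor; it is discordant at the -1.0 level.  A compound toxic
in either replicate is called toxic and flagged for rescreen at lower doses.
Activator calls carry an autofluorescence caveat: compounds that fluoresce on
their own, or that are toxic, can raise the reporter signal spuriously.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .plate_model import (
    AnalysisConfig,
    PlateScreenError,
    ScreenDataset,
    WellAddress,
    WellRecord,
    WellRole,
    WellStatus,
    standard_layout,
)
from .scoring import ScreenScores


class HitCallingError(PlateScreenError):
    pass


class WellClass(str, enum.Enum):
    STRONG_INHIBITOR = "strong_inhibitor"
    INHIBITOR = "inhibitor"
    ACTIVATOR = "activator"
    INACTIVE = "inactive"
    TOXIC = "toxic"
    EXCLUDED = "excluded"


class FinalCall(str, enum.Enum):
    STRONG_INHIBITOR = "strong_inhibitor"
    INHIBITOR = "inhibitor"
    ACTIVATOR = "activator"
    INACTIVE = "inactive"
    TOXIC = "toxic"
    EXCLUDED = "excluded"
    NOT_REPLICATED = "not_replicated"


@dataclass
class HitCall:
    compound_id: str
    class_by_replicate: dict[int, Optional[WellClass]]
    final_call: FinalCall
    rescreen_recommended: bool = False
    autofluorescence_suspect: bool = False
    missing_in: list[int] = field(default_factory=list)


def classify_well(
    score: Optional[float], status: WellStatus, config: AnalysisConfig
) -> WellClass:
    """Classify one well from its status and (for ok wells) its score.

    Status is consulted first: a dead well is toxic and a defective/excluded
    well is excluded regardless of any score.  Threshold comparisons are
    strict, so a score exactly at -0.5 is inactive.
    """
    if status is WellStatus.DEAD:
        return WellClass.TOXIC
    if status in (WellStatus.DEFECTIVE, WellStatus.EXCLUDED):
        return WellClass.EXCLUDED
    if score is None or pd.isna(score):
        raise HitCallingError("ok well without a score cannot be classified")
    if score < config.strong_inhibitor_threshold:
        return WellClass.STRONG_INHIBITOR
    if score < config.inhibitor_threshold:
        return WellClass.INHIBITOR
    if score > config.activator_threshold:
        return WellClass.ACTIVATOR
    return WellClass.INACTIVE


def replicate_calls(
    scores: ScreenScores, config: AnalysisConfig
) -> dict[int, dict[str, WellClass]]:
    """Per-replicate classification of every test compound on scored plates."""
    calls: dict[int, dict[str, WellClass]] = {}
    for plate in scores.plates:
        sub = plate.frame[plate.frame["role"] == WellRole.TEST.value]
        for row in sub.itertuples(index=False):
            if not row.compound_id:
                continue
            status = WellStatus(row.status)
            cls = classify_well(row.ssmd_star, status, config)
            rep_calls = calls.setdefault(plate.replicate, {})
            if row.compound_id in rep_calls:
                raise HitCallingError(
                    f"compound {row.compound_id} appears more than once in "
                    f"replicate {plate.replicate}"
                )
            rep_calls[row.compound_id] = cls
    return calls


_HIT_CLASSES = {WellClass.STRONG_INHIBITOR, WellClass.INHIBITOR, WellClass.ACTIVATOR}
_INHIBITORY = {WellClass.STRONG_INHIBITOR, WellClass.INHIBITOR}


def _concordant_final(a: WellClass, b: WellClass) -> FinalCall:
    if a == b:
        return FinalCall(a.value)
    if a in _INHIBITORY and b in _INHIBITORY:
        # concordant at the -0.5 level, discordant at -1.0
        return FinalCall.INHIBITOR
    return FinalCall.NOT_REPLICATED


def concordant_hits(
    calls1: Mapping[str, WellClass], calls2: Mapping[str, WellClass]
) -> list[HitCall]:
    """Combine two replicates' per-compound classes into final calls.

    Toxicity in either replicate dominates (final toxic, rescreen flagged).
    Exclusion in either replicate leaves the compound unconfirmable:
    excluded if both replicates were excluded, otherwise not_replicated.
    A compound seen in only one replicate is flagged, never dropped.
    Symmetric in replicate order.
    """
    result: list[HitCall] = []
    for compound in sorted(set(calls1) | set(calls2)):
        a = calls1.get(compound)
        b = calls2.get(compound)
        missing = [rep for rep, c in ((1, a), (2, b)) if c is None]
        if missing:
            final = FinalCall.NOT_REPLICATED
        elif WellClass.TOXIC in (a, b):
            final = FinalCall.TOXIC
        elif WellClass.EXCLUDED in (a, b):
            final = (
                FinalCall.EXCLUDED
                if a is WellClass.EXCLUDED and b is WellClass.EXCLUDED
                else FinalCall.NOT_REPLICATED
            )
        else:
            final = _concordant_final(a, b)
        result.append(
            HitCall(
                compound_id=compound,
                class_by_replicate={1: a, 2: b},
                final_call=final,
                rescreen_recommended=final is FinalCall.TOXIC,
                autofluorescence_suspect=final is FinalCall.ACTIVATOR,
                missing_in=missing,
            )
        )
    return result


def screen_hit_calls(
    scores: ScreenScores, config: AnalysisConfig
) -> list[HitCall]:
    """Full classification pipeline for a two-replicate screen's scores."""
    per_rep = replicate_calls(scores, config)
    reps = sorted(per_rep)
    if len(reps) != 2:
        raise HitCallingError(
            f"concordance requires exactly 2 replicates, found {reps}"
        )
    return concordant_hits(per_rep[reps[0]], per_rep[reps[1]])


def hit_summary(calls: Sequence[HitCall], n_screened: int) -> pd.DataFrame:
    """Screen-level hit statistics by threshold class.

    Rows count replicated calls below -0.5 (inhibitor or strong inhibitor),
    below -1.0 (strong inhibitor only), above +1.0 (activator) and toxic
    compounds, each as a count and a percentage of compounds screened.
    """
    if n_screened < 1:
        raise HitCallingError("n_screened must be >= 1")
    finals = [c.final_call for c in calls]
    n_below_05 = sum(f in (FinalCall.INHIBITOR, FinalCall.STRONG_INHIBITOR) for f in finals)
    n_below_10 = sum(f is FinalCall.STRONG_INHIBITOR for f in finals)
    n_above_10 = sum(f is FinalCall.ACTIVATOR for f in finals)
    n_toxic = sum(f is FinalCall.TOXIC for f in finals)
    rows = [
        ("below_-0.5", n_below_05),
        ("below_-1.0", n_below_10),
        ("above_+1.0", n_above_10),
        ("caused_death", n_toxic),
    ]
    return pd.DataFrame(
        [
            {
                "threshold_class": name,
                "n_hits": n,
                "n_screened": n_screened,
                "percent": 100.0 * n / n_screened,
            }
            for name, n in rows
        ]
    )


def hit_table(calls: Sequence[HitCall], scores: Optional[ScreenScores] = None) -> pd.DataFrame:
    """Per-compound hit table, one row per compound with both replicate calls."""
    score_by: dict[tuple[str, int], float] = {}
    if scores is not None:
        df = scores.to_frame()
        sub = df[(df["role"] == WellRole.TEST.value) & df["compound_id"].notna()]
        reps = sorted(sub["replicate"].unique())
        rep_index = {rep: i + 1 for i, rep in enumerate(reps)}
        for row in sub.itertuples(index=False):
            score_by[(row.compound_id, rep_index[row.replicate])] = row.ssmd_star
    rows = []
    for c in calls:
        rows.append(
            {
                "compound_id": c.compound_id,
                "score_rep1": score_by.get((c.compound_id, 1)),
                "score_rep2": score_by.get((c.compound_id, 2)),
                "class_rep1": c.class_by_replicate.get(1).value
                if c.class_by_replicate.get(1)
                else "missing",
                "class_rep2": c.class_by_replicate.get(2).value
                if c.class_by_replicate.get(2)
                else "missing",
                "final_call": c.final_call.value,
                "rescreen_recommended": c.rescreen_recommended,
                "autofluorescence_suspect": c.autofluorescence_suspect,
            }
        )
    return pd.DataFrame(rows)


def toxic_rescreen_list(
    calls: Sequence[HitCall],
    doses_um: Sequence[float] = (1.0, 0.1),
    wells_per_plate: int = 48,
) -> pd.DataFrame:
    """Plate-map manifest rescreening every toxic compound at lower doses.

    One row per toxic compound per dose, laid out on fresh plates using the
    standard test-well positions so the manifest round-trips through
    ``read_plate_map``.
    """
    toxic = sorted(c.compound_id for c in calls if c.final_call is FinalCall.TOXIC)
    layout = [addr for addr, role in standard_layout(0, 0, wells_per_plate)
              if role is WellRole.TEST]
    rows = []
    i = 0
    for compound in toxic:
        for dose in doses_um:
            plate = i // wells_per_plate + 1
            addr = layout[i % wells_per_plate]
            rows.append(
                {
                    "plate_id": f"RESCREEN-{plate}",
                    "well": str(addr),
                    "role": WellRole.TEST.value,
                    "compound_id": compound,
                    "dose_um": dose,
                }
            )
            i += 1
    return pd.DataFrame(
        rows, columns=["plate_id", "well", "role", "compound_id", "dose_um"]
    )
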