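"""Synthetic plate screens and dose series with planted ground truth.

Two generators cover two distinct needs:

* ``simulate_screen`` is the *stochastic* generator: one embryo per well,
  log-normal fluorescence noise (default CV 15 %), multiplicative compound
  effects, plate and day batch effects, toxicity (dead wells) and a small
  background exclusion rate.  It emulates the statistical structure the assay
  assumes and is the workhorse for QC and recovery properties.

* ``simulate_planted_screen`` is the *deterministic verification* generator:
  it plants compounds directly in score space, so every planted inhibitor,
  strong inhibitor and activator lands in its intended score band in every
  replicate by construction.  A single well scored against its own plate's
  population always carries a null score spread of about 1/sqrt(2), so a
  purely stochastic screen can never pin exact hit counts; this generator
  exists so the decision logic (thresholds, concordance, summary arithmetic)
  can be checked against exact planted counts end to end.

Planted truth is retained alongside every generated dataset so pipeline
calls can be scored against it (``recovery_report``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hit_calling import FinalCall, HitCall, WellClass
from .plate_model import (
    ConfigError,
    ScreenDataset,
    WellRecord,
    WellRole,
    WellStatus,
    standard_layout,
)
from .scoring import MAD_TO_SD

_SQRT2 = math.sqrt(2.0)

POSITIVE_CONTROL_ID = "riluzole"
NEGATIVE_CONTROL_ID = "DMSO"


def cv_to_log_sd(cv: float) -> float:
    """Log-scale SD of a log-normal with the given coefficient of variation."""
    if cv < 0:
        raise ConfigError("CV must be nonnegative")
    return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class CompoundTruth:
    well_class: WellClass
    effect_factor: float = 1.0  # multiplicative fluorescence factor (stochastic mode)
    target_score: Optional[float] = None  # intended score band centre (planted mode)


@dataclass
class PlantedTruth:
    """Ground-truth class and effect per compound, kept for recovery scoring."""

    compounds: dict[str, CompoundTruth]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "compound_id": cid,
                    "class": t.well_class.value,
                    "effect_factor": t.effect_factor,
                    "target_score": t.target_score,
                }
                for cid, t in sorted(self.compounds.items())
            ]
        )


@dataclass
class SimulationConfig:
    """Parameters of the stochastic screen generator.

    Defaults mirror the screen design: 96-well plates carrying 12 positive
    controls (a riluzole-like inhibitor halving the signal), 12 vehicle
    controls and 48 single-embryo test wells, read in two independent
    replicates.  Baseline fluorescence is log-normal with CV 15 % around
    1000 arbitrary units; plate and day effects are shared multiplicative
    log-normal batch shifts.  ``inert_effect_log_sd`` adds compound-level
    heterogeneity shared across replicates (0 = all inert compounds behave
    identically).
    """

    plates: int = 4
    test_wells_per_plate: int = 48
    positive_controls_per_plate: int = 12
    negative_controls_per_plate: int = 12
    replicates: int = 2
    baseline_log_mean: float = math.log(1000.0)
    baseline_cv: float = 0.15
    positive_control_effect: float = 0.5
    inert_effect_log_sd: float = 0.0
    toxic_death_probability: float = 1.0
    background_exclusion_rate: float = 0.02
    plate_effect_log_sd: float = 0.05
    day_effect_log_sd: float = 0.05
    plates_per_day: int = 10
    test_dose_um: float = 10.0
    positive_control_dose_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        occupied = (
            self.test_wells_per_plate
            + self.positive_controls_per_plate
            + self.negative_controls_per_plate
        )
        if occupied > 96:
            raise ConfigError(f"{occupied} occupied wells exceed 96-well capacity")
        if self.plates < 1 or self.replicates < 1:
            raise ConfigError("plates and replicates must be >= 1")
        if not 0 < self.positive_control_effect:
            raise ConfigError("positive_control_effect must be > 0")
        if not 0 <= self.background_exclusion_rate < 1:
            raise ConfigError("background_exclusion_rate must be in [0, 1)")
        if not 0 <= self.toxic_death_probability <= 1:
            raise ConfigError("toxic_death_probability must be in [0, 1]")

    @property
    def baseline_log_sd(self) -> float:
        return cv_to_log_sd(self.baseline_cv)


def make_planted_truth(
    n_compounds: int,
    n_inhibitors: int = 0,
    n_strong_inhibitors: int = 0,
    n_activators: int = 0,
    n_toxic: int = 0,
    inhibitor_factor: float = 0.85,
    strong_inhibitor_factor: float = 0.55,
    activator_factor: float = 1.35,
    rng: Optional[np.random.Generator] = None,
) -> PlantedTruth:
    """Assign hit classes to randomly chosen compounds.

    ``n_strong_inhibitors`` is the subset of ``n_inhibitors`` planted with the
    stronger effect, mirroring the nesting of the -1.0 threshold inside -0.5.
    """
    if n_strong_inhibitors > n_inhibitors:
        raise ConfigError("n_strong_inhibitors cannot exceed n_inhibitors")
    n_planted = n_inhibitors + n_activators + n_toxic
    if n_planted > n_compounds:
        raise ConfigError("more planted compounds than compounds in the screen")
    rng = rng or np.random.default_rng(0)
    ids = [f"C{i + 1:05d}" for i in range(n_compounds)]
    order = rng.permutation(n_compounds)
    truth: dict[str, CompoundTruth] = {cid: CompoundTruth(WellClass.INACTIVE) for cid in ids}
    k = 0
    for _ in range(n_strong_inhibitors):
        truth[ids[order[k]]] = CompoundTruth(
            WellClass.STRONG_INHIBITOR, strong_inhibitor_factor
        )
        k += 1
    for _ in range(n_inhibitors - n_strong_inhibitors):
        truth[ids[order[k]]] = CompoundTruth(WellClass.INHIBITOR, inhibitor_factor)
        k += 1
    for _ in range(n_activators):
        truth[ids[order[k]]] = CompoundTruth(WellClass.ACTIVATOR, activator_factor)
        k += 1
    for _ in range(n_toxic):
        truth[ids[order[k]]] = CompoundTruth(WellClass.TOXIC, 1.0)
        k += 1
    return PlantedTruth(truth)


def _plate_map_records(
    compound_ids: Sequence[str],
    config: SimulationConfig,
) -> list[WellRecord]:
    """Lay compounds out on consecutive plates using the standard layout."""
    records: list[WellRecord] = []
    layout = standard_layout(
        config.positive_controls_per_plate,
        config.negative_controls_per_plate,
        config.test_wells_per_plate,
    )
    test_slots = [addr for addr, role in layout if role is WellRole.TEST]
    control_slots = [
        (addr, role) for addr, role in layout if role not in (WellRole.TEST, WellRole.EMPTY)
    ]
    n = len(compound_ids)
    n_plates = max(1, math.ceil(n / config.test_wells_per_plate))
    base, extra = divmod(n, n_plates)  # spread compounds evenly over plates
    i = 0
    for p in range(n_plates):
        pid = f"P{p + 1:03d}"
        for addr, role in control_slots:
            if role is WellRole.POSITIVE_CONTROL:
                records.append(
                    WellRecord(pid, addr, role, POSITIVE_CONTROL_ID,
                               config.positive_control_dose_um)
                )
            else:
                records.append(WellRecord(pid, addr, role, NEGATIVE_CONTROL_ID, 0.0))
        n_here = base + (1 if p < extra else 0)
        for addr in test_slots[:n_here]:
            records.append(
                WellRecord(pid, addr, WellRole.TEST, compound_ids[i], config.test_dose_um)
            )
            i += 1
    return records


def _day_label(plate_index: int, plates_per_day: int) -> str:
    return f"D{plate_index // max(1, plates_per_day) + 1}"


def simulate_screen(
    config: SimulationConfig, truth: Optional[PlantedTruth] = None
) -> tuple[ScreenDataset, PlantedTruth]:
    """Stochastic screen: log-normal wells, batch effects, toxicity, exclusions.

    Per ok well the reading is ``exp(N(log_mean, log_sd)) * effect * plate_eff
    * day_eff``.  Compound effects (and any heterogeneity draw) are shared
    across replicates; well noise, batch effects, deaths and background
    exclusions are independent per replicate.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    if truth is None:
        n = config.plates * config.test_wells_per_plate
        truth = make_planted_truth(n)
    ids = sorted(truth.compounds)
    rng.shuffle(ids)
    map_records = _plate_map_records(ids, config)
    plate_ids = sorted({w.plate_id for w in map_records})

    # compound-level multiplicative heterogeneity, shared across replicates
    hetero = {
        cid: math.exp(rng.normal(0.0, config.inert_effect_log_sd))
        if config.inert_effect_log_sd > 0
        else 1.0
        for cid in ids
    }

    wells: list[WellRecord] = []
    for rep in range(1, config.replicates + 1):
        day_eff = {}
        for i, pid in enumerate(plate_ids):
            day = _day_label(i, config.plates_per_day)
            if day not in day_eff:
                day_eff[day] = math.exp(rng.normal(0.0, config.day_effect_log_sd))
        for i, pid in enumerate(plate_ids):
            day = _day_label(i, config.plates_per_day)
            plate_eff = math.exp(rng.normal(0.0, config.plate_effect_log_sd))
            batch = plate_eff * day_eff[day]
            for base in map_records:
                if base.plate_id != pid:
                    continue
                if base.role is WellRole.TEST:
                    t = truth.compounds[base.compound_id]
                    factor = t.effect_factor * hetero[base.compound_id]
                    is_toxic = t.well_class is WellClass.TOXIC
                elif base.role is WellRole.POSITIVE_CONTROL:
                    factor = config.positive_control_effect
                    is_toxic = False
                else:
                    factor = 1.0
                    is_toxic = False
                status = WellStatus.OK
                if is_toxic and rng.random() < config.toxic_death_probability:
                    status = WellStatus.DEAD
                elif rng.random() < config.background_exclusion_rate:
                    status = WellStatus.DEAD if rng.random() < 0.5 else WellStatus.DEFECTIVE
                fluor = None
                if status is WellStatus.OK:
                    fluor = float(
                        math.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd))
                        * factor
                        * batch
                    )
                wells.append(
                    WellRecord(
                        base.plate_id,
                        base.address,
                        base.role,
                        base.compound_id,
                        base.dose_um,
                        status=status,
                        fluorescence=fluor,
                        replicate=rep,
                        day=day,
                    )
                )
    return ScreenDataset(wells), truth


# ---------------------------------------------------------------------------
# Deterministic score-space planting

def _planted_plate_scores(
    n_inert: int,
    planted_targets: dict[int, float],
    rng: np.random.Generator,
    denominator: float = _SQRT2 * MAD_TO_SD,
) -> tuple[np.ndarray, float, float]:
    """Construct raw deviations for one plate's scored test wells.

    ``planted_targets`` maps positions (0..n-1) of planted wells to their
    target scores; the remaining positions are inert.  Inert wells form a
    sign-count-balanced comb — a tight cluster just below the median and a
    spread cluster on the (wide) activator side — whose realised scores stay
    strictly inside the inactive band (-0.5, +1.0).  Planted wells are then
    placed by a fixed-point iteration so their realised score against the
    plate's own median/MAD equals the target.  Returns the raw deviation
    vector plus the final median and robust scale (for placing control wells).
    """
    n_total = n_inert + len(planted_targets)
    n_neg_planted = sum(1 for t in planted_targets.values() if t < 0)
    n_pos_planted = len(planted_targets) - n_neg_planted
    z = n_total % 2
    half = (n_total - z) // 2
    n_neg_inert = half - n_neg_planted
    n_pos_inert = half - n_pos_planted
    if n_neg_inert < 1 or n_pos_inert < 1:
        raise ConfigError(
            "too many planted compounds on one plate for balanced construction"
        )
    neg = np.linspace(-1.00, -0.96, n_neg_inert) + rng.uniform(-0.002, 0.002, n_neg_inert)
    pos = np.linspace(0.99, 1.90, n_pos_inert) + rng.uniform(-0.002, 0.002, n_pos_inert)
    centre = rng.uniform(-0.01, 0.01, z)
    inert = np.concatenate([neg, centre, pos])
    rng.shuffle(inert)

    raw = np.empty(n_total)
    inert_positions = [i for i in range(n_total) if i not in planted_targets]
    raw[inert_positions] = inert
    planted_idx = np.array(sorted(planted_targets), dtype=int)
    targets = np.array([planted_targets[i] for i in planted_idx])
    raw[planted_idx] = targets  # rough start for the fixed point
    med, scale = 0.0, 1.0
    for _ in range(20):
        med = float(np.median(raw))
        scale = MAD_TO_SD * float(np.median(np.abs(raw - med)))
        new = med + targets * denominator * scale / MAD_TO_SD
        if np.allclose(new, raw[planted_idx], rtol=0, atol=1e-13):
            break
        raw[planted_idx] = new
    med = float(np.median(raw))
    scale = MAD_TO_SD * float(np.median(np.abs(raw - med)))
    return raw, med, scale


def simulate_planted_screen(
    n_compounds: int = 2000,
    n_inhibitors: int = 38,
    n_strong_inhibitors: int = 7,
    n_activators: int = 20,
    n_toxic: int = 142,
    replicates: int = 2,
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
) -> tuple[ScreenDataset, PlantedTruth]:
    """Deterministic planted-truth screen for end-to-end pipeline verification.

    Every planted inhibitor scores in (-1.0, -0.5), every planted strong
    inhibitor below -1.0 and every planted activator above +1.0 in *both*
    replicates by construction; every inert compound stays strictly inside
    the inactive band; toxic compounds emit dead wells.  Positive controls are
    placed well below -0.5 on every plate (the always-active reference
    inhibitor) and negative controls inside the inactive band.
    """
    if config is None:
        config = SimulationConfig(plates=1, seed=seed)
    rng = np.random.default_rng(seed)
    truth = make_planted_truth(
        n_compounds,
        n_inhibitors=n_inhibitors,
        n_strong_inhibitors=n_strong_inhibitors,
        n_activators=n_activators,
        n_toxic=n_toxic,
        rng=rng,
    )
    target_bands = {
        WellClass.INHIBITOR: (-0.72, 0.03),
        WellClass.STRONG_INHIBITOR: (-1.55, 0.10),
        WellClass.ACTIVATOR: (1.40, 0.10),
    }
    compounds = dict(truth.compounds)
    for cid, t in compounds.items():
        if t.well_class in target_bands:
            centre, _ = target_bands[t.well_class]
            compounds[cid] = CompoundTruth(t.well_class, t.effect_factor, centre)
    truth = PlantedTruth(compounds)

    ids = sorted(truth.compounds)
    rng.shuffle(ids)
    map_records = _plate_map_records(ids, config)
    plate_ids = sorted({w.plate_id for w in map_records})
    reading_unit = math.exp(config.baseline_log_mean)
    denominator = _SQRT2 * MAD_TO_SD

    wells: list[WellRecord] = []
    for rep in range(1, replicates + 1):
        for i, pid in enumerate(plate_ids):
            day = _day_label(i, config.plates_per_day)
            plate_level = reading_unit * math.exp(
                rng.normal(0.0, config.plate_effect_log_sd)
            )
            plate_wells = [w for w in map_records if w.plate_id == pid]
            test_wells = [w for w in plate_wells if w.role is WellRole.TEST]
            scored, toxic = [], []
            for w in test_wells:
                t = truth.compounds[w.compound_id]
                (toxic if t.well_class is WellClass.TOXIC else scored).append(w)
            planted_targets: dict[int, float] = {}
            for j, w in enumerate(scored):
                t = truth.compounds[w.compound_id]
                if t.well_class in target_bands:
                    centre, jitter = target_bands[t.well_class]
                    planted_targets[j] = centre + rng.uniform(-jitter, jitter)
            raw, med, scale = _planted_plate_scores(
                len(scored) - len(planted_targets), planted_targets, rng
            )
            readings = plate_level * (1.0 + 0.08 * raw)

            def emit(base: WellRecord, status: WellStatus, fluor: Optional[float]) -> None:
                wells.append(
                    WellRecord(
                        base.plate_id, base.address, base.role, base.compound_id,
                        base.dose_um, status=status, fluorescence=fluor,
                        replicate=rep, day=day,
                    )
                )

            for j, w in enumerate(scored):
                emit(w, WellStatus.OK, float(readings[j]))
            for w in toxic:
                emit(w, WellStatus.DEAD, None)
            for w in plate_wells:
                if w.role is WellRole.POSITIVE_CONTROL:
                    target = -2.2 + rng.uniform(-0.2, 0.2)
                elif w.role is WellRole.NEGATIVE_CONTROL:
                    target = rng.uniform(-0.35, 0.35)
                else:
                    continue
                raw_ctrl = med + target * denominator * scale / MAD_TO_SD
                emit(w, WellStatus.OK, float(plate_level * (1.0 + 0.08 * raw_ctrl)))
    return ScreenDataset(wells), truth


# ---------------------------------------------------------------------------
# Dose series and control groups

def simulate_control_groups(
    n: int = 19,
    effect: float = 0.5,
    cv: float = 0.15,
    baseline: float = 1000.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Treated and vehicle readings for a positive-control comparison.

    Treated wells carry the multiplicative ``effect`` (0.5 = 50 % reduction)
    on the same log-normal baseline as the vehicle wells.
    """
    rng = np.random.default_rng(seed)
    sd = cv_to_log_sd(cv)
    mu = math.log(baseline)
    vehicle = np.exp(rng.normal(mu, sd, n))
    treated = effect * np.exp(rng.normal(mu, sd, n))
    return treated, vehicle


def simulate_dose_response(
    top_effect: float = 0.5,
    doses_um: Sequence[float] = (0.0, 1.0, 3.0, 10.0, 30.0),
    n_per_dose: int = 12,
    cv: float = 0.15,
    baseline: float = 1000.0,
    compound_id: str = POSITIVE_CONTROL_ID,
    seed: int = 0,
):
    """Seeded dose series with a monotone planted effect.

    The planted factor interpolates log-linearly in dose between 1.0 (vehicle)
    and ``top_effect`` at the highest dose: factor(d) = 1 - (1 - top_effect) *
    log1p(d)/log1p(d_max).  ``top_effect`` 1.0 gives a flat (null) series.
    """
    from .dose_response import DoseSeries  # local import avoids a cycle

    doses = sorted(float(d) for d in doses_um)
    if doses[0] != 0.0:
        doses = [0.0] + doses
    d_max = doses[-1]
    if d_max <= 0:
        raise ConfigError("dose grid needs a positive top dose")
    rng = np.random.default_rng(seed)
    sd = cv_to_log_sd(cv)
    mu = math.log(baseline)
    groups = {}
    for d in doses:
        factor = 1.0 - (1.0 - top_effect) * math.log1p(d) / math.log1p(d_max)
        groups[d] = factor * np.exp(rng.normal(mu, sd, n_per_dose))
    return DoseSeries(compound_id=compound_id, groups=groups)


# ---------------------------------------------------------------------------
# Recovery against planted truth

@dataclass
class RecoveryReport:
    confusion: pd.DataFrame  # truth class (rows) x final call (columns)
    per_class: pd.DataFrame  # class, n_truth, n_called, recall, precision


def recovery_report(calls: Sequence[HitCall], truth: PlantedTruth) -> RecoveryReport:
    """Confusion matrix and per-class precision/recall of pipeline calls."""
    called = {c.compound_id for c in calls}
    if called != set(truth.compounds):
        missing = set(truth.compounds) - called
        extra = called - set(truth.compounds)
        raise ConfigError(
            f"compound set mismatch: {len(missing)} missing from calls, "
            f"{len(extra)} unknown to truth"
        )
    truth_classes = [c.value for c in WellClass]
    final_classes = [c.value for c in FinalCall]
    counts = pd.DataFrame(0, index=truth_classes, columns=final_classes, dtype=int)
    for c in calls:
        counts.loc[truth.compounds[c.compound_id].well_class.value, c.final_call.value] += 1
    rows = []
    for cls in truth_classes:
        n_truth = int(counts.loc[cls].sum())
        n_called = int(counts[cls].sum()) if cls in counts.columns else 0
        correct = int(counts.loc[cls, cls]) if cls in counts.columns else 0
        rows.append(
            {
                "class": cls,
                "n_truth": n_truth,
                "n_called": n_called,
                "recall": correct / n_truth if n_truth else float("nan"),
                "precision": correct / n_called if n_called else float("nan"),
            }
        )
    return RecoveryReport(confusion=counts, per_class=pd.DataFrame(rows))
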