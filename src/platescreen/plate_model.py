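"""Data model and delimited-text I/O for single-well plate screens.

A screen is a collection of 96-well plates.  Each plate carries positive-control
wells (a reference inhibitor such as riluzole), negative-control wells (vehicle,
e.g. DMSO) and test-compound wells, one embryo/sample per well.  Wells whose
sample died or was otherwise unusable are flagged and never contribute a
fluorescence reading to any downstream statistic.

Two tidy CSV files describe a screen:

* a *plate map* — ``plate_id, well, role, compound_id, dose_um`` — the static
  layout shared by all replicates, and
* a *readings* file — ``plate_id, well, replicate, status, fluorescence`` —
  one row per well per replicate.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

ROWS = "ABCDEFGH"
N_COLUMNS = 12

_ADDRESS_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")


class PlateScreenError(Exception):
    """Base class for all errors raised by this package."""


class PlateMapError(PlateScreenError):
    """Malformed or inconsistent plate-map input."""


class ReadingsError(PlateScreenError):
    """Malformed or inconsistent readings input."""


class ConfigError(PlateScreenError):
    """Invalid analysis or simulation configuration."""


@dataclass(frozen=True, order=True)
class WellAddress:
    """Canonical 96-well address, row letter A–H plus 1-based column 1–12."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise PlateMapError(f"well row {self.row!r} outside A-{ROWS[-1]}")
        if not 1 <= self.column <= N_COLUMNS:
            raise PlateMapError(f"well column {self.column} outside 1-{N_COLUMNS}")

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        m = _ADDRESS_RE.match(text.strip())
        if not m:
            raise PlateMapError(f"cannot parse well address {text!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


class WellRole(str, enum.Enum):
    POSITIVE_CONTROL = "positive_control"
    NEGATIVE_CONTROL = "negative_control"
    TEST = "test"
    EMPTY = "empty"


class WellStatus(str, enum.Enum):
    OK = "ok"
    DEAD = "dead"
    DEFECTIVE = "defective"
    EXCLUDED = "excluded"


@dataclass
class WellRecord:
    """One well of one plate in one replicate.

    ``fluorescence`` is present iff ``status`` is ``ok``; non-ok wells never
    carry a reading into any downstream computation.
    """

    plate_id: str
    address: WellAddress
    role: WellRole
    compound_id: Optional[str]
    dose_um: float
    status: Optional[WellStatus] = None
    fluorescence: Optional[float] = None
    replicate: Optional[int] = None
    day: Optional[str] = None

    @property
    def is_scored(self) -> bool:
        return self.status is WellStatus.OK


@dataclass
class ScreenDataset:
    """All well records of a screen (possibly several replicates)."""

    wells: list[WellRecord] = field(default_factory=list)

    @property
    def plate_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            seen.setdefault(w.plate_id)
        return list(seen)

    @property
    def replicates(self) -> list[int]:
        return sorted({w.replicate for w in self.wells if w.replicate is not None})

    @property
    def compounds(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            if w.role is WellRole.TEST and w.compound_id:
                seen.setdefault(w.compound_id)
        return list(seen)

    def plate_replicates(self) -> Iterator[tuple[str, int, list[WellRecord]]]:
        """Yield (plate_id, replicate, wells) groups in stable order."""
        groups: dict[tuple[str, int], list[WellRecord]] = {}
        for w in self.wells:
            if w.replicate is None:
                continue
            groups.setdefault((w.plate_id, w.replicate), []).append(w)
        for (pid, rep) in sorted(groups):
            yield pid, rep, groups[(pid, rep)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            rows.append(
                {
                    "plate_id": w.plate_id,
                    "well": str(w.address),
                    "role": w.role.value,
                    "compound_id": w.compound_id,
                    "dose_um": w.dose_um,
                    "status": None if w.status is None else w.status.value,
                    "fluorescence": w.fluorescence,
                    "replicate": w.replicate,
                    "day": w.day,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "plate_id",
                "well",
                "role",
                "compound_id",
                "dose_um",
                "status",
                "fluorescence",
                "replicate",
                "day",
            ],
        )


@dataclass
class AnalysisConfig:
    """Thresholds and reference policy for scoring and hit calling.

    The hit cut-offs follow the screen's operating values: per-well scores
    below −0.5 call inhibitors, below −1.0 strong inhibitors, above +1.0
    activators.  ``reference_policy`` selects which wells define the plate's
    robust reference population:

    * ``"test"`` (default) — all ok test wells of the plate, including the
      scored well itself (the median is insensitive to a single well);
    * ``"test_loo"`` — leave-one-out: each test well is scored against the
      other test wells;
    * ``"test_and_negative"`` — ok test wells plus ok negative controls.

    ``denominator_factor`` is the constant multiplying the robust scale in the
    per-well score denominator; √2 accounts for the variance of a single-well
    difference from the reference population.  Other conventions (e.g. no
    factor) can be matched by changing it.
    """

    inhibitor_threshold: float = -0.5
    strong_inhibitor_threshold: float = -1.0
    activator_threshold: float = 1.0
    reference_policy: str = "test"
    min_reference_size: int = 8
    denominator_factor: float = math.sqrt(2.0)
    seed: int = 0

    _POLICIES = ("test", "test_loo", "test_and_negative")

    def __post_init__(self) -> None:
        if not (
            self.strong_inhibitor_threshold
            <= self.inhibitor_threshold
            < 0.0
            < self.activator_threshold
        ):
            raise ConfigError(
                "thresholds must satisfy strong <= inhibitor < 0 < activator; got "
                f"{self.strong_inhibitor_threshold}, {self.inhibitor_threshold}, "
                f"{self.activator_threshold}"
            )
        if self.reference_policy not in self._POLICIES:
            raise ConfigError(
                f"unknown reference_policy {self.reference_policy!r}; "
                f"expected one of {self._POLICIES}"
            )
        if self.min_reference_size < 2:
            raise ConfigError("min_reference_size must be >= 2")
        if self.denominator_factor <= 0:
            raise ConfigError("denominator_factor must be > 0")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Plate layout

def standard_layout(
    n_positive: int = 12, n_negative: int = 12, n_test: int = 48
) -> list[tuple[WellAddress, WellRole]]:
    """Canonical 96-well layout: controls then test wells in column-major order.

    Positive controls fill A1 downwards, negative controls follow, then test
    wells; remaining wells are empty.  With the default 12 + 12 + 48 the
    controls occupy columns 1–3 and the test compounds columns 4–9.
    """
    total = n_positive + n_negative + n_test
    if total > len(ROWS) * N_COLUMNS:
        raise ConfigError(f"{total} occupied wells exceed plate capacity 96")
    addresses = [
        WellAddress(row, col) for col in range(1, N_COLUMNS + 1) for row in ROWS
    ]
    layout = []
    for i, addr in enumerate(addresses):
        if i < n_positive:
            role = WellRole.POSITIVE_CONTROL
        elif i < n_positive + n_negative:
            role = WellRole.NEGATIVE_CONTROL
        elif i < total:
            role = WellRole.TEST
        else:
            role = WellRole.EMPTY
        layout.append((addr, role))
    return layout


# ---------------------------------------------------------------------------
# Readers / writers

_MAP_COLUMNS = ["plate_id", "well", "role", "compound_id", "dose_um"]
_READING_COLUMNS = ["plate_id", "well", "replicate", "status", "fluorescence"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateMapError(f"{what} is missing columns {missing}")


def read_plate_map(path: Union[str, Path]) -> ScreenDataset:
    """Read a plate-map CSV into a dataset skeleton (no readings attached)."""
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "role": str})
    _require_columns(df, _MAP_COLUMNS, "plate map")
    wells: list[WellRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        addr = WellAddress.parse(row.well)
        key = (row.plate_id, str(addr))
        if key in seen:
            raise PlateMapError(
                f"duplicate well {addr} on plate {row.plate_id} (file row {i})"
            )
        seen.add(key)
        try:
            role = WellRole(row.role)
        except ValueError:
            raise PlateMapError(
                f"unknown role {row.role!r} (file row {i}); expected one of "
                f"{[r.value for r in WellRole]}"
            ) from None
        compound = None if pd.isna(row.compound_id) or row.compound_id == "" else str(row.compound_id)
        dose = 0.0 if pd.isna(row.dose_um) else float(row.dose_um)
        if dose < 0:
            raise PlateMapError(f"negative dose on plate {row.plate_id} well {addr}")
        if role is WellRole.EMPTY and compound is not None:
            raise PlateMapError(
                f"empty well {addr} on plate {row.plate_id} carries compound {compound!r}"
            )
        if role in (WellRole.TEST, WellRole.POSITIVE_CONTROL) and dose == 0.0:
            raise PlateMapError(
                f"{role.value} well {addr} on plate {row.plate_id} has dose 0; "
                "dose 0 is reserved for vehicle/negative-control wells"
            )
        wells.append(WellRecord(str(row.plate_id), addr, role, compound, dose))
    return ScreenDataset(wells)


def read_readings(path: Union[str, Path], dataset: ScreenDataset) -> ScreenDataset:
    """Attach per-replicate status and fluorescence to a plate-map skeleton.

    Returns a new dataset with one record per readings row.  Fluorescence
    values accompanying non-ok rows are discarded so that no downstream
    computation can ever consume a reading from a dead/defective/excluded well.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "status": str})
    _require_columns(df, _READING_COLUMNS, "readings file")
    has_day = "day" in df.columns
    by_key: dict[tuple[str, str], WellRecord] = {
        (w.plate_id, str(w.address)): w for w in dataset.wells
    }
    out: list[WellRecord] = []
    seen: set[tuple[str, str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        addr = WellAddress.parse(row.well)
        key = (str(row.plate_id), str(addr))
        base = by_key.get(key)
        if base is None:
            raise ReadingsError(
                f"reading for unmapped well {addr} on plate {row.plate_id} (file row {i})"
            )
        rep = int(row.replicate)
        if (key[0], key[1], rep) in seen:
            raise ReadingsError(
                f"duplicate reading for plate {key[0]} well {key[1]} replicate {rep}"
            )
        seen.add((key[0], key[1], rep))
        try:
            status = WellStatus(row.status)
        except ValueError:
            raise ReadingsError(f"unknown status {row.status!r} (file row {i})") from None
        fluor: Optional[float] = None
        if status is WellStatus.OK:
            if pd.isna(row.fluorescence):
                raise ReadingsError(
                    f"ok well {addr} on plate {row.plate_id} has no fluorescence value"
                )
            fluor = float(row.fluorescence)
            if fluor < 0:
                raise ReadingsError(
                    f"negative fluorescence on plate {row.plate_id} well {addr}"
                )
        day = None
        if has_day:
            d = getattr(row, "day")
            day = None if pd.isna(d) else str(d)
        out.append(
            dataclasses.replace(
                base, status=status, fluorescence=fluor, replicate=rep, day=day
            )
        )
    return ScreenDataset(out)


def write_plate_map(dataset: ScreenDataset, path: Union[str, Path]) -> None:
    seen: set[tuple[str, str]] = set()
    rows = []
    for w in dataset.wells:
        key = (w.plate_id, str(w.address))
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {
                "plate_id": w.plate_id,
                "well": str(w.address),
                "role": w.role.value,
                "compound_id": w.compound_id or "",
                "dose_um": w.dose_um,
            }
        )
    pd.DataFrame(rows, columns=_MAP_COLUMNS).to_csv(path, index=False)


def write_readings(dataset: ScreenDataset, path: Union[str, Path]) -> None:
    rows = []
    for w in dataset.wells:
        if w.replicate is None:
            continue
        rows.append(
            {
                "plate_id": w.plate_id,
                "well": str(w.address),
                "replicate": w.replicate,
                "status": w.status.value,
                "fluorescence": "" if w.fluorescence is None else w.fluorescence,
                "day": w.day or "",
            }
        )
    pd.DataFrame(rows, columns=_READING_COLUMNS + ["day"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation

@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    plate_counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_screen(dataset: ScreenDataset, config: AnalysisConfig) -> ValidationReport:
    """Report-only consistency check: control counts and reference sizes per plate.

    Never mutates the dataset.  A plate whose ok test-well count falls below
    the minimum reference size cannot be scored and is flagged as a warning.
    """
    report = ValidationReport()
    counts: list[dict] = []
    for pid, rep, wells in dataset.plate_replicates():
        n_ok = {role: 0 for role in WellRole}
        n_total = {role: 0 for role in WellRole}
        for w in wells:
            n_total[w.role] += 1
            if w.is_scored:
                n_ok[w.role] += 1
        counts.append(
            {
                "plate_id": pid,
                "replicate": rep,
                "ok_test": n_ok[WellRole.TEST],
                "ok_positive": n_ok[WellRole.POSITIVE_CONTROL],
                "ok_negative": n_ok[WellRole.NEGATIVE_CONTROL],
                "total_wells": sum(n_total.values()),
            }
        )
        if n_ok[WellRole.TEST] < config.min_reference_size:
            report.warnings.append(
                f"plate {pid} replicate {rep}: insufficient reference "
                f"({n_ok[WellRole.TEST]} ok test wells < {config.min_reference_size})"
            )
        if n_ok[WellRole.NEGATIVE_CONTROL] < 2:
            report.warnings.append(
                f"plate {pid} replicate {rep}: fewer than 2 ok negative controls"
            )
        if n_ok[WellRole.POSITIVE_CONTROL] < 1:
            report.warnings.append(
                f"plate {pid} replicate {rep}: no ok positive control"
            )
    report.plate_counts = pd.DataFrame(
        counts,
        columns=[
            "plate_id",
            "replicate",
            "ok_test",
            "ok_positive",
            "ok_negative",
            "total_wells",
        ],
    )
    return report
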