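"""Measurement data model and CSV I/O for indoor NO2 campaigns.

A *measurement* is one sampled indoor location-shift: which hospital
(and hence which traffic-congestion category its main street falls in),
which season, the location label (clinic, ICU, ...), the fraction of the
shift staff spend there, and the indoor NO2 concentration in ug/m3.

Concentrations either come in directly or are computed from a raw
active-sampling record (collected NO2 mass, pump flow rate, sampling
duration).  Sampling follows the standard bubbler/personal-pump envelope
(NIOSH 6014): a 6-hour morning shift at a pump flow of 0.2-1.0 L/min;
records outside that flow window are rejected by QC.  No
desorption/collection-efficiency factor is applied to the collected
mass — a deliberate simplification, since the method's analytic
constants are instrument-specific.

CSV schema (UTF-8, comma-delimited, dot decimal), one row per location:

    hospital_id, traffic, season, location_label, occupancy_fraction,
    concentration, n_staff

``n_staff`` is optional (empty cell when absent).  An alternate raw
schema replaces ``concentration`` with ``collected_mass_ug``,
``flow_rate_l_min`` and ``duration_min``; exactly one of the two forms
must be present per row.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple

__all__ = [
    "TrafficCategory",
    "Season",
    "SamplingRecord",
    "Measurement",
    "QCError",
    "QCIssue",
    "ReadResult",
    "FLOW_RATE_RANGE",
    "SHIFT_MINUTES",
    "concentration_from_sample",
    "occupancy_fraction_from_minutes",
    "read_measurements",
    "write_measurements",
    "write_qc_report",
]

#: NIOSH 6014 pump-flow envelope, L/min.
FLOW_RATE_RANGE = (0.2, 1.0)

#: Morning shift (08:00-14:00) used as the likelihood denominator, minutes.
SHIFT_MINUTES = 360.0


class QCError(ValueError):
    """A sampling record violates the quality-control envelope."""


class TrafficCategory(Enum):
    """Traffic-congestion category of a hospital's main street.

    Classes are defined by vehicle speed: heavy (0-20 km/h), moderate
    (20-40 km/h), low (> 40 km/h) and the on-sea road (> 40 km/h, a
    seafront street with low congestion).  For rank correlations the
    on-sea road shares the lowest ordinal rank with low traffic.
    """

    HT = "HT"
    MT = "MT"
    LT = "LT"
    OS = "OS"

    @property
    def speed_class(self) -> str:
        return {
            TrafficCategory.HT: "0-20 km/h",
            TrafficCategory.MT: "20-40 km/h",
            TrafficCategory.LT: "> 40 km/h",
            TrafficCategory.OS: "> 40 km/h (on-sea road)",
        }[self]

    @property
    def ordinal_rank(self) -> int:
        return {
            TrafficCategory.HT: 3,
            TrafficCategory.MT: 2,
            TrafficCategory.LT: 1,
            TrafficCategory.OS: 1,
        }[self]


class Season(Enum):
    HOT = "hot"
    COLD = "cold"


@dataclass(frozen=True)
class SamplingRecord:
    """Raw active-sampling record: mass collected over a pumped air volume."""

    collected_mass: float  # ug NO2
    flow_rate: float  # L/min
    duration: float  # minutes

    def __post_init__(self) -> None:
        if self.collected_mass < 0:
            raise ValueError(f"collected mass {self.collected_mass} ug is negative")
        if self.duration <= 0:
            raise ValueError(f"duration {self.duration} min must be positive")
        lo, hi = FLOW_RATE_RANGE
        if not lo <= self.flow_rate <= hi:
            raise QCError(
                f"flow rate {self.flow_rate} L/min outside the NIOSH 6014 "
                f"envelope [{lo}, {hi}] L/min"
            )


@dataclass(frozen=True)
class Measurement:
    """One sampled indoor location-shift."""

    hospital_id: str
    traffic: TrafficCategory
    season: Season
    location_label: str
    occupancy_fraction: float
    concentration: float  # ug/m3
    n_staff: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy_fraction <= 1.0:
            raise ValueError(
                f"occupancy fraction {self.occupancy_fraction} outside [0, 1]"
            )
        if not self.concentration >= 0:
            raise ValueError(f"concentration {self.concentration} is negative")
        if self.n_staff is not None and (self.n_staff < 0 or self.n_staff != int(self.n_staff)):
            raise ValueError(f"n_staff {self.n_staff} must be a non-negative integer")


def concentration_from_sample(record: SamplingRecord) -> float:
    """Concentration in ug/m3 from a raw sampling record.

    The pumped air volume is ``flow_rate x duration`` litres, i.e.
    ``flow_rate x duration / 1000`` m3; concentration is collected mass
    per that volume.
    """
    volume_m3 = record.flow_rate * record.duration / 1000.0
    return record.collected_mass / volume_m3


def occupancy_fraction_from_minutes(
    minutes_present: float, shift_minutes: float = SHIFT_MINUTES
) -> float:
    """Convert minutes present during the shift to the canonical fraction."""
    if shift_minutes <= 0:
        raise ValueError("shift length must be positive")
    if not 0 <= minutes_present <= shift_minutes:
        raise ValueError(
            f"minutes present {minutes_present} outside [0, {shift_minutes}]"
        )
    return minutes_present / shift_minutes


# -- CSV I/O -------------------------------------------------------------

_BASE_COLUMNS = ["hospital_id", "traffic", "season", "location_label", "occupancy_fraction"]
_DIRECT_COLUMNS = _BASE_COLUMNS + ["concentration", "n_staff"]
_RAW_VALUE_COLUMNS = ["collected_mass_ug", "flow_rate_l_min", "duration_min"]


class QCIssue(NamedTuple):
    """One rejected row: 1-based data row number, offending field, reason."""

    row: int
    field: str
    reason: str


class ReadResult(NamedTuple):
    measurements: list[Measurement]
    rejects: list[QCIssue]

    def __iter__(self):  # iterate measurements directly
        return iter(self.measurements)

    def __len__(self) -> int:
        return len(self.measurements)


def _parse_row(row: dict[str, str], has_raw: bool) -> Measurement:
    conc_text = (row.get("concentration") or "").strip()
    raw_texts = [(row.get(c) or "").strip() for c in _RAW_VALUE_COLUMNS] if has_raw else []
    if has_raw:
        any_raw = any(raw_texts)
        if bool(conc_text) == any_raw:
            raise ValueError(
                "exactly one of {concentration} or {mass, flow, duration} per row"
            )
        if any_raw and not all(raw_texts):
            raise ValueError("raw rows need all of mass, flow and duration")
    elif not conc_text:
        raise ValueError("missing concentration")

    if conc_text:
        concentration = float(conc_text)
    else:
        concentration = concentration_from_sample(
            SamplingRecord(
                collected_mass=float(raw_texts[0]),
                flow_rate=float(raw_texts[1]),
                duration=float(raw_texts[2]),
            )
        )

    n_staff_text = (row.get("n_staff") or "").strip()
    return Measurement(
        hospital_id=row["hospital_id"].strip(),
        traffic=TrafficCategory(row["traffic"].strip().upper()),
        season=Season(row["season"].strip().lower()),
        location_label=row["location_label"].strip(),
        occupancy_fraction=float(row["occupancy_fraction"]),
        concentration=concentration,
        n_staff=int(n_staff_text) if n_staff_text else None,
    )


def read_measurements(path: str | Path, strict: bool = False) -> ReadResult:
    """Read a measurement CSV, validating every row.

    Invalid rows are reported in ``rejects`` with their 1-based data row
    number and reason (or raised immediately when ``strict``).  Row
    order is preserved.  A missing required column raises
    ``ValueError`` regardless of ``strict``.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _BASE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"measurement CSV missing required columns: {missing}")
        has_raw = all(c in header for c in _RAW_VALUE_COLUMNS)
        if "concentration" not in header and not has_raw:
            raise ValueError(
                "measurement CSV needs a concentration column or the raw "
                f"columns {_RAW_VALUE_COLUMNS}"
            )
        measurements: list[Measurement] = []
        rejects: list[QCIssue] = []
        for i, row in enumerate(reader, start=1):
            try:
                measurements.append(_parse_row(row, has_raw))
            except (ValueError, KeyError) as exc:
                if strict:
                    raise ValueError(f"row {i}: {exc}") from exc
                field = _guess_field(str(exc))
                rejects.append(QCIssue(row=i, field=field, reason=str(exc)))
    return ReadResult(measurements, rejects)


def _guess_field(reason: str) -> str:
    for name in (
        "occupancy fraction",
        "concentration",
        "flow rate",
        "duration",
        "collected mass",
        "n_staff",
    ):
        if name in reason:
            return name.replace(" ", "_")
    return ""


def _format_number(x: float) -> str:
    """Round-trip-safe numeric text: integers without a trailing .0."""
    if math.isfinite(x) and x == int(x):
        return str(int(x))
    return repr(float(x))


def write_measurements(measurements: Iterable[Measurement], path: str | Path) -> Path:
    """Write measurements to the standard CSV schema.

    ``read_measurements(write_measurements(x))`` is the identity on
    valid collections; absent ``n_staff`` round-trips through an empty
    cell.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DIRECT_COLUMNS)
        for m in measurements:
            writer.writerow(
                [
                    m.hospital_id,
                    m.traffic.value,
                    m.season.value,
                    m.location_label,
                    _format_number(m.occupancy_fraction),
                    _format_number(m.concentration),
                    "" if m.n_staff is None else str(m.n_staff),
                ]
            )
    return path


def write_qc_report(rejects: Iterable[QCIssue], path: str | Path) -> Path:
    """Write rejected rows as JSON lines: {"row": ..., "field": ..., "reason": ...}."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for issue in rejects:
            fh.write(json.dumps(issue._asdict()) + "\n")
    return path
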