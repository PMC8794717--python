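"""Tabular isotope I/O and raw-run normalization.

Delta values (δ15N, δ13C) are expressed in per-mil (‰) relative to the
international scale anchors: atmospheric N₂ (AIR) for nitrogen and Vienna
Pee Dee Belemnite (VPDB, here in its VPDB-LSVEC realization) for carbon.
Instrument drift and offset in a run are corrected by a per-run two-point
affine map anchored on two reference standards with assigned values, the
conventional pair for organic samples being USGS40 and USGS41a.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CalibrationError,
    DomainError,
    EmptyInputError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Canonical element codes and the scale each is anchored to.
ELEMENT_SCALES = {"N15": "AIR", "C13": "VPDB"}

#: Canonical column name per element in tidy sample tables.
ELEMENT_COLUMNS = {"N15": "d15N", "C13": "d13C"}


@dataclass(frozen=True)
class DeltaValue:
    """A single delta value in ‰ on its fixed international scale."""

    element: str  # "N15" or "C13"
    value: float  # ‰

    def __post_init__(self) -> None:
        if self.element not in ELEMENT_SCALES:
            raise DomainError(f"unknown element {self.element!r}")
        if not np.isfinite(self.value):
            raise DomainError(f"non-finite delta value for {self.element}")

    @property
    def scale(self) -> str:
        return ELEMENT_SCALES[self.element]


@dataclass(frozen=True)
class ReferenceStandard:
    """An international reference material with assigned delta values."""

    name: str
    assigned_d15N: float
    assigned_d13C: float
    uncertainty_d15N: float = 0.0
    uncertainty_d13C: float = 0.0

    def assigned(self, element: str) -> float:
        if element == "N15":
            return self.assigned_d15N
        if element == "C13":
            return self.assigned_d13C
        raise DomainError(f"unknown element {element!r}")


#: Assigned values for the USGS40/USGS41a glutamic-acid standard pair
#: (δ13C on the VPDB-LSVEC realization; no scale conversion is attempted).
USGS40 = ReferenceStandard("USGS40", -4.52, -26.39, 0.06, 0.04)
USGS41A = ReferenceStandard("USGS41a", 47.55, 36.55, 0.15, 0.08)


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One whisker-segment measurement: a δ15N/δ13C pair with provenance."""

    individual_id: str
    segment_id: str
    d15N: DeltaValue
    d13C: DeltaValue
    sample_mass: float | None = None  # mg
    date_window: tuple[date, date] | None = None

    def __post_init__(self) -> None:
        if self.sample_mass is not None and not self.sample_mass > 0:
            raise DomainError("sample_mass must be positive")
        if self.date_window is not None:
            start, end = self.date_window
            if start > end:
                raise DomainError("date_window start must not exceed end")


@dataclass(frozen=True)
class RowRejection:
    """Report of one rejected input row (0-based data-row index)."""

    row: int
    reason: str


# ---------------------------------------------------------------------------
# sample tables

REQUIRED_COLUMNS = ("individual_id", "segment_id", "d15N", "d13C")
OPTIONAL_COLUMNS = ("mass_mg",)


def read_sample_table(
    source,
    schema: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[RowRejection]]:
    """Read a tidy per-segment isotope table.

    Parameters
    ----------
    source
        Path or text stream of a CSV file with a header row.
    schema
        Optional map from canonical column names (``individual_id``,
        ``segment_id``, ``d15N``, ``d13C``, ``mass_mg``) to the names used
        in the file, so external table dialects can be adapted without
        code change.

    Returns
    -------
    (table, rejections)
        ``table`` has canonical columns; rows whose numeric fields do not
        parse are dropped and reported (never silently) in ``rejections``.
    """
    schema = dict(schema or {})
    raw = pd.read_csv(source, dtype=str, skipinitialspace=True)
    if raw.shape[1] and raw.dropna(how="all").empty:
        raise EmptyInputError("sample table contains no data rows")

    rename = {schema.get(canon, canon): canon for canon in
              REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    present = {c: rename[c] for c in raw.columns if c in rename}
    table = raw.rename(columns=present)

    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if table.empty:
        raise EmptyInputError("sample table contains no data rows")

    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS
            if c in table.columns]
    table = table[keep]

    numeric = ["d15N", "d13C"] + (["mass_mg"] if "mass_mg" in keep else [])
    rejections: list[RowRejection] = []
    mask = pd.Series(True, index=table.index)
    parsed = {}
    for col in numeric:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() & (col != "mass_mg")  # mass is optional per row
        for i in table.index[bad]:
            reason = f"unparseable {col}={table.at[i, col]!r}"
            rejections.append(RowRejection(int(i), reason))
            logger.warning("WARN row=%d reason=%s", i, reason)
        mask &= ~bad
        parsed[col] = vals
    for col, vals in parsed.items():
        table[col] = vals
    table = table[mask].reset_index(drop=True)
    return table, rejections


def write_sample_table(table: pd.DataFrame, target) -> None:
    """Write a tidy sample table as UTF-8 CSV ('.' decimal separator)."""
    table.to_csv(target, index=False)


def to_measurements(table: pd.DataFrame) -> list[IsotopeMeasurement]:
    """Convert a tidy sample table into :class:`IsotopeMeasurement` records."""
    out = []
    for _, row in table.iterrows():
        mass = row.get("mass_mg")
        out.append(
            IsotopeMeasurement(
                individual_id=str(row["individual_id"]),
                segment_id=str(row["segment_id"]),
                d15N=DeltaValue("N15", float(row["d15N"])),
                d13C=DeltaValue("C13", float(row["d13C"])),
                sample_mass=None if mass is None or pd.isna(mass)
                else float(mass),
            )
        )
    return out


# ---------------------------------------------------------------------------
# delta notation

def delta_from_ratio(r_sample: float, r_reference: float) -> float:
    """δ (‰) = (R_sample/R_reference − 1) × 1000."""
    if not (r_sample > 0 and r_reference > 0):
        raise DomainError("isotope ratios must be positive")
    return (r_sample / r_reference - 1.0) * 1000.0


def ratio_from_delta(delta: float, r_reference: float) -> float:
    """Inverse of :func:`delta_from_ratio`."""
    if not r_reference > 0:
        raise DomainError("reference ratio must be positive")
    r = (delta / 1000.0 + 1.0) * r_reference
    if not r > 0:
        raise DomainError("delta implies a non-positive sample ratio")
    return r


# ---------------------------------------------------------------------------
# two-point normalization

def two_point_calibration(
    raw1: float, assigned1: float, raw2: float, assigned2: float
) -> tuple[float, float]:
    """Solve corrected = a + b·raw mapping each raw anchor to its assigned
    value. Raises :class:`CalibrationError` when the anchors coincide."""
    if raw1 == raw2:
        raise CalibrationError(
            "standards' raw readings are equal; two-point line is degenerate"
        )
    b = (assigned2 - assigned1) / (raw2 - raw1)
    a = assigned1 - b * raw1
    return a, b


def _mean_reading(reading) -> float:
    # replicate standard readings are averaged before fitting the line
    arr = np.atleast_1d(np.asarray(reading, dtype=float))
    return float(arr.mean())


def two_point_normalize(
    run: pd.DataFrame,
    standards: Sequence[tuple[ReferenceStandard, Mapping[str, object]]],
    *,
    element_col: str = "element",
    value_col: str = "raw_value",
) -> pd.DataFrame:
    """Correct a raw instrument run against two reference standards.

    ``run`` is a tidy table with one row per (sample, element) raw reading;
    ``standards`` pairs each :class:`ReferenceStandard` with its raw
    readings, a mapping ``element -> reading`` (scalar or replicate
    sequence, averaged). The affine correction is fitted per element
    independently. Returns a copy of ``run`` with a ``corrected`` column.
    """
    if len(standards) != 2:
        raise CalibrationError("exactly two reference standards are required")
    (std1, raw1), (std2, raw2) = standards
    out = run.copy()
    out["corrected"] = np.nan
    for element in out[element_col].unique():
        if element not in ELEMENT_SCALES:
            raise DomainError(f"unknown element {element!r} in run")
        for std, readings in ((std1, raw1), (std2, raw2)):
            if element not in readings:
                raise CalibrationError(
                    f"standard {std.name} has no reading for {element}"
                )
        if std1.assigned(element) == std2.assigned(element):
            raise CalibrationError(
                f"standards share an assigned value for {element}"
            )
        a, b = two_point_calibration(
            _mean_reading(raw1[element]), std1.assigned(element),
            _mean_reading(raw2[element]), std2.assigned(element),
        )
        sel = out[element_col] == element
        out.loc[sel, "corrected"] = a + b * out.loc[sel, value_col].astype(float)
    return out
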