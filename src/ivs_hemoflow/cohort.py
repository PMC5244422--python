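"""Clinical and macroscopic placenta descriptors and derived morphometrics.

Houses the per-case record (gestational age, birth and placental weight,
placental diameters, surface area, thickness) for the three exemplary
pregnancies driving the flow scenarios -- clinically normal, intrauterine
growth retardation (IUGR), and IUGR with preeclampsia (IUGR/PE) -- and
computes the two derived ratios reported alongside them: the placental/birth
weight ratio PW/BW and the roundness LD/SD (longest over shortest diameter).

Surface area is stored as given; no formula recomputes it.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Any

log = logging.getLogger(__name__)

GROUPS = ("normal", "iugr", "iugr_pe")

MANDATORY_COLUMNS = (
    "group",
    "ga_weeks",
    "bw_g",
    "pw_g",
    "ld_cm",
    "sd_cm",
    "surface_cm2",
    "thickness_cm",
)


class InvalidRecordError(ValueError):
    """A placenta record violates its invariants (non-positive measures, LD < SD)."""


class CohortSchemaError(ValueError):
    """A cohort CSV lacks a mandatory column."""


class CohortParseError(ValueError):
    """A cohort CSV cell could not be parsed; message names the row."""


@dataclass(frozen=True)
class PlacentaRecord:
    """One placenta: clinical group, gestational age and macroscopic measures.

    Units: gestational age in weeks, weights in grams, diameters and
    thickness in centimetres, surface area in cm².
    """

    group: str
    ga_weeks: float
    bw_g: float
    pw_g: float
    ld_cm: float
    sd_cm: float
    surface_cm2: float
    thickness_cm: float
    annotations: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidRecordError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        for name in ("ga_weeks", "bw_g", "pw_g", "ld_cm", "sd_cm", "surface_cm2", "thickness_cm"):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidRecordError(f"{name} must be strictly positive, got {value!r}")
        if self.ld_cm < self.sd_cm:
            raise InvalidRecordError(
                f"longest diameter ({self.ld_cm}) smaller than shortest ({self.sd_cm})"
            )


def round2(x: float) -> float:
    """Round to two decimals with round-half-to-even, as printed clinical tables do."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def morphometrics(record: PlacentaRecord) -> dict[str, float]:
    """Derived morphometrics for one record.

    Returns both full-precision values and their 2-decimal rounded
    counterparts (keys with suffix ``_2dp``):

    * ``pw_bw_ratio`` -- placental weight / birth weight (dimensionless);
    * ``roundness`` -- longest / shortest placental diameter (>= 1).
    """
    pw_bw = record.pw_g / record.bw_g
    roundness = record.ld_cm / record.sd_cm
    return {
        "pw_bw_ratio": pw_bw,
        "roundness": roundness,
        "pw_bw_ratio_2dp": round2(pw_bw),
        "roundness_2dp": round2(roundness),
    }


def read_cohort_csv(path: str | Path | io.TextIOBase) -> list[PlacentaRecord]:
    """Read a cohort CSV (header row, one case per row) into validated records.

    Unknown columns are preserved verbatim in ``record.annotations``.
    An empty file yields an empty list (with a logged warning).
    """
    if isinstance(path, io.TextIOBase):
        handle = path
        close = False
    else:
        handle = open(path, newline="", encoding="utf-8")
        close = True
    try:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            log.warning("cohort CSV %s is empty", path)
            warnings.warn(f"cohort CSV {path} is empty", stacklevel=2)
            return []
        missing = [c for c in MANDATORY_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CohortSchemaError(f"cohort CSV missing mandatory column(s): {missing}")
        records: list[PlacentaRecord] = []
        for i, row in enumerate(reader):
            kwargs: dict[str, Any] = {"group": (row["group"] or "").strip()}
            for col in MANDATORY_COLUMNS[1:]:
                cell = row[col]
                try:
                    kwargs[col] = float(cell)
                except (TypeError, ValueError) as exc:
                    raise CohortParseError(
                        f"row {i}: column {col!r} value {cell!r} is not numeric"
                    ) from exc
            extras = {k: v for k, v in row.items() if k not in MANDATORY_COLUMNS and k is not None}
            try:
                records.append(PlacentaRecord(annotations=extras, **kwargs))
            except InvalidRecordError as exc:
                raise InvalidRecordError(f"row {i}: {exc}") from exc
        if not records:
            log.warning("cohort CSV %s has a header but no rows", path)
        return records
    finally:
        if close:
            handle.close()


def morphometrics_json(records: list[PlacentaRecord]) -> list[dict[str, Any]]:
    """JSON-serialisable export: per record, raw fields plus derived morphometrics."""
    out = []
    for r in records:
        row: dict[str, Any] = {c: getattr(r, c) for c in MANDATORY_COLUMNS}
        row.update(morphometrics(r))
        out.append(row)
    return out


#: The three exemplary cases whose Doppler traces drive the flow scenarios
#: (clinical/macroscopic table of the source cohort; printed values are inputs).
EXEMPLARY_COHORT: tuple[PlacentaRecord, ...] = (
    PlacentaRecord("normal", 38.5, 3130.0, 488.0, 17.5, 15.0, 825.0, 2.10),
    PlacentaRecord("iugr", 33.6, 1620.0, 277.0, 15.0, 13.0, 613.0, 2.00),
    PlacentaRecord("iugr_pe", 33.3, 1470.0, 339.0, 19.5, 10.5, 643.0, 1.30),
)
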