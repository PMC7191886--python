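"""Measurement-record data model and CSV input/output.

A :class:`DustMeasurement` is one single-fraction workplace dust
measurement: a concentration in mg m⁻³ of either the inhalable or the
respirable aerosol fraction, together with the metadata needed to match
it to its parallel measurement of the other fraction (factory, location,
timestamps, industrial sector, report number, sampling type, working
activity, material).  A :class:`MeasurementPair` is a matched
inhalable/respirable duo carrying the natural-log concentrations used by
the regression stage.

Records travel as UTF-8 CSV with a header row, "." decimal separator and
ISO-8601 timestamps at minute precision.  Foreign exports can be adapted
by passing a column mapping (field name -> column name).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from datetime import datetime
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .grouping import GroupAssignment

__all__ = [
    "Fraction",
    "SamplingType",
    "DustMeasurement",
    "MeasurementPair",
    "RowReject",
    "read_measurements",
    "write_measurements",
    "write_reject_report",
    "write_pairs",
    "read_pairs",
]

TIME_FORMAT = "%Y-%m-%dT%H:%M"

#: tolerance between duration_h and (end - start), in hours (one minute)
_DURATION_TOL_H = 1.0 / 60.0


class Fraction(str, enum.Enum):
    """Aerosol size fraction of a measurement."""

    INHALABLE = "inhalable"
    RESPIRABLE = "respirable"


class SamplingType(str, enum.Enum):
    """Whether the sampler was worn by a person or placed in the room."""

    PERSONAL = "personal"
    STATIONARY = "stationary"


#: CSV columns in canonical order; keys double as field names.
FIELD_ORDER = (
    "record_id",
    "fraction",
    "concentration",
    "below_loq",
    "start",
    "end",
    "duration_h",
    "factory_id",
    "location_id",
    "industrial_sector",
    "report_number",
    "sampling_type",
    "working_activity",
    "material_category",
    "sampler_model",
    "year",
)


@dataclasses.dataclass(frozen=True)
class DustMeasurement:
    """One single-fraction dust measurement with matching metadata.

    ``concentration`` is in mg m⁻³.  Records flagged ``below_loq`` carry
    the limit of quantification as their concentration; they are kept at
    read time and removed by the exclusion filter so that the filter can
    count them.  ``material_category`` holds the raw subcategory string;
    it is interpreted against the taxonomy at grouping time.
    """

    record_id: str
    fraction: Fraction
    concentration: float
    below_loq: bool
    start: datetime
    end: datetime
    duration_h: float
    factory_id: str
    location_id: str
    industrial_sector: str
    report_number: str
    sampling_type: SamplingType
    working_activity: str
    material_category: str
    sampler_model: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("empty record_id")
        if not self.below_loq and not self.concentration > 0:
            raise ValueError("nonpositive concentration")
        if self.below_loq and self.concentration < 0:
            raise ValueError("negative LOQ concentration")
        if self.end < self.start:
            raise ValueError("end before start")
        if self.duration_h < 0:
            raise ValueError("negative duration")
        elapsed_h = (self.end - self.start).total_seconds() / 3600.0
        if abs(elapsed_h - self.duration_h) > _DURATION_TOL_H + 1e-9:
            raise ValueError("duration inconsistent with start/end")


@dataclasses.dataclass
class MeasurementPair:
    """A matched inhalable/respirable measurement duo.

    ``ln_ci`` / ``ln_cr`` are the natural logs of the inhalable and
    respirable concentrations; the respirable concentration never
    exceeds the inhalable one.  ``group`` is filled in by the grouping
    stage.
    """

    inhalable: DustMeasurement
    respirable: DustMeasurement
    ln_ci: float
    ln_cr: float
    group: "GroupAssignment | None" = None

    def __post_init__(self) -> None:
        if self.inhalable.fraction is not Fraction.INHALABLE:
            raise ValueError("first member must be the inhalable measurement")
        if self.respirable.fraction is not Fraction.RESPIRABLE:
            raise ValueError("second member must be the respirable measurement")
        if self.respirable.concentration > self.inhalable.concentration:
            raise ValueError("respirable concentration exceeds inhalable")
        for name, value, conc in (
            ("ln_ci", self.ln_ci, self.inhalable.concentration),
            ("ln_cr", self.ln_cr, self.respirable.concentration),
        ):
            if not math.isclose(value, math.log(conc), rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(f"{name} inconsistent with concentration")

    @classmethod
    def from_records(
        cls, inhalable: DustMeasurement, respirable: DustMeasurement
    ) -> "MeasurementPair":
        return cls(
            inhalable=inhalable,
            respirable=respirable,
            ln_ci=math.log(inhalable.concentration),
            ln_cr=math.log(respirable.concentration),
        )


@dataclasses.dataclass(frozen=True)
class RowReject:
    """A CSV row that could not be turned into a valid record."""

    row_index: int
    record_id: str
    reason: str


def _parse_bool(text: str) -> bool:
    t = str(text).strip().lower()
    if t in {"true", "1", "yes"}:
        return True
    if t in {"false", "0", "no", ""}:
        return False
    raise ValueError(f"unparsable boolean {text!r}")


def _row_to_record(row: Mapping[str, str]) -> DustMeasurement:
    return DustMeasurement(
        record_id=str(row["record_id"]).strip(),
        fraction=Fraction(str(row["fraction"]).strip().lower()),
        concentration=float(row["concentration"]),
        below_loq=_parse_bool(row["below_loq"]),
        start=datetime.strptime(str(row["start"]).strip(), TIME_FORMAT),
        end=datetime.strptime(str(row["end"]).strip(), TIME_FORMAT),
        duration_h=float(row["duration_h"]),
        factory_id=str(row["factory_id"]).strip(),
        location_id=str(row["location_id"]).strip(),
        industrial_sector=str(row["industrial_sector"]).strip(),
        report_number=str(row["report_number"]).strip(),
        sampling_type=SamplingType(str(row["sampling_type"]).strip().lower()),
        working_activity=str(row["working_activity"]).strip(),
        material_category=str(row["material_category"]).strip(),
        sampler_model=str(row.get("sampler_model", "") or ""),
        year=int(row["year"]),
    )


def read_measurements(
    path,
    columns: Mapping[str, str] | None = None,
) -> tuple[list[DustMeasurement], list[RowReject]]:
    """Read measurement records from CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    columns
        Optional mapping ``field name -> column name in the file`` for
        adapting foreign exports; unmapped fields use their own name.

    Returns
    -------
    (records, rejects)
        Every input row ends up in exactly one of the two lists; a
        reject carries the row index and a human-readable reason.

    Raises
    ------
    ValueError
        If a mandatory column is missing entirely (fatal, unlike a
        malformed row).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping = {f: f for f in FIELD_ORDER}
    if columns:
        mapping.update(columns)
    missing = [
        col
        for field, col in mapping.items()
        if field != "sampler_model" and col not in frame.columns
    ]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(sorted(missing))}")

    records: list[DustMeasurement] = []
    rejects: list[RowReject] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        raw = dict(zip(frame.columns, row))
        renamed = {field: raw.get(col, "") for field, col in mapping.items()}
        try:
            records.append(_row_to_record(renamed))
        except (ValueError, KeyError) as exc:
            rejects.append(
                RowReject(
                    row_index=idx,
                    record_id=str(renamed.get("record_id", "")),
                    reason=str(exc),
                )
            )
    assert len(records) + len(rejects) == len(frame)
    return records, rejects


def _record_to_row(rec: DustMeasurement) -> dict[str, object]:
    return {
        "record_id": rec.record_id,
        "fraction": rec.fraction.value,
        "concentration": repr(rec.concentration),
        "below_loq": rec.below_loq,
        "start": rec.start.strftime(TIME_FORMAT),
        "end": rec.end.strftime(TIME_FORMAT),
        "duration_h": repr(rec.duration_h),
        "factory_id": rec.factory_id,
        "location_id": rec.location_id,
        "industrial_sector": rec.industrial_sector,
        "report_number": rec.report_number,
        "sampling_type": rec.sampling_type.value,
        "working_activity": rec.working_activity,
        "material_category": rec.material_category,
        "sampler_model": rec.sampler_model,
        "year": rec.year,
    }


def write_measurements(records: Iterable[DustMeasurement], path) -> None:
    """Write records as CSV (re-readable by :func:`read_measurements`)."""
    rows = [_record_to_row(r) for r in records]
    pd.DataFrame(rows, columns=list(FIELD_ORDER)).to_csv(path, index=False)


def write_reject_report(rejects: Sequence[RowReject], path) -> None:
    """Write the reject report as CSV with a reason column."""
    pd.DataFrame(
        [dataclasses.asdict(r) for r in rejects],
        columns=["row_index", "record_id", "reason"],
    ).to_csv(path, index=False)


_PAIR_EXTRA = ("ln_ci", "ln_cr", "activity", "material", "combined", "heuristic")


def write_pairs(pairs: Sequence[MeasurementPair], path) -> None:
    """Write pairs as CSV, one row per pair.

    Both member records are written in full (prefixes ``i_`` and ``r_``)
    plus the log concentrations and, if assigned, the group labels, so
    the file is re-readable by :func:`read_pairs`.
    """
    columns = (
        [f"i_{f}" for f in FIELD_ORDER]
        + [f"r_{f}" for f in FIELD_ORDER]
        + list(_PAIR_EXTRA)
    )
    rows = []
    for p in pairs:
        row: dict[str, object] = {}
        for prefix, rec in (("i_", p.inhalable), ("r_", p.respirable)):
            for key, value in _record_to_row(rec).items():
                row[prefix + key] = value
        row["ln_ci"] = repr(p.ln_ci)
        row["ln_cr"] = repr(p.ln_cr)
        g = p.group
        row["activity"] = "" if g is None else g.activity
        row["material"] = "" if g is None else g.material
        row["combined"] = "" if g is None or g.combined is None else g.combined
        row["heuristic"] = "" if g is None or g.heuristic is None else g.heuristic
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_pairs(path) -> list[MeasurementPair]:
    """Read a pair file written by :func:`write_pairs`."""
    from .grouping import GroupAssignment  # deferred: avoids import cycle

    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    pairs: list[MeasurementPair] = []
    for _, row in frame.iterrows():
        members = {}
        for prefix in ("i_", "r_"):
            raw = {f: row[prefix + f] for f in FIELD_ORDER}
            members[prefix] = _row_to_record(raw)
        pair = MeasurementPair(
            inhalable=members["i_"],
            respirable=members["r_"],
            ln_ci=float(row["ln_ci"]),
            ln_cr=float(row["ln_cr"]),
        )
        if row["activity"] != "":
            pair.group = GroupAssignment(
                activity=int(row["activity"]),
                material=row["material"],
                combined=row["combined"] or None,
                heuristic=row["heuristic"] or None,
            )
        pairs.append(pair)
    return pairs
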