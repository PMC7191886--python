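"""Exclusion filters and inhalable/respirable pair formation.

Raw single-fraction records are first filtered: measurements shorter
than 2 h, below the limit of quantification, or above the concentration
cutoffs (100 mg m⁻³ inhalable, 10 mg m⁻³ respirable) are removed, each
with an auditable reason.  Surviving records are then matched into
inhalable/respirable pairs: both measurements must come from the same
factory, location and calendar day, start and end within a 5-minute
tolerance, agree on industrial sector, report number, sampling type and
working activity, and the respirable concentration must not exceed the
inhalable one (respirable dust is a physical subfraction of inhalable
dust).  Matching is deterministic and greedy; each record is used at
most once.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from datetime import date, datetime
from typing import Sequence

from .records import DustMeasurement, Fraction, MeasurementPair

__all__ = [
    "FilterReport",
    "PairingReport",
    "apply_exclusion_filters",
    "form_pairs",
]

REASON_DURATION = "duration below minimum"
REASON_LOQ = "below limit of quantification"
REASON_RANGE_INHALABLE = "inhalable concentration above cutoff"
REASON_RANGE_RESPIRABLE = "respirable concentration above cutoff"


@dataclasses.dataclass
class FilterReport:
    """Bookkeeping of the exclusion-filter stage.

    A record can carry several reasons; ``n_remaining`` counts records
    with no reason at all, so per-reason counts may sum to more than
    ``n_input - n_remaining``.
    """

    n_input: int = 0
    n_excluded_duration: int = 0
    n_excluded_loq: int = 0
    n_excluded_range: int = 0
    n_remaining: int = 0
    reasons: dict[str, list[str]] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class PairingReport:
    """Bookkeeping of the pair-formation stage.

    Rejected near-matches are counted once per unmatched inhalable
    record, by the most specific criterion it got past: records whose
    only failure was the concentration ordering count as
    ``n_rejected_cr_gt_ci``, then the time tolerance, then the metadata
    equality.  Inhalable records with no candidate at all (no respirable
    record in the same factory/location/day) are not near-matches and
    are not counted.
    """

    n_candidates: int = 0
    n_pairs: int = 0
    n_rejected_time: int = 0
    n_rejected_metadata: int = 0
    n_rejected_cr_gt_ci: int = 0


def apply_exclusion_filters(
    records: Sequence[DustMeasurement],
    max_ci: float = 100.0,
    max_cr: float = 10.0,
    min_duration_h: float = 2.0,
) -> tuple[list[DustMeasurement], FilterReport]:
    """Apply the pre-pairing exclusion rules.

    Cutoffs are strict as stated: concentrations *above* ``max_ci`` /
    ``max_cr`` and durations *below* ``min_duration_h`` are excluded, so
    a respirable measurement of exactly 10 mg m⁻³ or a 2.0 h measurement
    is retained.
    """
    report = FilterReport(n_input=len(records))
    kept: list[DustMeasurement] = []
    for rec in records:
        reasons: list[str] = []
        if rec.duration_h < min_duration_h:
            reasons.append(REASON_DURATION)
            report.n_excluded_duration += 1
        if rec.below_loq:
            reasons.append(REASON_LOQ)
            report.n_excluded_loq += 1
        if rec.fraction is Fraction.INHALABLE and rec.concentration > max_ci:
            reasons.append(REASON_RANGE_INHALABLE)
            report.n_excluded_range += 1
        elif rec.fraction is Fraction.RESPIRABLE and rec.concentration > max_cr:
            reasons.append(REASON_RANGE_RESPIRABLE)
            report.n_excluded_range += 1
        if reasons:
            report.reasons[rec.record_id] = reasons
        else:
            kept.append(rec)
    report.n_remaining = len(kept)
    assert report.n_remaining == report.n_input - len(report.reasons)
    return kept, report


def _metadata_key(rec: DustMeasurement) -> tuple:
    return (
        rec.industrial_sector,
        rec.report_number,
        rec.sampling_type,
        rec.working_activity,
    )


def _day_key(rec: DustMeasurement) -> tuple[str, str, date]:
    return (rec.factory_id, rec.location_id, rec.start.date())


def _offset_min(a: datetime, b: datetime) -> float:
    return abs((a - b).total_seconds()) / 60.0


def form_pairs(
    records: Sequence[DustMeasurement],
    time_tolerance_min: float = 5.0,
) -> tuple[list[MeasurementPair], PairingReport]:
    """Form inhalable/respirable pairs by the 12-variable matching rule.

    Inhalable records are processed in (start, record_id) order; for
    each, the respirable candidates sharing factory, location and
    calendar day are narrowed by metadata equality, the inclusive
    ±``time_tolerance_min`` window on both start and end, and the
    c_R ≤ c_I requirement.  Ambiguities are resolved deterministically:
    smallest |start offset| + |end offset|, ties by record_id.  The
    result is independent of the input order.
    """
    inhalable = sorted(
        (r for r in records if r.fraction is Fraction.INHALABLE),
        key=lambda r: (r.start, r.record_id),
    )
    respirable = [r for r in records if r.fraction is Fraction.RESPIRABLE]

    by_day: dict[tuple, list[DustMeasurement]] = defaultdict(list)
    for rec in respirable:
        by_day[_day_key(rec)].append(rec)

    used: set[str] = set()
    pairs: list[MeasurementPair] = []
    report = PairingReport(n_candidates=len(records))

    for ih in inhalable:
        day_candidates = [r for r in by_day.get(_day_key(ih), ()) if r.record_id not in used]
        meta_ok = [r for r in day_candidates if _metadata_key(r) == _metadata_key(ih)]
        time_ok = [
            r
            for r in meta_ok
            if _offset_min(r.start, ih.start) <= time_tolerance_min
            and _offset_min(r.end, ih.end) <= time_tolerance_min
        ]
        phys_ok = [r for r in time_ok if r.concentration <= ih.concentration]
        if phys_ok:
            best = min(
                phys_ok,
                key=lambda r: (
                    _offset_min(r.start, ih.start) + _offset_min(r.end, ih.end),
                    r.record_id,
                ),
            )
            used.add(best.record_id)
            pairs.append(MeasurementPair.from_records(ih, best))
            report.n_pairs += 1
        elif time_ok:
            report.n_rejected_cr_gt_ci += 1
        elif meta_ok:
            report.n_rejected_time += 1
        elif day_candidates:
            report.n_rejected_metadata += 1
    return pairs, report
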