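"""Shared fixtures: record factories, taxonomy and registry."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from dustconv import (
    DustMeasurement,
    Fraction,
    SamplingType,
    load_registry,
    load_taxonomy,
)

TIME_FORMAT = "%Y-%m-%dT%H:%M"


def make_record(
    record_id: str,
    fraction: Fraction | str,
    concentration: float,
    start: str = "2005-01-03T08:00",
    duration_h: float = 8.0,
    *,
    below_loq: bool = False,
    factory_id: str = "F1",
    location_id: str = "hall 1",
    industrial_sector: str = "foundries",
    report_number: str = "R1",
    sampling_type: SamplingType = SamplingType.PERSONAL,
    working_activity: str = "metal inert gas welding",
    material_category: str = "metal/metal ores/slag/metallic shot",
    sampler_model: str = "GSP-10",
) -> DustMeasurement:
    """Build a valid record with sensible defaults for pairing tests."""
    begin = datetime.strptime(start, TIME_FORMAT)
    end = begin + timedelta(minutes=round(duration_h * 60))
    return DustMeasurement(
        record_id=record_id,
        fraction=Fraction(fraction),
        concentration=concentration,
        below_loq=below_loq,
        start=begin,
        end=end,
        duration_h=duration_h,
        factory_id=factory_id,
        location_id=location_id,
        industrial_sector=industrial_sector,
        report_number=report_number,
        sampling_type=sampling_type,
        working_activity=working_activity,
        material_category=material_category,
        sampler_model=sampler_model,
        year=begin.year,
    )


def make_duo(
    index: int,
    ci: float = 4.0,
    cr: float = 1.0,
    start: str = "2005-01-03T08:00",
    start_offset_min: int = 0,
    end_offset_min: int = 0,
    **kwargs,
) -> tuple[DustMeasurement, DustMeasurement]:
    """Build a matched inhalable/respirable duo, optionally perturbed."""
    report = kwargs.pop("report_number", f"R{index:04d}")
    inhalable = make_record(
        f"D{index:04d}-I", "inhalable", ci, start=start,
        report_number=report, **kwargs,
    )
    begin = inhalable.start + timedelta(minutes=start_offset_min)
    end = inhalable.end + timedelta(minutes=end_offset_min)
    duration = (end - begin).total_seconds() / 3600.0
    respirable = make_record(
        f"D{index:04d}-R", "respirable", cr,
        start=begin.strftime(TIME_FORMAT), duration_h=duration,
        report_number=report, **kwargs,
    )
    return inhalable, respirable


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def registry():
    return load_registry()
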