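"""Group taxonomy: working activity, material, combined and heuristic groups.

The conversion analysis splits measurement pairs along two technical
axes: the *working activity* (six mutually independent groups — surface
treatment, high temperature processing, filling/transport/storage,
machining/abrasive techniques, forming, others) and the *material*
(mineral-, metal- and fiber-dominated pools of the printed
subcategories).  Four activity/material combinations and seven
trial-and-error "heuristic" groups (soldering, casting, welding, high
temperature cutting, blasting, chiseling/embossing, wire drawing —
labelled alpha..eta) have their own published conversion functions.

When converting, the most specific applicable group should be used:
heuristic, then combined, then activity or material; the whole-dataset
function mixes too many dust-generating processes and is only returned
on explicit request.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .records import DustMeasurement, MeasurementPair

__all__ = [
    "GroupAssignment",
    "GroupTaxonomy",
    "HeuristicGroup",
    "NoApplicableGroupError",
    "load_taxonomy",
    "assign_groups",
    "resolve_conversion_group",
    "split_by_group",
]

GROUP_LEVELS = ("activity", "material", "combined", "heuristic")

HEURISTIC_IDS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta")

#: greek symbol -> ascii id, accepted anywhere a heuristic id is taken
GREEK_ALIASES = dict(zip("αβγδεζη", HEURISTIC_IDS))


class NoApplicableGroupError(LookupError):
    """No conversion group can be resolved for an assignment."""


def _norm(code: str) -> str:
    return re.sub(r"\s+", " ", code.strip().lower())


@dataclasses.dataclass(frozen=True)
class GroupAssignment:
    """A pair's position in the group taxonomy.

    ``activity_explicit`` records whether the activity code was found in
    the taxonomy (as opposed to falling back to group 6 "others"); a
    fallback assignment is not specific enough to select the group-6
    conversion function on its own.  The flag does not take part in
    equality.
    """

    activity: int
    material: str  # 'A' | 'B' | 'C' | 'unclassified'
    combined: str | None = None
    heuristic: str | None = None
    activity_explicit: bool = dataclasses.field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.activity not in range(1, 7):
            raise ValueError("activity group must be 1..6")
        if self.material not in {"A", "B", "C", "unclassified"}:
            raise ValueError("material group must be A, B, C or unclassified")
        if self.heuristic is not None and self.heuristic not in HEURISTIC_IDS:
            raise ValueError(f"unknown heuristic group {self.heuristic!r}")


@dataclasses.dataclass(frozen=True)
class HeuristicGroup:
    group_id: str
    name: str
    originating: str
    material: str | None  # required material group, None = any
    activities: frozenset[str]


@dataclasses.dataclass(frozen=True)
class GroupTaxonomy:
    """Loaded taxonomy maps (see the packaged ``data/taxonomy.yaml``)."""

    activity_map: Mapping[str, int]
    material_map: Mapping[str, str]
    combined: frozenset[tuple[int, str]]
    heuristics: Mapping[str, HeuristicGroup]
    activity_names: Mapping[int, str]
    material_names: Mapping[str, str]

    def activity_group(self, code: str) -> tuple[int, bool]:
        """Map a working-activity code to its group; unknown -> (6, False)."""
        group = self.activity_map.get(_norm(code))
        if group is None:
            return 6, False
        return group, True

    def material_group(self, subcategory: str) -> str:
        return self.material_map.get(_norm(subcategory), "unclassified")


def load_taxonomy(path=None) -> GroupTaxonomy:
    """Load the taxonomy from YAML (packaged default if no path given)."""
    if path is None:
        text = (resources.files("dustconv") / "data" / "taxonomy.yaml").read_text(
            encoding="utf-8"
        )
        raw = yaml.safe_load(text)
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)

    activity_map: dict[str, int] = {}
    activity_names: dict[int, str] = {}
    for gid, spec in raw["activity_groups"].items():
        gid = int(gid)
        activity_names[gid] = spec["name"]
        for code in spec.get("activities") or []:
            activity_map[_norm(code)] = gid

    material_map: dict[str, str] = {}
    material_names: dict[str, str] = {}
    for gid, spec in raw["material_groups"].items():
        material_names[gid] = spec["name"]
        for sub in spec["subcategories"]:
            material_map[_norm(sub)] = gid

    combined = frozenset(
        (int(label.split("-")[0]), label.split("-")[1])
        for label in raw["combined_groups"]
    )

    heuristics: dict[str, HeuristicGroup] = {}
    for hid, spec in raw["heuristic_groups"].items():
        material = spec["material"]
        group = HeuristicGroup(
            group_id=hid,
            name=spec["name"],
            originating=str(spec["originating"]),
            material=None if material == "any" else material,
            activities=frozenset(_norm(a) for a in spec["activities"]),
        )
        heuristics[hid] = group
        # heuristic codes inherit the activity group they originate from
        parent_activity = int(group.originating.split("-")[0])
        for code in group.activities:
            activity_map.setdefault(code, parent_activity)
    return GroupTaxonomy(
        activity_map=activity_map,
        material_map=material_map,
        combined=combined,
        heuristics=heuristics,
        activity_names=activity_names,
        material_names=material_names,
    )


def assign_groups(
    pair: MeasurementPair | DustMeasurement, taxonomy: GroupTaxonomy
) -> GroupAssignment:
    """Assign a pair (or single record) to all four taxonomy levels.

    Unknown activity codes fall back to activity group 6 ("others");
    unknown material subcategories become "unclassified" and never carry
    a combined or heuristic label.
    """
    rec = pair.inhalable if isinstance(pair, MeasurementPair) else pair
    code = _norm(rec.working_activity)
    activity, explicit = taxonomy.activity_group(code)
    material = taxonomy.material_group(rec.material_category)

    combined = None
    if (activity, material) in taxonomy.combined:
        combined = f"{activity}-{material}"

    heuristic = None
    for hid, group in taxonomy.heuristics.items():
        if code in group.activities and (
            group.material is None or group.material == material
        ):
            heuristic = hid
            break
    return GroupAssignment(
        activity=activity,
        material=material,
        combined=combined,
        heuristic=heuristic,
        activity_explicit=explicit,
    )


def resolve_conversion_group(
    assignment: GroupAssignment, allow_whole_dataset: bool = False
) -> str:
    """Return the most specific conversion group for an assignment.

    Priority: heuristic, then combined, then activity (for codes the
    taxonomy knows), then material.  The whole-dataset function ("0") is
    only returned when ``allow_whole_dataset`` is set — with a warning,
    since one of the specific groups should almost always fit better.
    """
    if assignment.heuristic is not None:
        return assignment.heuristic
    if assignment.combined is not None:
        return assignment.combined
    if assignment.activity_explicit:
        return str(assignment.activity)
    if assignment.material != "unclassified":
        return assignment.material
    if allow_whole_dataset:
        warnings.warn(
            "falling back to the whole-dataset conversion function; "
            "using a specific group is strongly preferred",
            stacklevel=2,
        )
        return "0"
    raise NoApplicableGroupError(
        "no applicable group: activity unknown and material unclassified"
    )


def split_by_group(
    pairs: Sequence[MeasurementPair],
    level: str,
    taxonomy: GroupTaxonomy | None = None,
) -> dict[object, list[MeasurementPair]]:
    """Partition pairs by group label at one taxonomy level.

    Pairs must already carry a :class:`GroupAssignment` (or a taxonomy
    must be given, in which case assignments are computed on the fly).
    At the ``activity`` and ``material`` levels every pair lands in a
    bin; at the ``combined`` and ``heuristic`` levels pairs without a
    label are omitted, so the bins are disjoint but not exhaustive.
    """
    if level not in GROUP_LEVELS:
        raise ValueError(f"level must be one of {GROUP_LEVELS}")
    out: dict[object, list[MeasurementPair]] = {}
    for pair in pairs:
        group = pair.group
        if group is None:
            if taxonomy is None:
                raise ValueError("pair has no group assignment and no taxonomy given")
            group = assign_groups(pair, taxonomy)
            pair.group = group
        label = getattr(group, level)
        if label is None:
            continue
        out.setdefault(label, []).append(pair)
    return out
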