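"""Published conversion functions and their application.

A conversion function estimates a respirable dust concentration from an
inhalable one through the back-transformed log-log regression,

    c_R = c_I**k · exp(C0),        (k in (0, 1], C0 < 0)

for a specific working-condition group.  The packaged registry carries
the published coefficients for the whole dataset (group "0"), the six
working-activity groups, the three material groups, the four combined
groups and the seven heuristic groups — 21 entries, protected by a
transcription checksum.

These functions were derived from parallel measurements in German
industry between 1998 and 2016; outside comparable working conditions
and concentration ranges they are extrapolations.  Because the exponent
k is below 1, the ratio c_R/c_I declines with increasing c_I, and at
sufficiently small c_I the power law crosses the identity line
(predicting the unphysical c_R > c_I).  Each function therefore carries
a validity range whose lower bound is never below that crossing point;
queries outside it emit a warning but are still computed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from importlib import resources
from typing import Mapping

import yaml
from scipy import stats

from .grouping import GREEK_ALIASES
from .regression import RegressionResult

__all__ = [
    "ConversionFunction",
    "ConversionRegistry",
    "ConversionResult",
    "RegistryCorruptedError",
    "ValidityWarning",
    "convert",
    "ratio",
    "inverse_ratio",
    "inhalable_convention",
    "load_registry",
]


class RegistryCorruptedError(RuntimeError):
    """The registry file does not match its transcription checksum."""


class ValidityWarning(UserWarning):
    """A query lies outside a conversion function's validity range."""


def _identity_crossing(k: float, C0: float) -> float:
    """c_I below which the power law predicts c_R > c_I (0 if never)."""
    if k >= 1.0:
        return 0.0
    return math.exp(C0 / (1.0 - k))


@dataclasses.dataclass(frozen=True)
class ConversionFunction:
    """One conversion-function registry entry (published or fitted).

    Published entries only carry the s_Fit range, so their intervals are
    minimum-width approximations; entries built from a fresh fit via
    :meth:`from_regression` also know the design summaries (x_mean, Sxx,
    s_resid) and yield exact bands.
    """

    group_id: str
    name: str
    k: float
    C0: float
    se_k: float | None = None
    se_C0: float | None = None
    n: int | None = None
    s_fit_min: float | None = None
    s_fit_max: float | None = None
    x_mean: float | None = None
    Sxx: float | None = None
    s_resid: float | None = None
    validity: tuple[float, float] = (0.01, 100.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.k <= 1.0:
            raise ValueError("exponent k must be in (0, 1]")
        lo = max(self.validity[0], _identity_crossing(self.k, self.C0))
        if lo > self.validity[0]:
            object.__setattr__(self, "validity", (lo, self.validity[1]))
        if self.validity[0] >= self.validity[1]:
            raise ValueError("empty validity range")

    @classmethod
    def from_regression(
        cls, result: RegressionResult, name: str = ""
    ) -> "ConversionFunction":
        return cls(
            group_id=str(result.group_id),
            name=name,
            k=result.k,
            C0=result.C0,
            se_k=result.se_k,
            se_C0=result.se_C0,
            n=result.n,
            s_fit_min=result.s_fit_min,
            s_fit_max=result.s_fit_max,
            x_mean=result.x_mean,
            Sxx=result.Sxx,
            s_resid=result.s_resid,
        )


@dataclasses.dataclass(frozen=True)
class ConversionResult:
    """Point estimate and interval for one conversion query (mg m⁻³).

    ``approximate`` flags minimum-width intervals computed from a
    published entry's smallest s_Fit instead of the full design
    summaries; the true interval is at least this wide.
    """

    cr_point: float
    cr_lower: float
    cr_upper: float
    approximate: bool


@dataclasses.dataclass(frozen=True)
class ConversionRegistry:
    """The published conversion functions, keyed by group id."""

    entries: Mapping[str, ConversionFunction]
    version: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, group_id: str) -> ConversionFunction:
        key = GREEK_ALIASES.get(str(group_id), str(group_id))
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(f"no conversion function for group {group_id!r}") from None


def _check_validity(ci: float, fn: ConversionFunction) -> None:
    if ci <= 0:
        raise ValueError("c_I must be positive")
    lo, hi = fn.validity
    if not lo <= ci <= hi:
        warnings.warn(
            f"c_I = {ci:g} mg/m3 outside the validity range "
            f"[{lo:.3g}, {hi:.3g}] of group {fn.group_id}; result is an "
            "extrapolation",
            ValidityWarning,
            stacklevel=3,
        )


def convert(
    ci: float, fn: ConversionFunction, level: float = 0.95
) -> ConversionResult:
    """Estimate the respirable concentration for an inhalable one.

    The point estimate is ``ci**k · exp(C0)``; the interval exponentiates
    the log-space confidence band of the regression mean.  For published
    entries without design summaries the band uses the smallest s_Fit
    and is flagged approximate.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be inside (0, 1)")
    _check_validity(ci, fn)
    ln_ci = math.log(ci)
    center = fn.k * ln_ci + fn.C0
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    approximate = True
    if fn.s_resid is not None and fn.x_mean is not None and fn.Sxx and fn.n:
        s = fn.s_resid * math.sqrt(1.0 / fn.n + (ln_ci - fn.x_mean) ** 2 / fn.Sxx)
        approximate = False
    elif fn.s_fit_min is not None:
        s = fn.s_fit_min
    else:
        s = 0.0
    half = z * s
    return ConversionResult(
        cr_point=math.exp(center),
        cr_lower=math.exp(center - half),
        cr_upper=math.exp(center + half),
        approximate=approximate,
    )


def ratio(ci: float, fn: ConversionFunction) -> float:
    """Predicted ratio c_R/c_I at ``ci``: ``ci**(k−1) · exp(C0)``.

    Strictly decreasing in ``ci`` whenever k < 1.
    """
    _check_validity(ci, fn)
    return ci ** (fn.k - 1.0) * math.exp(fn.C0)


def inverse_ratio(target_ratio: float, fn: ConversionFunction) -> float:
    """Inhalable concentration at which the ratio c_R/c_I equals a target.

    Closed-form inversion ``ci = exp[(ln r − C0)/(k − 1)]``; unique
    because the ratio is strictly monotone for k < 1.
    """
    if fn.k == 1.0:
        raise ValueError("ratio is constant for k = 1, no inverse exists")
    if not 0.0 < target_ratio < 1.0:
        raise ValueError("target ratio must be inside (0, 1)")
    return math.exp((math.log(target_ratio) - fn.C0) / (fn.k - 1.0))


def inhalable_convention(D: float) -> float:
    """Inhalable-fraction sampling convention, in percent.

    ``I(D) = 50·(1 + exp(−0.06·D))`` for aerodynamic diameter D in µm,
    defined for 0 ≤ D ≤ 100; decreases monotonically from 100% toward
    50%.
    """
    if not 0.0 <= D <= 100.0:
        raise ValueError("convention defined for 0 <= D <= 100 µm")
    return 50.0 * (1.0 + math.exp(-0.06 * D))


def _canonical_digest(raw_entries: list[dict]) -> str:
    payload = json.dumps(raw_entries, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def load_registry(path=None) -> ConversionRegistry:
    """Load the conversion-function registry (packaged default).

    The file stores a SHA-256 digest of its canonical entry
    serialisation; a mismatch (e.g. a silently edited coefficient)
    raises :class:`RegistryCorruptedError`.
    """
    if path is None:
        text = (resources.files("dustconv") / "data" / "registry.yaml").read_text(
            encoding="utf-8"
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    digest = _canonical_digest(raw["entries"])
    if digest != raw["sha256"]:
        raise RegistryCorruptedError(
            f"registry corrupted: checksum {digest} != recorded {raw['sha256']}"
        )
    entries: dict[str, ConversionFunction] = {}
    for spec in raw["entries"]:
        gid = str(spec["id"])
        entries[gid] = ConversionFunction(
            group_id=gid,
            name=spec["name"],
            k=float(spec["k"]),
            C0=float(spec["C0"]),
            se_k=float(spec["se_k"]),
            se_C0=float(spec["se_C0"]),
            n=int(spec["n"]),
            s_fit_min=float(spec["s_fit_min"]),
            s_fit_max=float(spec["s_fit_max"]),
        )
    if len(entries) != len(raw["entries"]):
        raise RegistryCorruptedError("duplicate group ids in registry")
    return ConversionRegistry(entries=entries, version=str(raw.get("version", "")))
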