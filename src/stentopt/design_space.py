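"""Factor definitions, coded/natural transforms, and shared record types.

The stent design space has five geometric factors: strut width ``w`` [µm],
strut thickness ``t`` [µm], number of struts ``NS`` [count], link amplitude
``LA`` [mm], and strut amplitude ``SA`` [mm].  Every factor is varied over
three levels (lower bound, mid value, upper bound) and the three-level grid
is always symmetric about the mid value, so the usual DOE coding

    coded = (x - mid) / (upper - mid)

maps the natural box onto ``[-1, +1]^k`` bijectively.

Internal units are fixed as above (µm for w/t, mm for LA/SA); unit
conversion happens only at I/O boundaries so that fitted polynomial
coefficients are directly comparable across the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Factor",
    "FactorSpace",
    "StentDesign",
    "ResponseSet",
    "RESPONSES",
    "ResponseMeta",
    "TABLE1_SPACE",
    "DOE2_SPACE",
    "SPACE_PRESETS",
    "load_factor_space",
]

FACTOR_NAMES = ("w", "t", "NS", "LA", "SA")

#: Fixed geometric constants shared by every design (not DOE factors).
OUTER_DIAMETER_MM = 8.0
N_RINGS = 7
N_LINK_SETS = 6
LINK_LENGTH_MM = math.pi / 2

_SYMMETRY_RTOL = 1e-9


class BoundsError(ValueError):
    """A design coordinate fell outside its factor's bounds."""


@dataclass(frozen=True)
class Factor:
    """One DOE factor with its three symmetric levels."""

    name: str
    lower: float
    mid: float
    upper: float
    unit: str

    def __post_init__(self) -> None:
        if not (self.lower < self.mid < self.upper):
            raise ValueError(
                f"factor {self.name!r}: levels must satisfy lower < mid < upper, "
                f"got ({self.lower}, {self.mid}, {self.upper})"
            )
        lo, hi = self.mid - self.lower, self.upper - self.mid
        if not math.isclose(lo, hi, rel_tol=_SYMMETRY_RTOL, abs_tol=1e-12):
            raise ValueError(
                f"factor {self.name!r}: asymmetric level spacing "
                f"(mid-lower={lo}, upper-mid={hi}) is not supported"
            )

    @property
    def half_range(self) -> float:
        return self.upper - self.mid

    @property
    def range(self) -> float:
        return self.upper - self.lower

    def code(self, x: float) -> float:
        if not (self.lower - 1e-12 <= x <= self.upper + 1e-12):
            raise BoundsError(
                f"factor {self.name!r}: value {x} outside [{self.lower}, {self.upper}]"
            )
        return (x - self.mid) / self.half_range

    def decode(self, c: float) -> float:
        if not (-1 - 1e-12 <= c <= 1 + 1e-12):
            raise BoundsError(f"factor {self.name!r}: coded value {c} outside [-1, 1]")
        return float(self.mid + c * self.half_range)


@dataclass(frozen=True)
class FactorSpace:
    """An ordered collection of factors defining the design box."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate factor names: {names}")
        unknown = set(names) - set(FACTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown factor names {sorted(unknown)}; expected subset of {FACTOR_NAMES}")

    def __iter__(self):
        return iter(self.factors)

    def __len__(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def __getitem__(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def midpoint_design(self, **fixed: float) -> "StentDesign":
        vals = {f.name: f.mid for f in self.factors}
        vals.update(fixed)
        return StentDesign(**vals)

    def contains(self, design: "StentDesign") -> bool:
        try:
            self.to_coded(design)
        except BoundsError:
            return False
        return True

    def to_coded(self, design: "StentDesign | Mapping[str, float]") -> np.ndarray:
        """Map a design (or name->value mapping) to coded units in [-1, 1]^k."""
        get = design.get if isinstance(design, Mapping) else lambda n: getattr(design, n)
        return np.array([f.code(get(f.name)) for f in self.factors], dtype=float)

    def to_natural(self, coded: Sequence[float], **fixed: float) -> "StentDesign":
        """Inverse of :meth:`to_coded`.

        Factors absent from this space (e.g. NS and LA in a three-factor
        space) may be supplied through ``fixed``; otherwise they default to
        the values of :class:`StentDesign`.
        """
        coded = np.asarray(coded, dtype=float)
        if coded.shape != (len(self.factors),):
            raise ValueError(f"expected {len(self.factors)} coded values, got {coded.shape}")
        vals = {f.name: f.decode(c) for f, c in zip(self.factors, coded)}
        vals.update({k: v for k, v in fixed.items() if k not in vals})
        return StentDesign(**vals)

    def to_natural_array(self, coded: np.ndarray) -> np.ndarray:
        """Vectorized decode of an (n, k) coded array (no bounds checks)."""
        coded = np.asarray(coded, dtype=float)
        mids = np.array([f.mid for f in self.factors])
        halves = np.array([f.half_range for f in self.factors])
        return mids + coded * halves


@dataclass(frozen=True)
class StentDesign:
    """One point in the design space plus the fixed geometric constants.

    NS may be non-integer inside continuous optimization; geometry
    generation additionally requires it to be a positive even integer so
    that sine peaks pair up around the circumference.
    """

    w: float  # strut width [µm]
    t: float  # strut thickness [µm]
    NS: float = 16.0  # number of struts [count]
    LA: float = 0.4  # link amplitude [mm]
    SA: float = 0.5  # strut amplitude [mm]
    outer_diameter: float = OUTER_DIAMETER_MM  # [mm]
    n_rings: int = N_RINGS
    n_link_sets: int = N_LINK_SETS
    link_length: float = LINK_LENGTH_MM  # [mm]

    def as_dict(self) -> dict[str, float]:
        return {"w": self.w, "t": self.t, "NS": self.NS, "LA": self.LA, "SA": self.SA}

    def get(self, name: str) -> float:
        return self.as_dict()[name]

    def validate_for_geometry(self) -> None:
        ns = self.NS
        if not (ns > 0 and float(ns).is_integer() and int(ns) % 2 == 0):
            raise ValueError(f"NS={ns} must be a positive even integer for geometry generation")

    def with_values(self, **kwargs: float) -> "StentDesign":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ResponseMeta:
    """Metadata for one FEA-derived outcome."""

    key: str          # attribute name on ResponseSet
    column: str       # canonical CSV column
    unit: str
    goal: str         # 'STB' (smaller the better) or 'LTB' (larger the better)
    label: str


#: The four stent-artery interaction outcomes, in canonical order.
RESPONSES: tuple[ResponseMeta, ...] = (
    ResponseMeta("mean_stress", "mean_stress_kPa", "kPa", "STB", "mean intramural stress"),
    ResponseMeta("high_stress_area", "high_stress_pct", "%", "STB", "luminal area with stress > 100 kPa"),
    ResponseMeta("apposition", "apposition_pct", "%", "LTB", "stent-artery apposition"),
    ResponseMeta("pinching", "pinching", "", "STB", "lumen pinching ratio"),
)

RESPONSE_COLUMNS = tuple(r.column for r in RESPONSES)


@dataclass(frozen=True)
class ResponseSet:
    """The four outcomes for one design; validated on construction."""

    mean_stress: float       # [kPa], >= 0
    high_stress_area: float  # [% of luminal area], in [0, 100]
    apposition: float        # [% of strut area], in [0, 100]
    pinching: float          # max/min lumen diameter, >= 1

    def __post_init__(self) -> None:
        if not np.isfinite([self.mean_stress, self.high_stress_area, self.apposition, self.pinching]).all():
            raise ValueError("non-finite response value")
        if self.mean_stress < 0:
            raise ValueError(f"mean_stress={self.mean_stress} must be >= 0")
        if not 0 <= self.high_stress_area <= 100:
            raise ValueError(f"high_stress_area={self.high_stress_area} outside [0, 100]")
        if not 0 <= self.apposition <= 100:
            raise ValueError(f"apposition={self.apposition} outside [0, 100]")
        if self.pinching < 1.0:
            raise ValueError(f"pinching={self.pinching} must be >= 1 (1.0 = circular lumen)")

    def as_dict(self) -> dict[str, float]:
        return {m.key: getattr(self, m.key) for m in RESPONSES}


def _space(*rows: tuple[str, float, float, float, str]) -> FactorSpace:
    return FactorSpace(tuple(Factor(*r) for r in rows))


#: First-DOE design space (five factors, levels from commercial stents).
TABLE1_SPACE = _space(
    ("w", 100.0, 175.0, 250.0, "µm"),
    ("t", 100.0, 175.0, 250.0, "µm"),
    ("NS", 16.0, 24.0, 32.0, "count"),
    ("LA", 0.0, 0.4, 0.8, "mm"),
    ("SA", 0.50, 1.25, 2.00, "mm"),
)

#: Second-DOE design space (w, t, SA refined downward; NS=16 and LA=0.4 fixed).
DOE2_SPACE = _space(
    ("w", 50.0, 100.0, 150.0, "µm"),
    ("t", 50.0, 100.0, 150.0, "µm"),
    ("SA", 0.3, 0.5, 0.7, "mm"),
)

SPACE_PRESETS: dict[str, FactorSpace] = {"table1": TABLE1_SPACE, "doe2": DOE2_SPACE}

#: Factors held constant in the second DOE, taken over from the first-DOE optimum
#: (LA was set to 0.4 there; see the packaged fixture docs).
DOE2_FIXED = {"NS": 16.0, "LA": 0.4}


def load_factor_space(source: str | Path) -> FactorSpace:
    """Load a factor space from a preset name or a YAML/JSON file.

    The file maps to a list of records with keys name/lower/mid/upper/unit.
    """
    if isinstance(source, str) and source in SPACE_PRESETS:
        return SPACE_PRESETS[source]
    path = Path(source)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        records = yaml.safe_load(text)
    else:
        records = json.loads(text)
    if isinstance(records, Mapping) and "factors" in records:
        records = records["factors"]
    factors = tuple(
        Factor(r["name"], float(r["lower"]), float(r["mid"]), float(r["upper"]), r.get("unit", ""))
        for r in records
    )
    return FactorSpace(factors)
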