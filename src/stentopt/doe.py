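"""Face-centered central composite designs and the packaged DOE tables.

A face-centered CCD over k three-level factors consists of the full 2^k
factorial at the box corners, 2k axial points on the box faces (one factor
at ±1, the rest at 0), and a single center point: 2^k + 2k + 1 runs.  With
k = 5 this gives the 43-run first DOE; with k = 3 the 15-run second DOE.

The two response matrices printed by the study are shipped as CSV fixtures
(``table4_doe1.csv``, ``table5_doe2.csv``) and loaded with full validation
against their factor spaces.  Note the first-DOE fixture contains two rows
at near-center settings (runs 17 and 29, differing only in LA) with
different responses; both are kept exactly as printed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .design_space import (
    DOE2_FIXED,
    DOE2_SPACE,
    RESPONSES,
    RESPONSE_COLUMNS,
    FactorSpace,
    ResponseSet,
    StentDesign,
    TABLE1_SPACE,
)

__all__ = [
    "DOEPlan",
    "DOETable",
    "generate_ccd",
    "load_doe_table",
    "save_doe_table",
    "load_table4",
    "load_table5",
    "factor_orthogonality",
    "FACTOR_COLUMNS",
]

#: canonical CSV column per factor name
FACTOR_COLUMNS = {"w": "w_um", "t": "t_um", "NS": "NS", "LA": "LA_mm", "SA": "SA_mm"}


class DesignError(ValueError):
    pass


class TableError(ValueError):
    pass


@dataclass(frozen=True)
class DOEPlan:
    """An ordered face-centered CCD over a factor space."""

    space: FactorSpace
    coded: np.ndarray          # (n, k) with entries in {-1, 0, +1}
    families: tuple[str, ...]  # 'factorial' | 'axial' | 'center' per run

    @property
    def k(self) -> int:
        return len(self.space)

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def run_ids(self) -> np.ndarray:
        return np.arange(1, self.n_runs + 1)

    def designs(self, **fixed: float) -> list[StentDesign]:
        return [self.space.to_natural(row, **fixed) for row in self.coded]

    def to_frame(self, **fixed: float) -> pd.DataFrame:
        natural = self.space.to_natural_array(self.coded)
        data = {"run": self.run_ids}
        for j, name in enumerate(self.space.names):
            data[FACTOR_COLUMNS[name]] = natural[:, j]
        df = pd.DataFrame(data)
        df["family"] = list(self.families)
        return df


def generate_ccd(space: FactorSpace) -> DOEPlan:
    """Face-centered CCD: 2^k factorial core, 2k face points, one center.

    Run ordering is canonical and deterministic: factorial corners in
    binary order (first factor slowest, -1 before +1), then axial pairs in
    factor order (-1 before +1), then the center run.
    """
    k = len(space)
    if k < 2:
        raise DesignError(f"CCD needs at least 2 factors, got {k}")
    corners = np.array(
        [[-1.0 if (i >> (k - 1 - j)) & 1 == 0 else 1.0 for j in range(k)] for i in range(2**k)]
    )
    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -1.0
        axial[2 * j + 1, j] = 1.0
    center = np.zeros((1, k))
    coded = np.vstack([corners, axial, center])
    families = ("factorial",) * len(corners) + ("axial",) * len(axial) + ("center",)
    return DOEPlan(space=space, coded=coded, families=families)


@dataclass(frozen=True)
class DOETable:
    """Validated join of design points with their four responses."""

    space: FactorSpace
    frame: pd.DataFrame  # columns: run, factor columns, response columns

    @property
    def n_runs(self) -> int:
        return len(self.frame)

    @property
    def factor_columns(self) -> list[str]:
        return [FACTOR_COLUMNS[n] for n in self.space.names]

    def coded(self) -> np.ndarray:
        mids = np.array([f.mid for f in self.space])
        halves = np.array([f.half_range for f in self.space])
        return (self.frame[self.factor_columns].to_numpy(dtype=float) - mids) / halves

    def response(self, key_or_column: str) -> np.ndarray:
        col = key_or_column
        for m in RESPONSES:
            if key_or_column == m.key:
                col = m.column
        return self.frame[col].to_numpy(dtype=float)

    def designs(self, **fixed: float) -> list[StentDesign]:
        out = []
        for _, row in self.frame.iterrows():
            vals = {n: float(row[FACTOR_COLUMNS[n]]) for n in self.space.names}
            vals.update({k: v for k, v in fixed.items() if k not in vals})
            out.append(StentDesign(**vals))
        return out


def _validate_table(df: pd.DataFrame, space: FactorSpace, *, check_levels: bool) -> None:
    expected = ["run"] + [FACTOR_COLUMNS[n] for n in space.names] + list(RESPONSE_COLUMNS)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise TableError(f"missing columns: {missing}")
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based with header
        for name in space.names:
            val = float(row[FACTOR_COLUMNS[name]])
            f = space[name]
            if check_levels:
                levels = (f.lower, f.mid, f.upper)
                if not any(np.isclose(val, lv, rtol=1e-9, atol=1e-12) for lv in levels):
                    raise TableError(
                        f"row {rownum}: factor {name}={val} is not one of the levels {levels}"
                    )
        try:
            ResponseSet(
                mean_stress=float(row["mean_stress_kPa"]),
                high_stress_area=float(row["high_stress_pct"]),
                apposition=float(row["apposition_pct"]),
                pinching=float(row["pinching"]),
            )
        except ValueError as exc:
            raise TableError(f"row {rownum}: {exc}") from exc


def load_doe_table(
    path_or_buffer, space: FactorSpace, *, check_levels: bool = True
) -> DOETable:
    """Load and validate a DOE response table from CSV."""
    try:
        df = pd.read_csv(path_or_buffer)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableError(f"cannot parse CSV: {exc}") from exc
    _validate_table(df, space, check_levels=check_levels)
    keep = ["run"] + [FACTOR_COLUMNS[n] for n in space.names] + list(RESPONSE_COLUMNS)
    return DOETable(space=space, frame=df[keep].copy())


def save_doe_table(table: DOETable, path) -> None:
    """Serialize with canonical column order and minimal decimal formatting.

    The format is idempotent: saving a loaded copy of a saved table
    reproduces the bytes.
    """
    df = table.frame
    cols = ["run"] + table.factor_columns + list(RESPONSE_COLUMNS)
    lines = [",".join(cols)]
    for _, row in df.iterrows():
        cells = [str(int(row["run"]))]
        for c in cols[1:]:
            cells.append(f"{float(row[c]):.12g}")
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def _load_fixture(name: str, space: FactorSpace) -> DOETable:
    text = resources.files("stentopt.data").joinpath(name).read_text()
    return load_doe_table(io.StringIO(text), space)


def load_table4() -> DOETable:
    """The packaged 43-run first-DOE response matrix (five factors)."""
    return _load_fixture("table4_doe1.csv", TABLE1_SPACE)


def load_table5() -> DOETable:
    """The packaged 15-run second-DOE response matrix (w, t, SA)."""
    return _load_fixture("table5_doe2.csv", DOE2_SPACE)


def factor_orthogonality(source: "DOEPlan | DOETable") -> pd.DataFrame:
    """Pairwise Pearson correlations between coded factor columns.

    A constant column has undefined correlation; it is reported as NaN and
    flagged with a warning rather than silently zeroed.
    """
    import warnings

    coded = source.coded if isinstance(source, DOEPlan) else source.coded()
    coded = np.asarray(coded, dtype=float)
    if coded.shape[0] < 3:
        raise DesignError("need at least 3 runs to assess orthogonality")
    names = source.space.names
    k = coded.shape[1]
    out = np.eye(k)
    sd = coded.std(axis=0)
    for j, name in enumerate(names):
        if sd[j] == 0:
            warnings.warn(f"factor {name!r} is constant; correlations undefined (NaN)")
    for a in range(k):
        for b in range(a + 1, k):
            if sd[a] == 0 or sd[b] == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(coded[:, a], coded[:, b])[0, 1])
            out[a, b] = out[b, a] = r
    return pd.DataFrame(out, index=list(names), columns=list(names))
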