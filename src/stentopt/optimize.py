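"""Desirability-based multi-response optimization and sensitivity analysis.

Each predicted response ŷ_j is mapped to a desirability d_j ∈ [0, 1] by a
piecewise-linear ramp — larger-the-better (LTB) for apposition,
smaller-the-better (STB) for mean stress, high-stress area, and pinching —
and the composite desirability D = Π d_j (equal weights) is maximized over
the coded design box by a dense grid search followed by a local polish.

The ramp anchors y_min/y_max default to the min/max of each model's
predictions over the box, which makes the desirabilities self-contained
functions of the fitted models; observed-table ranges or explicit targets
can be supplied instead.

Sensitivity contributions follow the midpoint-derivative convention:
∂y/∂x_i evaluated at the all-midpoint design, normalized by the factor
range, and expressed as a percentage of the total across factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sopt

from .design_space import RESPONSES, FactorSpace, StentDesign
from .rsm import QuadraticModel

__all__ = [
    "ResponseGoal",
    "DesirabilitySpec",
    "DesirabilityResult",
    "SensitivityReport",
    "desirability",
    "composite",
    "predicted_ranges",
    "default_spec",
    "optimize_designs",
    "sensitivity_contributions",
]

GOALS = {m.key: m.goal for m in RESPONSES}


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class ResponseGoal:
    """Direction and ramp anchors for one response."""

    direction: str  # 'STB' | 'LTB'
    y_min: float
    y_max: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("STB", "LTB"):
            raise SpecError(f"direction must be STB or LTB, got {self.direction!r}")
        if not self.y_min < self.y_max:
            raise SpecError(f"need y_min < y_max, got [{self.y_min}, {self.y_max}]")
        if self.weight <= 0:
            raise SpecError("weights must be > 0")


DesirabilitySpec = dict[str, ResponseGoal]


def desirability(value, goal: ResponseGoal):
    """Piecewise-linear desirability of predicted value(s) under a goal.

    LTB: 0 at/below y_min, linear ramp, 1 at/above y_max; STB mirrored.
    """
    y = np.asarray(value, dtype=float)
    ramp = (y - goal.y_min) / (goal.y_max - goal.y_min)
    d = np.clip(ramp if goal.direction == "LTB" else 1.0 - ramp, 0.0, 1.0)
    return float(d) if np.isscalar(value) else d


def composite(ds: Sequence[float] | np.ndarray, weights: Sequence[float] | None = None):
    """Composite desirability: plain product for equal weights, otherwise a
    weighted geometric mean (Π d^w)^(1/Σw)."""
    arr = np.asarray(ds, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise SpecError("desirabilities must lie in [0, 1]")
    if weights is None or len(set(map(float, weights))) == 1:
        return arr.prod(axis=0)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise SpecError("weights must be > 0")
    with np.errstate(divide="ignore"):
        logd = np.where(arr > 0, np.log(np.where(arr > 0, arr, 1.0)), -np.inf)
    out = np.exp(np.tensordot(w, logd, axes=1) / w.sum())
    return np.where(np.any(arr == 0, axis=0), 0.0, out)


def _coded_mesh(space: FactorSpace, grid: int) -> dict[str, np.ndarray]:
    axes = [np.linspace(-1.0, 1.0, grid) for _ in space.names]
    mesh = np.meshgrid(*axes, indexing="ij")
    return {n: m.ravel() for n, m in zip(space.names, mesh)}


def predicted_ranges(
    models: Mapping[str, QuadraticModel], space: FactorSpace, grid: int = 21
) -> dict[str, tuple[float, float]]:
    """Min/max model prediction per response over the coded grid."""
    mesh = _coded_mesh(space, grid)
    out = {}
    for key, model in models.items():
        pred = model.predict_coded_grid(mesh)
        out[key] = (float(pred.min()), float(pred.max()))
    return out


def default_spec(
    models: Mapping[str, QuadraticModel],
    space: FactorSpace,
    *,
    range_mode: str = "predicted",
    observed: Mapping[str, np.ndarray] | None = None,
    explicit: Mapping[str, tuple[float, float]] | None = None,
    grid: int = 21,
) -> DesirabilitySpec:
    """Build the four-response desirability spec with equal weights."""
    if range_mode == "predicted":
        ranges = predicted_ranges(models, space, grid)
    elif range_mode == "observed":
        if observed is None:
            raise SpecError("observed range mode needs response arrays")
        ranges = {k: (float(np.min(v)), float(np.max(v))) for k, v in observed.items()}
    elif range_mode == "explicit":
        if explicit is None:
            raise SpecError("explicit range mode needs (y_min, y_max) per response")
        ranges = dict(explicit)
    else:
        raise SpecError(f"unknown range mode {range_mode!r}")
    return {
        key: ResponseGoal(GOALS[key], *ranges[key]) for key in models
    }


@dataclass
class DesirabilityResult:
    design: StentDesign
    coded: np.ndarray
    per_response_d: dict[str, float]
    composite_d: float
    predicted: dict[str, float]
    trace: dict = field(default_factory=dict)


def _evaluate(
    models: Mapping[str, QuadraticModel],
    spec: DesirabilitySpec,
    coded_values: dict[str, np.ndarray],
):
    preds = {k: m.predict_coded_grid(coded_values) for k, m in models.items()}
    ds = np.stack([desirability(preds[k], spec[k]) for k in models])
    weights = [spec[k].weight for k in models]
    D = composite(ds, weights)
    return preds, ds, D


def optimize_designs(
    models: Mapping[str, QuadraticModel],
    space: FactorSpace,
    spec: DesirabilitySpec | None = None,
    *,
    range_mode: str = "predicted",
    grid: int = 21,
    polish: bool = True,
    fixed: Mapping[str, float] | None = None,
) -> DesirabilityResult:
    """Maximize composite desirability over the design box.

    Dense coded grid (``grid`` points per axis) locates the best cell;
    a bounded Powell search then polishes the continuous optimum.  Ties on
    the grid resolve to the first (lowest-index) cell, and axes along which
    D is constant are detected and reported in the trace — the optimum
    coordinate on such an axis is not informative.  NS, if present, is
    rounded to the nearest even integer in the reported design, with D
    re-evaluated at the rounded point.
    """
    if spec is None:
        spec = default_spec(models, space, range_mode=range_mode, grid=grid)
    names = space.names
    k = len(names)
    mesh = _coded_mesh(space, grid)
    _, _, D = _evaluate(models, spec, mesh)
    if np.all(D == 0):
        _, ds0, _ = _evaluate(models, spec, {n: np.zeros(1) for n in names})
        collapsed = [key for key, d in zip(models, ds0[:, 0]) if d == 0]
        import warnings

        warnings.warn(
            f"composite desirability is zero everywhere; collapsing responses: {collapsed}"
        )
    shape = (grid,) * k
    Dg = D.reshape(shape)
    best_idx = np.unravel_index(int(np.argmax(Dg)), shape)
    axes_1d = np.linspace(-1.0, 1.0, grid)
    best = np.array([axes_1d[i] for i in best_idx])

    flat_axes = []
    for j in range(k):
        sl = list(best_idx)
        sl[j] = slice(None)
        line = Dg[tuple(sl)]
        if float(line.max() - line.min()) < 1e-12:
            flat_axes.append(names[j])

    n_eval = D.size
    if polish:
        def neg_d(x):
            vals = {n: np.atleast_1d(x[j]) for j, n in enumerate(names)}
            _, _, d = _evaluate(models, spec, vals)
            return -float(np.asarray(d).ravel()[0])

        res = sopt.minimize(
            neg_d, best, method="Powell", bounds=[(-1.0, 1.0)] * k,
            options={"xtol": 1e-8, "ftol": 1e-10},
        )
        # keep the polished point only if it genuinely improves on the grid cell
        if -res.fun >= Dg[best_idx] - 1e-15:
            best = np.clip(res.x, -1.0, 1.0)
        n_eval += int(res.nfev)
        # a flat axis is left at its grid value, not where Powell drifted
        for j, n in enumerate(names):
            if n in flat_axes:
                best[j] = axes_1d[best_idx[j]]

    fixed = dict(fixed or {})
    design = space.to_natural(best, **fixed)
    if "NS" in names:
        ns_even = 2 * round(design.NS / 2)
        design = design.with_values(NS=float(ns_even))
        best = space.to_coded(design)
    vals = {n: np.atleast_1d(c) for n, c in zip(names, best)}
    preds, ds, Dfin = _evaluate(models, spec, vals)
    return DesirabilityResult(
        design=design,
        coded=best,
        per_response_d={key: float(d) for key, d in zip(models, ds[:, 0])},
        composite_d=float(Dfin[0]),
        predicted={key: float(v[0]) for key, v in preds.items()},
        trace={
            "method": "grid+powell" if polish else "grid",
            "grid": grid,
            "n_evaluations": n_eval,
            "flat_axes": flat_axes,
            "ranges": {key: (g.y_min, g.y_max) for key, g in spec.items()},
        },
    )


@dataclass
class SensitivityReport:
    """Midpoint sensitivities and relative contributions per response."""

    table: pd.DataFrame  # index: factor; columns: (response, quantity)

    def contributions(self, response: str) -> pd.Series:
        return self.table[(response, "contribution_pct")]


def sensitivity_contributions(
    models: Mapping[str, QuadraticModel], space: FactorSpace
) -> SensitivityReport:
    """Range-normalized midpoint sensitivities as percentages.

    sensitivity_i = |∂y/∂x_i| at the all-midpoint design × (upper_i − lower_i);
    contribution_i = 100 × sensitivity_i / Σ_j sensitivity_j, per response.
    """
    mid = space.midpoint_design()
    cols = {}
    for key, model in models.items():
        grad = model.gradient(mid)
        sens = {n: abs(grad[n]) * space[n].range for n in space.names}
        total = sum(sens.values())
        if total == 0:
            raise SpecError(f"all derivatives of {key!r} vanish at the midpoint")
        cols[(key, "derivative")] = {n: grad[n] for n in space.names}
        cols[(key, "sensitivity")] = sens
        cols[(key, "contribution_pct")] = {n: 100.0 * s / total for n, s in sens.items()}
    table = pd.DataFrame(cols)
    table.index.name = "factor"
    return SensitivityReport(table=table)
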