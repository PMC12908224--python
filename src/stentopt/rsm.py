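"""Second-order response-surface models: fitting, screening, prediction.

Each response y is modeled as a full quadratic polynomial in the k design
factors,

    y = β0 + Σ βi·xi + Σ βii·xi² + Σ βij·xi·xj + ε ,

fitted by ordinary least squares (statsmodels).  Non-significant terms are
screened out with a two-tailed t-test at α = 0.05 and the reduced model is
refitted.  Two unit systems are supported:

* ``natural`` — coefficients in printed units (µm, mm, count), directly
  comparable across studies;
* ``coded``   — factors mapped to [-1, +1].  In a face-centered CCD the
  coded linear and interaction columns are mutually orthogonal, so coded
  t-values cleanly separate effects; screening therefore always operates
  on the coded fit even when the reported model is refit in natural units.

The ten-term reduced set found significant in the five-factor study
(w, t, NS, SA, w², SA², w·NS, w·SA, t·SA, NS·SA) is available as the
``eq5`` preset; it equals the union of per-response screened terms over
the packaged first-DOE table.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design_space import BoundsError, FactorSpace, StentDesign
from .doe import DOETable, FACTOR_COLUMNS
from .design_space import RESPONSES

__all__ = [
    "ModelTerm",
    "intercept",
    "linear",
    "quadratic",
    "interaction",
    "full_quadratic_terms",
    "eq5_terms",
    "build_design_matrix",
    "fit",
    "screen_terms",
    "screen_union",
    "reduce_model",
    "predict",
    "residual_diagnostics",
    "QuadraticModel",
    "FitDiagnostics",
]


class ModelError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class ModelTerm:
    """One polynomial term, identified by kind and the factor(s) involved."""

    kind: str  # 'intercept' | 'linear' | 'quadratic' | 'interaction'
    factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = {"intercept": 0, "linear": 1, "quadratic": 1, "interaction": 2}.get(self.kind)
        if n is None:
            raise ModelError(f"unknown term kind {self.kind!r}")
        if len(self.factors) != n:
            raise ModelError(f"{self.kind} term takes {n} factor(s), got {self.factors}")
        if self.kind == "interaction" and self.factors[0] == self.factors[1]:
            raise ModelError("interaction terms need two distinct factors")

    @property
    def label(self) -> str:
        if self.kind == "intercept":
            return "1"
        if self.kind == "linear":
            return self.factors[0]
        if self.kind == "quadratic":
            return f"{self.factors[0]}^2"
        return "*".join(self.factors)

    def evaluate(self, values: dict[str, np.ndarray | float]):
        if self.kind == "intercept":
            some = next(iter(values.values()))
            return np.ones_like(np.asarray(some, dtype=float))
        if self.kind == "linear":
            return np.asarray(values[self.factors[0]], dtype=float)
        if self.kind == "quadratic":
            v = np.asarray(values[self.factors[0]], dtype=float)
            return v * v
        a, b = self.factors
        return np.asarray(values[a], dtype=float) * np.asarray(values[b], dtype=float)


def intercept() -> ModelTerm:
    return ModelTerm("intercept")


def linear(f: str) -> ModelTerm:
    return ModelTerm("linear", (f,))


def quadratic(f: str) -> ModelTerm:
    return ModelTerm("quadratic", (f,))


def interaction(a: str, b: str) -> ModelTerm:
    return ModelTerm("interaction", tuple(sorted((a, b))))


def full_quadratic_terms(names: Sequence[str]) -> list[ModelTerm]:
    """1 + k linear + k quadratic + C(k,2) interaction terms."""
    return (
        [intercept()]
        + [linear(n) for n in names]
        + [quadratic(n) for n in names]
        + [interaction(a, b) for a, b in itertools.combinations(names, 2)]
    )


def eq5_terms() -> list[ModelTerm]:
    """The ten-term reduced set of the five-factor study (plus intercept)."""
    return [
        intercept(),
        linear("w"),
        linear("t"),
        linear("NS"),
        linear("SA"),
        quadratic("w"),
        quadratic("SA"),
        interaction("w", "NS"),
        interaction("w", "SA"),
        interaction("t", "SA"),
        interaction("NS", "SA"),
    ]


TERM_PRESETS = {"eq5": eq5_terms}


def _factor_values(table: DOETable, units: str) -> dict[str, np.ndarray]:
    if units == "coded":
        coded = table.coded()
        return {n: coded[:, j] for j, n in enumerate(table.space.names)}
    return {
        n: table.frame[FACTOR_COLUMNS[n]].to_numpy(dtype=float) for n in table.space.names
    }


def build_design_matrix(
    values: dict[str, np.ndarray], terms: Sequence[ModelTerm]
) -> np.ndarray:
    """One column per term, evaluated on name->array factor values."""
    if len(set(terms)) != len(terms):
        raise ModelError("duplicate terms in model")
    known = set(values)
    for t in terms:
        missing = set(t.factors) - known
        if missing:
            raise ModelError(f"term {t.label} references unknown factor(s) {sorted(missing)}")
    cols = [t.evaluate(values) for t in terms]
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """A fitted polynomial model for one response."""

    response: str
    terms: list[ModelTerm]
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    df_resid: int
    r_squared: float
    space: FactorSpace
    units: str  # 'natural' | 'coded'
    residuals: np.ndarray
    fitted: np.ndarray
    train_values: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [t.label for t in self.terms],
                "beta": self.beta,
                "se": self.se,
                "t": self.tvalues,
            }
        )

    # -- evaluation -----------------------------------------------------
    def _values_for(self, design: StentDesign) -> dict[str, float]:
        if self.units == "coded":
            coded = self.space.to_coded(design)
            return {n: coded[j] for j, n in enumerate(self.space.names)}
        return {n: design.get(n) for n in self.space.names}

    def predict(self, design: StentDesign, *, extrapolate: bool = False) -> float:
        if not extrapolate and not self.space.contains(design):
            raise BoundsError(
                f"design {design.as_dict()} outside the fitted space; "
                "pass extrapolate=True to override"
            )
        vals = {k: np.atleast_1d(v) for k, v in self._values_for(design).items()}
        X = build_design_matrix(vals, self.terms)
        return float((X @ self.beta)[0])

    def predict_coded_grid(self, coded: dict[str, np.ndarray]) -> np.ndarray:
        """Vectorized prediction on coded factor arrays (no bounds checks)."""
        if self.units == "coded":
            vals = coded
        else:
            vals = {
                n: self.space[n].mid + coded[n] * self.space[n].half_range
                for n in self.space.names
            }
        X = build_design_matrix(vals, self.terms)
        return X @ self.beta

    def gradient(self, design: StentDesign) -> dict[str, float]:
        """Analytic ∂y/∂x_i (natural units) at a design point."""
        x = {n: design.get(n) for n in self.space.names}
        scale = {
            n: (1.0 / self.space[n].half_range if self.units == "coded" else 1.0)
            for n in self.space.names
        }
        xv = self._values_for(design)
        grad = {n: 0.0 for n in self.space.names}
        for b, t in zip(self.beta, self.terms):
            if t.kind == "linear":
                grad[t.factors[0]] += b * scale[t.factors[0]]
            elif t.kind == "quadratic":
                f = t.factors[0]
                grad[f] += 2 * b * xv[f] * scale[f]
            elif t.kind == "interaction":
                a, c = t.factors
                grad[a] += b * xv[c] * scale[a]
                grad[c] += b * xv[a] * scale[c]
        return grad

    # -- serialization --------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "response": self.response,
            "units": self.units,
            "terms": [{"kind": t.kind, "factors": list(t.factors)} for t in self.terms],
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "t": self.tvalues.tolist(),
            "df_resid": int(self.df_resid),
            "r_squared": float(self.r_squared),
            "space": [
                {"name": f.name, "lower": f.lower, "mid": f.mid, "upper": f.upper, "unit": f.unit}
                for f in self.space
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "QuadraticModel":
        from .design_space import Factor

        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        space = FactorSpace(
            tuple(Factor(f["name"], f["lower"], f["mid"], f["upper"], f["unit"]) for f in payload["space"])
        )
        n = len(payload["beta"])
        return cls(
            response=payload["response"],
            terms=[ModelTerm(t["kind"], tuple(t["factors"])) for t in payload["terms"]],
            beta=np.array(payload["beta"]),
            se=np.array(payload["se"]),
            tvalues=np.array(payload["t"]),
            df_resid=payload["df_resid"],
            r_squared=payload["r_squared"],
            space=space,
            units=payload["units"],
            residuals=np.empty(0),
            fitted=np.empty(0),
        )


@dataclass
class FitDiagnostics:
    """Screening threshold, per-term flags, and residual checks."""

    t_crit: float
    significant: dict[str, bool]
    shapiro_stat: float | None = None
    shapiro_p: float | None = None
    levene_stat: float | None = None
    levene_p: float | None = None
    levene_factor: str | None = None
    levene_by_factor: dict[str, tuple[float, float]] = field(default_factory=dict)


def fit(
    table: DOETable,
    response: str,
    terms: "Sequence[ModelTerm] | str" = "full",
    *,
    units: str = "natural",
) -> QuadraticModel:
    """Ordinary least squares fit of one response over a DOE table."""
    if isinstance(terms, str):
        if terms == "full":
            terms = full_quadratic_terms(table.space.names)
        elif terms in TERM_PRESETS:
            terms = TERM_PRESETS[terms]()
        else:
            raise ModelError(f"unknown term preset {terms!r}")
    terms = list(terms)
    y = table.response(response)
    if len(y) < len(terms) + 1:
        raise ModelError(
            f"{len(y)} runs cannot identify {len(terms)} terms with residual df"
        )
    values = _factor_values(table, units)
    X = build_design_matrix(values, terms)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ModelError(
            f"rank-deficient design matrix (rank {rank} < {X.shape[1]} terms); "
            f"terms: {[t.label for t in terms]}"
        )
    res = sm.OLS(y, X).fit()
    ybar = y.mean()
    r2 = 1.0 - np.sum(res.resid**2) / np.sum((y - ybar) ** 2)
    return QuadraticModel(
        response=response,
        terms=terms,
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        tvalues=np.asarray(res.tvalues),
        df_resid=int(res.df_resid),
        r_squared=float(r2),
        space=table.space,
        units=units,
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        train_values={k: np.array(v) for k, v in values.items()},
    )


def critical_t(df_resid: int, alpha: float = 0.05) -> float:
    return float(stats.t.ppf(1 - alpha / 2, df_resid))


def screen_terms(
    model: QuadraticModel,
    *,
    t_crit: float | None = None,
    alpha: float = 0.05,
    hierarchy: bool = True,
) -> tuple[list[ModelTerm], FitDiagnostics]:
    """Single-pass significance screen of a fitted full model.

    Terms with |t| > t_crit are retained (the intercept always is).  With
    ``hierarchy`` (weak heredity), a factor's linear term is kept whenever
    any retained quadratic/interaction term contains that factor.  The
    default threshold is the two-tailed t quantile at the model's residual
    df; pass ``t_crit`` explicitly to reproduce a fixed published constant.
    """
    if np.allclose(model.residuals, 0.0):
        raise ModelError("zero residual variance: all t-values undefined, cannot screen")
    if t_crit is None:
        t_crit = critical_t(model.df_resid, alpha)
    flags: dict[str, bool] = {}
    kept: list[ModelTerm] = []
    for term, tv in zip(model.terms, model.tvalues):
        sig = bool(abs(tv) > t_crit)
        flags[term.label] = sig
        if term.kind == "intercept" or sig:
            kept.append(term)
    if hierarchy:
        needed = {f for t in kept for f in t.factors if t.kind in ("quadratic", "interaction")}
        present = {t.factors[0] for t in kept if t.kind == "linear"}
        for f in needed - present:
            kept.append(linear(f))
        kept = [t for t in model.terms if t in kept]
    if not any(t.kind == "intercept" for t in kept):
        kept.insert(0, intercept())
    return kept, FitDiagnostics(t_crit=t_crit, significant=flags)


def screen_union(
    table: DOETable,
    responses: Iterable[str] | None = None,
    *,
    t_crit: float | None = None,
    alpha: float = 0.05,
) -> list[ModelTerm]:
    """Union of per-response screened terms — one shared reduced model.

    This is how the five-factor study arrived at its single reduced
    equation used for all four responses: a term is retained if it is
    significant for *any* response.
    """
    if responses is None:
        responses = [m.key for m in RESPONSES]
    union: set[ModelTerm] = set()
    for r in responses:
        full = fit(table, r, "full", units="coded")
        kept, _ = screen_terms(full, t_crit=t_crit, alpha=alpha)
        union.update(kept)
    ordered = [t for t in full_quadratic_terms(table.space.names) if t in union]
    return ordered


def reduce_model(
    table: DOETable,
    response: str,
    *,
    t_crit: float | None = None,
    alpha: float = 0.05,
    units: str = "natural",
) -> tuple[QuadraticModel, FitDiagnostics]:
    """Fit full quadratic (coded) → screen → refit reduced model.

    Screening always runs on the coded-unit fit, where CCD factor columns
    are orthogonal and t-values are not distorted by linear/quadratic
    collinearity; the reduced model is then refit in ``units``.
    """
    full = fit(table, response, "full", units="coded")
    kept, diag = screen_terms(full, t_crit=t_crit, alpha=alpha)
    reduced = fit(table, response, kept, units=units)
    return reduced, diag


def predict(model: QuadraticModel, design: StentDesign, *, extrapolate: bool = False) -> float:
    return model.predict(design, extrapolate=extrapolate)


def residual_diagnostics(
    model: QuadraticModel, diagnostics: FitDiagnostics | None = None
) -> FitDiagnostics:
    """Shapiro–Wilk normality and per-factor Levene homogeneity of residuals.

    Residuals are grouped by each factor's level for the Levene test; the
    factor with the smallest p is reported as the headline statistic.
    Results are informational — they never auto-reject a fit.
    """
    diag = diagnostics or FitDiagnostics(t_crit=critical_t(model.df_resid), significant={})
    resid = model.residuals
    if resid.size < 8:
        warnings.warn(f"only {resid.size} residuals; diagnostics skipped")
        return diag
    sw = stats.shapiro(resid)
    diag.shapiro_stat, diag.shapiro_p = float(sw.statistic), float(sw.pvalue)
    by_factor: dict[str, tuple[float, float]] = {}
    for name in model.space.names:
        vals = model.train_values.get(name)
        if vals is None:
            continue
        groups = [resid[np.isclose(vals, lv)] for lv in np.unique(vals)]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            continue
        if all(np.allclose(g, g[0]) for g in groups):
            by_factor[name] = (0.0, 1.0)
            continue
        lv = stats.levene(*groups)
        by_factor[name] = (float(lv.statistic), float(lv.pvalue))
    diag.levene_by_factor = by_factor
    if by_factor:
        worst = min(by_factor, key=lambda n: by_factor[n][1])
        diag.levene_factor = worst
        diag.levene_stat, diag.levene_p = by_factor[worst]
    return diag
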