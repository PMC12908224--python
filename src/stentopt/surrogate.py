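"""Synthetic FEA surrogate: quadratic response surfaces plus noise.

The finite-element stage that produced the study's response tables is far
outside desk scale, but the statistical structure its outputs feed into
the RSM pipeline is simple: smooth quadratic response surfaces with small
residual scatter (refit R² ≳ 0.96).  This module generates response
tables with exactly that structure from a configurable ground truth, plus
synthetic strain clouds shaped like the fatigue point clouds (a
low-amplitude bulk and a small heavy-tailed minority), so every pipeline
stage is exercisable end to end without any external data.

The default truth uses the reduced-model coefficients refit to the
packaged first-DOE table, so the surrogate emulates the study's own
surfaces.  Per-response noise SDs (0.8 kPa, 0.25 %, 1.5 %, 0.02) were
fixed once so that a CCD refit lands in the R² band above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design_space import RESPONSES, FactorSpace, StentDesign, TABLE1_SPACE
from .doe import DOETable, FACTOR_COLUMNS, load_table4
from .fatigue import StrainCloud
from .rsm import ModelTerm, QuadraticModel, build_design_matrix, eq5_terms, fit

__all__ = [
    "SurrogateTruth",
    "default_truth",
    "simulate_responses",
    "simulate_strain_cloud",
]

#: noise SD per response, natural units (kPa, %, %, ratio)
DEFAULT_SIGMA = {
    "mean_stress": 0.8,
    "high_stress_area": 0.25,
    "apposition": 1.5,
    "pinching": 0.02,
}

_CLAMPS = {
    "mean_stress": (0.0, None),
    "high_stress_area": (0.0, 100.0),
    "apposition": (0.0, 100.0),
    "pinching": (1.0, None),
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SurrogateTruth:
    """Ground-truth polynomial per response plus noise levels."""

    space: FactorSpace
    terms: dict[str, tuple[ModelTerm, ...]]
    beta: dict[str, np.ndarray]
    sigma: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))

    def evaluate(self, key: str, values: Mapping[str, np.ndarray]) -> np.ndarray:
        X = build_design_matrix(dict(values), list(self.terms[key]))
        return X @ self.beta[key]

    def with_sigma(self, **sigma: float) -> "SurrogateTruth":
        merged = dict(self.sigma)
        merged.update(sigma)
        return SurrogateTruth(self.space, self.terms, self.beta, merged)

    def noiseless(self) -> "SurrogateTruth":
        return self.with_sigma(**{k: 0.0 for k in self.sigma})

    def to_json(self, path=None) -> str:
        payload = {
            "space": [
                {"name": f.name, "lower": f.lower, "mid": f.mid, "upper": f.upper, "unit": f.unit}
                for f in self.space
            ],
            "responses": {
                key: {
                    "terms": [{"kind": t.kind, "factors": list(t.factors)} for t in self.terms[key]],
                    "beta": self.beta[key].tolist(),
                    "sigma": self.sigma[key],
                }
                for key in self.terms
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SurrogateTruth":
        from .design_space import Factor

        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        space = FactorSpace(
            tuple(Factor(f["name"], f["lower"], f["mid"], f["upper"], f["unit"]) for f in payload["space"])
        )
        terms, beta, sigma = {}, {}, {}
        for key, r in payload["responses"].items():
            terms[key] = tuple(ModelTerm(t["kind"], tuple(t["factors"])) for t in r["terms"])
            beta[key] = np.array(r["beta"])
            sigma[key] = float(r["sigma"])
        return cls(space=space, terms=terms, beta=beta, sigma=sigma)


def default_truth(space: FactorSpace | None = None) -> SurrogateTruth:
    """Truth surfaces from the reduced-model refit of the packaged table."""
    space = space or TABLE1_SPACE
    table = load_table4()
    terms, beta = {}, {}
    for m in RESPONSES:
        model = fit(table, m.key, eq5_terms(), units="natural")
        terms[m.key] = tuple(model.terms)
        beta[m.key] = model.beta.copy()
    return SurrogateTruth(space=space, terms=terms, beta=beta)


def truth_from_models(models: Mapping[str, QuadraticModel], sigma: Mapping[str, float] | None = None) -> SurrogateTruth:
    some = next(iter(models.values()))
    return SurrogateTruth(
        space=some.space,
        terms={k: tuple(m.terms) for k, m in models.items()},
        beta={k: m.beta.copy() for k, m in models.items()},
        sigma=dict(sigma or DEFAULT_SIGMA),
    )


def simulate_responses(
    designs: Sequence[StentDesign],
    truth: SurrogateTruth,
    seed: int | np.random.Generator = 0,
) -> DOETable:
    """Evaluate the truth polynomials plus N(0, σ) noise, clamped to the
    physical range of each response; deterministic per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for d in designs:
        if not truth.space.contains(d):
            from .design_space import BoundsError

            raise BoundsError(f"design {d.as_dict()} outside the surrogate's space")
    values = {
        n: np.array([d.get(n) for d in designs], dtype=float) for n in truth.space.names
    }
    data = {"run": np.arange(1, len(designs) + 1)}
    for n in truth.space.names:
        data[FACTOR_COLUMNS[n]] = values[n]
    for m in RESPONSES:
        y = truth.evaluate(m.key, values)
        sig = truth.sigma.get(m.key, 0.0)
        if sig > 0:
            y = y + rng.normal(0.0, sig, size=y.shape)
        lo, hi = _CLAMPS[m.key]
        clipped = np.clip(y, lo, hi)
        data[m.column] = clipped
        # tag rows whose value was pulled back into the physical range:
        # a clamped response no longer sits on the truth polynomial
        data[f"clamped_{m.column}"] = (clipped != y).astype(int)
    frame = pd.DataFrame(data)
    return DOETable(space=truth.space, frame=frame)


def simulate_strain_cloud(
    n_elements: int,
    *,
    tail_fraction: float = 0.003,
    seed: int | np.random.Generator = 0,
) -> StrainCloud:
    """Two-component strain cloud emulating a post-flexion fatigue export.

    Bulk elements: mean strain lognormal (median 0.5 %, σ_log 0.5, mostly
    below 2 %) with amplitudes strictly below 0.4 % (scaled Beta).  A
    Bernoulli(tail_fraction) minority carries amplitudes above 1 %
    (1 + Exp(0.4)), a small part of which exceeds 2 %.
    """
    if n_elements < 1:
        raise ConfigError("need at least one element")
    if not 0.0 <= tail_fraction <= 1.0:
        raise ConfigError(f"tail fraction {tail_fraction} outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = rng.lognormal(mean=np.log(0.5), sigma=0.5, size=n_elements)
    amp = 0.4 * rng.beta(2.0, 4.0, size=n_elements)
    tail = rng.random(n_elements) < tail_fraction
    amp[tail] = 1.0 + rng.exponential(0.4, size=int(tail.sum()))
    return StrainCloud(mean_strain=mean, amplitude=amp, provenance="synthetic")
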