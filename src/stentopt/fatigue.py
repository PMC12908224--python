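"""Fatigue screening of per-element strain clouds.

After limb flexion, each stent element carries a mean strain and a strain
amplitude (half the cyclic range between the deformed and straight
configurations).  Nitinol fatigue safety limits on strain amplitude range
from 0.4 % (standard, generation I material) to 2 % (high-purity,
generation III), so a strain cloud is summarized by the fraction of
elements inside the conservative envelope (mean strain < 2 % AND amplitude
< 0.4 %) and the fractions exceeding 1 % and 2 % amplitude.  All threshold
comparisons are strict, matching the below/under/above wording of the
criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StrainCloud", "FatigueThresholds", "FatigueSummary", "summarize", "load_strain_cloud"]


class CloudError(ValueError):
    pass


@dataclass(frozen=True)
class StrainCloud:
    """Per-element (mean strain, strain amplitude), both in percent."""

    mean_strain: np.ndarray
    amplitude: np.ndarray
    provenance: str = "synthetic"  # 'FEA export' | 'synthetic'

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_strain, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        object.__setattr__(self, "mean_strain", m)
        object.__setattr__(self, "amplitude", a)
        if m.size == 0:
            raise CloudError("empty strain cloud")
        if m.shape != a.shape:
            raise CloudError("mean strain and amplitude lengths differ")
        if not (np.isfinite(m).all() and np.isfinite(a).all()):
            raise CloudError("non-finite strain value")
        if (a < 0).any():
            raise CloudError("negative strain amplitude")

    @property
    def n_elements(self) -> int:
        return self.mean_strain.size


@dataclass(frozen=True)
class FatigueThresholds:
    """Strain thresholds in percent (defaults: generation-I envelope)."""

    amp_safe: float = 0.4
    amp_high: float = 1.0
    amp_very_high: float = 2.0
    mean_max: float = 2.0


@dataclass(frozen=True)
class FatigueSummary:
    """Fractions are percentages of the element count."""

    criterion_pct: float      # mean < mean_max AND amp < amp_safe
    above_high_pct: float     # amp > amp_high
    above_very_high_pct: float  # amp > amp_very_high
    n_elements: int
    thresholds: FatigueThresholds = FatigueThresholds()

    def as_dict(self) -> dict[str, float]:
        return {
            "criterion_pct": self.criterion_pct,
            "above_high_pct": self.above_high_pct,
            "above_very_high_pct": self.above_very_high_pct,
            "n_elements": self.n_elements,
        }


def summarize(cloud: StrainCloud, thresholds: FatigueThresholds | None = None) -> FatigueSummary:
    """Count elements against the fatigue thresholds (strict inequalities)."""
    th = thresholds or FatigueThresholds()
    n = cloud.n_elements
    m, a = cloud.mean_strain, cloud.amplitude
    crit = np.count_nonzero((m < th.mean_max) & (a < th.amp_safe))
    hi = np.count_nonzero(a > th.amp_high)
    vhi = np.count_nonzero(a > th.amp_very_high)
    return FatigueSummary(
        criterion_pct=100.0 * crit / n,
        above_high_pct=100.0 * hi / n,
        above_very_high_pct=100.0 * vhi / n,
        n_elements=n,
        thresholds=th,
    )


def load_strain_cloud(path, provenance: str = "FEA export") -> StrainCloud:
    """Read ``element,mean_strain_pct,amp_pct`` CSV."""
    df = pd.read_csv(path)
    required = {"mean_strain_pct", "amp_pct"}
    if not required <= set(df.columns):
        raise CloudError(f"expected columns {sorted(required)}, got {list(df.columns)}")
    return StrainCloud(
        mean_strain=df["mean_strain_pct"].to_numpy(dtype=float),
        amplitude=df["amp_pct"].to_numpy(dtype=float),
        provenance=provenance,
    )


def plot_cloud(cloud: StrainCloud, summary: FatigueSummary, path) -> None:
    """Optional scatter of amplitude vs mean strain with threshold lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    th = summary.thresholds
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(cloud.mean_strain, cloud.amplitude, s=2, alpha=0.3, rasterized=True)
    ax.axhline(th.amp_safe, color="tab:red", lw=1, label=f"amplitude {th.amp_safe}%")
    ax.axhline(th.amp_high, color="tab:orange", lw=1, ls="--", label=f"amplitude {th.amp_high}%")
    ax.axvline(th.mean_max, color="tab:gray", lw=1, ls=":", label=f"mean {th.mean_max}%")
    ax.set_xlabel("mean strain [%]")
    ax.set_ylabel("strain amplitude [%]")
    ax.set_title(f"{summary.criterion_pct:.1f}% of {summary.n_elements} elements in envelope")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
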