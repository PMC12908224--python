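"""Parametric stent centerline geometry.

The stent is drawn on a flat, unwrapped sheet of width π·D (the tube
circumference) as seven sine-wave rings joined by six sets of sine-wave
links, then wrapped onto a cylinder.  Coordinates on the sheet are
``(u, z)``: ``u`` runs circumferentially in [0, π·D] mm and ``z`` axially.

Conventions (documented because the source figure leaves them open):

* ``SA`` is the standard sine amplitude, so a ring's peak-to-peak axial
  extent is ``2·SA``.
* Adjacent rings alternate sine phase by π so that peaks face each other;
  the axial gap between facing peak tips is the link length ``LL = π/2`` mm,
  making the ring pitch ``2·SA + LL`` independent of LA.
* Each junction connects every other facing peak pair (NS/4 links for NS
  divisible by 4), and the selection phase alternates from junction to
  junction to avoid a stiff axial spine.
* A link is a half-wave sine excursion of amplitude LA in ``u`` spanning
  ``LL`` axially; LA = 0 degenerates to a straight axial strut.

The strut cross-section (w × t) is carried as metadata: all outputs are
centerline polylines, which is what the downstream metrics need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .design_space import StentDesign

__all__ = [
    "FlatPattern",
    "TubularStent",
    "make_ring_curve",
    "make_link_curves",
    "build_flat_pattern",
    "wrap_to_tube",
    "coverage_metrics",
]


class GeometryError(ValueError):
    pass


def _require_even_ns(design: StentDesign) -> int:
    ns = design.NS
    if not (float(ns).is_integer() and int(ns) > 0 and int(ns) % 2 == 0):
        raise GeometryError(f"NS={ns} must be a positive even integer (peaks must pair)")
    return int(ns)


@dataclass(frozen=True)
class FlatPattern:
    """Centerline curves on the unwrapped sheet, [mm]."""

    ring_curves: tuple[np.ndarray, ...]   # each (n, 2) array of (u, z)
    link_curves: tuple[tuple[np.ndarray, ...], ...]  # one tuple per junction
    sheet_width: float                    # π·D [mm]
    strut_width_um: float
    strut_thickness_um: float

    @property
    def n_rings(self) -> int:
        return len(self.ring_curves)

    @property
    def n_junctions(self) -> int:
        return len(self.link_curves)

    def all_curves(self) -> list[np.ndarray]:
        out = list(self.ring_curves)
        for group in self.link_curves:
            out.extend(group)
        return out


@dataclass(frozen=True)
class TubularStent:
    """Wrapped centerline curves, (n, 3) arrays of (x, y, z) [mm]."""

    curves: tuple[np.ndarray, ...]
    radius: float        # centerline radius D/2 - t/2 [mm]
    length: float        # axial extent [mm]
    metal_coverage: float  # centerline footprint area / tube surface area


def ring_pitch(design: StentDesign) -> float:
    """Axial distance between ring centerlines: facing peak tips are LL apart."""
    return 2.0 * design.SA + design.link_length


def stent_length(design: StentDesign) -> float:
    """Axial extent of the full ring stack (closed form)."""
    return (design.n_rings - 1) * ring_pitch(design) + 2.0 * design.SA


def make_ring_curve(
    design: StentDesign,
    samples_per_strut: int = 20,
    *,
    z_center: float = 0.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Sample one sine-wave ring on the flat sheet.

    z(u) = z_center + SA·sin(2π·(NS/2)·u/W + phase) with W = π·D, so one
    circumference carries NS extrema (NS/2 peaks up, NS/2 down).
    """
    ns = _require_even_ns(design)
    if samples_per_strut < 2:
        raise GeometryError("samples_per_strut must be >= 2")
    width = math.pi * design.outer_diameter
    n = ns * samples_per_strut
    u = np.linspace(0.0, width, n + 1)
    z = z_center + design.SA * np.sin(2 * math.pi * (ns / 2) * u / width + phase)
    return np.column_stack([u, z])


def _peak_positions(design: StentDesign, phase: float, kind: str) -> np.ndarray:
    """u-coordinates of the up-peaks ('up') or down-peaks ('down') of a ring."""
    ns = _require_even_ns(design)
    width = math.pi * design.outer_diameter
    omega = 2 * math.pi * (ns / 2) / width
    target = math.pi / 2 if kind == "up" else 3 * math.pi / 2
    # omega*u + phase = target (mod 2π)
    first = (target - phase) % (2 * math.pi) / omega
    period = 2 * math.pi / omega
    k = np.arange(ns // 2)
    return (first + k * period) % width


def make_link_curves(
    design: StentDesign,
    ring_pair_index: int,
    samples: int = 40,
) -> list[np.ndarray]:
    """Links joining ring ``i`` to ring ``i+1`` on the flat sheet.

    Rings alternate phase, so the up-peaks of ring ``i`` align in ``u``
    with the down-peaks of ring ``i+1``; a link spans the axial gap LL
    between the facing tips with a sine excursion of amplitude LA in u.
    Every other facing pair is connected, the starting peak alternating
    with junction parity.
    """
    ns = _require_even_ns(design)
    if ns < 4:
        raise GeometryError(f"NS={ns} < 4 leaves no every-other-peak pairs to link")
    if not 0 <= ring_pair_index < design.n_rings - 1:
        raise GeometryError(f"ring_pair_index {ring_pair_index} out of range")
    phase_lo = 0.0 if ring_pair_index % 2 == 0 else math.pi
    peaks = _peak_positions(design, phase_lo, "up")
    peaks = np.sort(peaks)
    start = ring_pair_index % 2  # alternate selection phase between junctions
    chosen = peaks[start::2]
    z0 = ring_pair_index * ring_pitch(design) + design.SA  # tip of the up-peak
    ll = design.link_length
    width = math.pi * design.outer_diameter
    curves = []
    zs = np.linspace(0.0, ll, samples + 1)
    for up in chosen:
        u = (up + design.LA * np.sin(math.pi * zs / ll)) % width
        curves.append(np.column_stack([u, z0 + zs]))
    return curves


def build_flat_pattern(design: StentDesign, samples_per_strut: int = 20) -> FlatPattern:
    """Assemble the full 7-ring / 6-junction flat pattern."""
    pitch = ring_pitch(design)
    rings = tuple(
        make_ring_curve(
            design,
            samples_per_strut,
            z_center=i * pitch,
            phase=0.0 if i % 2 == 0 else math.pi,
        )
        for i in range(design.n_rings)
    )
    links = tuple(
        tuple(make_link_curves(design, j, samples=2 * samples_per_strut))
        for j in range(design.n_rings - 1)
    )
    return FlatPattern(
        ring_curves=rings,
        link_curves=links,
        sheet_width=math.pi * design.outer_diameter,
        strut_width_um=design.w,
        strut_thickness_um=design.t,
    )


def wrap_to_tube(flat: FlatPattern, design: StentDesign) -> TubularStent:
    """Wrap the flat sheet onto a cylinder.

    The wrap angle is θ = u / (W / 2π) so that u = 0 and u = W coincide
    (exact seam closure); the centerline sits at the mid-wall radius
    r = D/2 − t/2.  Because r is slightly inside the sheet-width radius
    W/2π = D/2, circumferential arc lengths scale by (D − t)/D on wrapping;
    axial lengths are unchanged.
    """
    r_angle = flat.sheet_width / (2 * math.pi)  # = D/2
    radius = design.outer_diameter / 2 - (design.t * 1e-3) / 2  # t: µm -> mm
    curves = []
    for c in flat.all_curves():
        theta = c[:, 0] / r_angle
        curves.append(
            np.column_stack([radius * np.cos(theta), radius * np.sin(theta), c[:, 1]])
        )
    length, coverage = _coverage(curves, design)
    return TubularStent(curves=tuple(curves), radius=radius, length=length, metal_coverage=coverage)


def polyline_length(curve: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(curve, axis=0), axis=1)))


def _unwrapped_polyline_length(curve3d: np.ndarray, radius: float) -> float:
    """Arc length of a wrapped curve, measuring chords on the cylinder surface."""
    theta = np.unwrap(np.arctan2(curve3d[:, 1], curve3d[:, 0]))
    du = radius * np.diff(theta)
    dz = np.diff(curve3d[:, 2])
    return float(np.sum(np.hypot(du, dz)))


def _coverage(curves: list[np.ndarray], design: StentDesign) -> tuple[float, float]:
    zs = np.concatenate([c[:, 2] for c in curves])
    length = float(zs.max() - zs.min())
    radius = design.outer_diameter / 2 - (design.t * 1e-3) / 2
    total_arc = sum(_unwrapped_polyline_length(c, radius) for c in curves)
    footprint = total_arc * (design.w * 1e-3)  # centerline length × strut width [mm²]
    tube_area = math.pi * design.outer_diameter * length
    return length, footprint / tube_area


def coverage_metrics(stent: TubularStent, design: StentDesign) -> tuple[float, float]:
    """(stent length [mm], metal coverage ratio) for a wrapped stent."""
    return stent.length, stent.metal_coverage


def export_curves_csv(stent: TubularStent, path) -> None:
    """Write wrapped centerlines as ``curve,point,x_mm,y_mm,z_mm`` rows."""
    import csv

    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["curve", "point", "x_mm", "y_mm", "z_mm"])
        for ci, c in enumerate(stent.curves):
            for pi, (x, y, z) in enumerate(c):
                wr.writerow([ci, pi, f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"])
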