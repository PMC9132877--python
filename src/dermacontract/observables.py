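"""Scar metrics: tracked wound polygon, extremal times, collagen ratio,
and Monte Carlo error estimators.

The wound area is measured Lagrangianly: material points seeded on the wound
rectangle boundary are advected each step by the backend's displacement
increment interpolated at their current position, and the area follows from
the shoelace formula.  This is exact for affine deformations and keeps
``r(0) = 1`` identically.

``t_min`` is the (earliest) time of maximal contraction; ``t_end`` is the
first time after ``t_min`` at which the per-step area change falls below one
percent of the maximal contraction per unit time — the practical
re-equilibration time of the scar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LinearRing

__all__ = [
    "WoundPolygon",
    "ScarSeries",
    "t_min_of",
    "t_end_of",
    "collagen_ratio",
    "mc_error",
    "MCSummary",
]


def shoelace_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class WoundPolygon:
    """Material polygon tracking the deforming wound boundary."""

    def __init__(self, vertices: np.ndarray):
        self.vertices = np.asarray(vertices, float).copy()
        self.area0 = shoelace_area(self.vertices)
        if self.area0 <= 0:
            raise ValueError("polygon must be counter-clockwise with positive area")

    def advect(self, displacement_increment_at) -> None:
        """Move every vertex by the interpolated displacement increment."""
        self.vertices = self.vertices + displacement_increment_at(self.vertices)

    def area(self) -> float:
        return shoelace_area(self.vertices)

    def check_simple(self) -> None:
        if not LinearRing(self.vertices).is_simple:
            raise RuntimeError(
                "tracked wound polygon self-intersects; the deformation is too "
                "large for the material-point resolution"
            )


@dataclass
class ScarSeries:
    """Time series of scar metrics recorded during a run."""

    times: list[float] = field(default_factory=list)
    areas: list[float] = field(default_factory=list)
    rho_hat: list[float] = field(default_factory=list)
    n_fibro: list[int] = field(default_factory=list)
    n_myo: list[int] = field(default_factory=list)
    n_macro: list[int] = field(default_factory=list)

    def record(self, t, area, rho_hat=np.nan, n_f=0, n_m=0, n_mac=0) -> None:
        self.times.append(float(t))
        self.areas.append(float(area))
        self.rho_hat.append(float(rho_hat))
        self.n_fibro.append(int(n_f))
        self.n_myo.append(int(n_m))
        self.n_macro.append(int(n_mac))

    @property
    def r(self) -> np.ndarray:
        a = np.asarray(self.areas)
        return a / a[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "A": self.areas,
                "r": self.r,
                "rho_hat": self.rho_hat,
                "n_fibro": self.n_fibro,
                "n_myo": self.n_myo,
                "n_macro": self.n_macro,
            }
        )


def t_min_of(series: ScarSeries) -> float:
    """Earliest time (> 0) of maximal contraction A(0) - A(t)."""
    A = np.asarray(series.areas)
    if len(A) < 2:
        raise ValueError("series must contain more than the initial sample")
    contraction = A[0] - A[1:]
    idx = 1 + int(np.argmax(contraction))      # argmax takes the earliest tie
    return series.times[idx]


def t_end_of(series: ScarSeries) -> tuple[float, bool]:
    """First time after t_min with a per-step area change below the
    one-percent-of-maximal-contraction threshold.

    Returns ``(t_end, converged)``; when no time qualifies, the final time is
    returned with ``converged = False``.  Evaluated on the stored cadence.
    """
    A = np.asarray(series.areas)
    t = np.asarray(series.times)
    tmin = t_min_of(series)
    i_min = int(np.argwhere(t == tmin)[0, 0])
    max_contraction = abs(A[i_min] - A[0])
    for i in range(i_min + 1, len(A) - 1):
        dt_i = t[i + 1] - t[i]
        if abs(A[i + 1] - A[i]) <= 0.01 * dt_i * max_contraction:
            return float(t[i]), True
    return float(t[-1]), False


def _polygon_quadrature(polygon: WoundPolygon) -> tuple[np.ndarray, np.ndarray]:
    """Edge-midpoint quadrature on the centroid fan of the polygon.

    Exact for fields linear on each fan triangle; adequate for P1 fields on a
    finer mesh.  Returns (points (3k, 2), weights (3k,)).
    """
    v = polygon.vertices
    centroid = v.mean(axis=0)
    nxt = np.roll(v, -1, axis=0)
    # fan triangle (centroid, v_i, v_{i+1}); degree-2 rule at edge midpoints
    areas = 0.5 * ((v[:, 0] - centroid[0]) * (nxt[:, 1] - centroid[1])
                   - (v[:, 1] - centroid[1]) * (nxt[:, 0] - centroid[0]))
    m1 = 0.5 * (centroid + v)
    m2 = 0.5 * (v + nxt)
    m3 = 0.5 * (nxt + centroid)
    pts = np.concatenate([m1, m2, m3])
    w = np.concatenate([areas, areas, areas]) / 3.0
    return pts, w


def collagen_ratio(mesh, omega_c: np.ndarray, polygon: WoundPolygon, rho_c0: float) -> float:
    """Wound-integrated collagen density relative to the healthy-skin level.

    rho_hat(t) = int_{wound(t)} rho_c / int_{wound(t)} rho_c0 with rho_c0 the
    undamaged-skin collagen density (1/alpha_rho for the default tensors).
    """
    if rho_c0 <= 0:
        raise ValueError("reference collagen density must be positive")
    area = polygon.area()
    if area <= 0:
        raise ValueError("degenerate wound polygon")
    pts, w = _polygon_quadrature(polygon)
    rho = mesh.interpolate(omega_c[:, 0] + omega_c[:, 1], pts)
    return float((w @ rho) / (rho_c0 * area))


def mc_error(mean: float, sd: float, n: int) -> tuple[float, float]:
    """Monte Carlo standard error sd/sqrt(n) and relative error sd/(|mean| sqrt(n)).

    The relative error is NaN (flagged undefined) when the mean vanishes.
    """
    if n < 2:
        raise ValueError("need at least two samples")
    err = sd / np.sqrt(n)
    rel = err / abs(mean) if mean != 0 else float("nan")
    return float(err), float(rel)


@dataclass
class MCSummary:
    """Per-output Monte Carlo sample statistics with error estimates."""

    name: str
    mean: float
    sd: float
    n: int

    @property
    def mc_error(self) -> float:
        return mc_error(self.mean, self.sd, self.n)[0] if self.mean == self.mean else float("nan")

    @property
    def rel_error(self) -> float:
        return mc_error(self.mean, self.sd, self.n)[1]
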