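"""Structured triangular meshing of the rectangular skin domain.

The computational domain is the rectangle ``[-x0/2, x0/2] x [-y0/2, y0/2]``
with a rectangular wound subdomain ``[-xw/2, xw/2] x [-yw/2, yw/2]`` strictly
embedded in it.  The mesh is a crossed-diagonal structured triangulation:
every grid cell is split into two triangles with the diagonal alternating by
cell parity, so the wound boundary is an exact polygonal line of mesh edges
whenever the wound edges coincide with grid lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Mesh", "build_rect_mesh"]

_ALIGN_TOL = 1e-9


@dataclass
class Mesh:
    """Triangulated rectangle with wound-subdomain labelling.

    Node coordinates are in the length unit of the active preset (cm for the
    sensitivity preset, micrometre for the two-backend comparison preset).
    """

    nodes: np.ndarray          # (N, 2) coordinates
    triangles: np.ndarray      # (M, 3) node indices, counter-clockwise
    x0: float
    y0: float
    xw: float
    yw: float
    nx: int
    ny: int
    boundary_nodes: np.ndarray = field(init=False)      # indices on outer rectangle
    wound_indicator: np.ndarray = field(init=False)     # (N,) 0/1 per node
    element_areas: np.ndarray = field(init=False)       # (M,)
    grads: np.ndarray = field(init=False)               # (M, 3, 2) P1 basis gradients

    def __post_init__(self) -> None:
        p = self.nodes[self.triangles]                  # (M, 3, 2)
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        if np.any(det <= 0):
            raise ValueError("triangulation contains non-positively-oriented elements")
        self.element_areas = 0.5 * det
        # gradients of the three barycentric basis functions
        g = np.empty((len(self.triangles), 3, 2))
        g[:, 1, 0] = d2[:, 1] / det
        g[:, 1, 1] = -d2[:, 0] / det
        g[:, 2, 0] = -d1[:, 1] / det
        g[:, 2, 1] = d1[:, 0] / det
        g[:, 0] = -g[:, 1] - g[:, 2]
        self.grads = g

        x, y = self.nodes[:, 0], self.nodes[:, 1]
        hx, hy = self.hx, self.hy
        tol = _ALIGN_TOL * max(self.x0, self.y0)
        on_edge = (
            (np.abs(x - (-self.x0 / 2)) < tol)
            | (np.abs(x - (self.x0 / 2)) < tol)
            | (np.abs(y - (-self.y0 / 2)) < tol)
            | (np.abs(y - (self.y0 / 2)) < tol)
        )
        self.boundary_nodes = np.flatnonzero(on_edge)
        self.wound_indicator = (
            (np.abs(x) <= self.xw / 2 + tol) & (np.abs(y) <= self.yw / 2 + tol)
        ).astype(float)

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def hx(self) -> float:
        return self.x0 / self.nx

    @property
    def hy(self) -> float:
        return self.y0 / self.ny

    @property
    def wound_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.wound_indicator > 0.5)

    @property
    def interior_nodes(self) -> np.ndarray:
        mask = np.ones(self.n_nodes, bool)
        mask[self.boundary_nodes] = False
        return np.flatnonzero(mask)

    def element_edges(self, elem: int) -> list[tuple[int, int]]:
        """The three (tail, head) node pairs bounding element ``elem``."""
        a, b, c = self.triangles[elem]
        return [(a, b), (b, c), (c, a)]

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return (np.abs(pts[:, 0]) <= self.x0 / 2 + _ALIGN_TOL * self.x0) & (
            np.abs(pts[:, 1]) <= self.y0 / 2 + _ALIGN_TOL * self.y0
        )

    # -- point location ----------------------------------------------------

    def _cell_triangles(self, ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
        """Indices of the two triangles of structured grid cell (ix, iy)."""
        base = 2 * (iy * self.nx + ix)
        return np.stack([base, base + 1], axis=-1)

    def locate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Containing triangle and barycentric coordinates for each point.

        Points on inter-element edges resolve to the lowest-indexed containing
        triangle so that runs are bit-reproducible.  Raises ``ValueError`` for
        points outside the domain.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        if not np.all(self.contains(pts)):
            bad = pts[~self.contains(pts)][0]
            raise ValueError(f"point {tuple(bad)} lies outside the computational domain")
        ix = np.clip(((pts[:, 0] + self.x0 / 2) / self.hx).astype(int), 0, self.nx - 1)
        iy = np.clip(((pts[:, 1] + self.y0 / 2) / self.hy).astype(int), 0, self.ny - 1)
        cand = self._cell_triangles(ix, iy)                     # (n, 2)
        tri = np.empty(len(pts), int)
        bary = np.empty((len(pts), 3))
        for k in range(2):  # lowest index first => deterministic tie-break
            t = cand[:, k]
            lam = self._barycentric(t, pts)
            ok = np.all(lam >= -1e-12, axis=1)
            if k == 0:
                sel = ok
                tri[sel] = t[sel]
                bary[sel] = lam[sel]
                rest = ~sel
            else:
                tri[rest] = t[rest]
                bary[rest] = lam[rest]
        return tri, np.clip(bary, 0.0, 1.0)

    def _barycentric(self, tris: np.ndarray, pts: np.ndarray) -> np.ndarray:
        p = self.nodes[self.triangles[tris]]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        r = pts - p[:, 0]
        l1 = (r[:, 0] * d2[:, 1] - r[:, 1] * d2[:, 0]) / det
        l2 = (d1[:, 0] * r[:, 1] - d1[:, 1] * r[:, 0]) / det
        return np.stack([1.0 - l1 - l2, l1, l2], axis=1)

    def interpolate(self, nodal: np.ndarray, points: np.ndarray) -> np.ndarray:
        """P1 interpolation of a nodal field (any trailing shape) at points."""
        tri, lam = self.locate(points)
        vals = np.asarray(nodal)[self.triangles[tri]]           # (n, 3, ...)
        lamx = lam.reshape(lam.shape + (1,) * (vals.ndim - 2))
        return (lamx * vals).sum(axis=1)

    def gradient_at(self, nodal: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Piecewise-constant gradient of a P1 scalar field at points: (n, 2)."""
        tri, _ = self.locate(points)
        vals = np.asarray(nodal)[self.triangles[tri]]           # (n, 3)
        return np.einsum("nk,nkd->nd", vals, self.grads[tri])

    def wound_boundary_polygon(self, n_per_side: int = 24) -> np.ndarray:
        """Material points on the wound rectangle boundary, counter-clockwise."""
        a, b = self.xw / 2, self.yw / 2
        t = np.arange(n_per_side) / n_per_side
        south = np.stack([-a + 2 * a * t, np.full_like(t, -b)], axis=1)
        east = np.stack([np.full_like(t, a), -b + 2 * b * t], axis=1)
        north = np.stack([a - 2 * a * t, np.full_like(t, b)], axis=1)
        west = np.stack([np.full_like(t, -a), b - 2 * b * t], axis=1)
        return np.concatenate([south, east, north, west])


def _check_resolvable(length: float, half_span: float, n: int, axis: str) -> None:
    h = length / n
    # a node must sit exactly on the wound edge at +/- half_span
    k = (length / 2 - half_span) / h
    m = 2 * half_span / h
    if abs(k - round(k)) > 1e-9 * n or abs(m - round(m)) > 1e-9 * n:
        raise ValueError(
            f"wound edge at ±{half_span:g} along {axis} does not coincide with a "
            f"mesh line (grid spacing {h:g}); choose n{axis} so the wound edges "
            "lie on grid lines"
        )


def build_rect_mesh(
    x0: float, y0: float, nx: int, ny: int, xw: float, yw: float
) -> Mesh:
    """Crossed-diagonal triangulation of the domain with an embedded wound.

    Parameters are the domain side lengths ``x0, y0``, grid divisions
    ``nx, ny`` and wound side lengths ``xw, yw``.  The wound rectangle must be
    strictly inside the domain and its edges must coincide with grid lines,
    otherwise the mesh is rejected naming the misaligned edge.
    """
    if nx < 2 or ny < 2:
        raise ValueError("nx and ny must both be at least 2")
    if not (0 < xw < x0 and 0 < yw < y0):
        raise ValueError("wound rectangle must be strictly inside the domain")
    _check_resolvable(x0, xw / 2, nx, "x")
    _check_resolvable(y0, yw / 2, ny, "y")

    xs = np.linspace(-x0 / 2, x0 / 2, nx + 1)
    ys = np.linspace(-y0 / 2, y0 / 2, ny + 1)
    X, Y = np.meshgrid(xs, ys)                       # row-major: node = iy*(nx+1)+ix
    nodes = np.stack([X.ravel(), Y.ravel()], axis=1)

    tris = np.empty((2 * nx * ny, 3), int)
    for iy in range(ny):
        for ix in range(nx):
            a = iy * (nx + 1) + ix
            b = a + 1
            c = b + (nx + 1)
            d = a + (nx + 1)
            e = 2 * (iy * nx + ix)
            if (ix + iy) % 2 == 0:                   # diagonal a-c
                tris[e] = (a, b, c)
                tris[e + 1] = (a, c, d)
            else:                                    # diagonal b-d
                tris[e] = (a, b, d)
                tris[e + 1] = (b, c, d)
    return Mesh(nodes=nodes, triangles=tris, x0=x0, y0=y0, xw=xw, yw=yw, nx=nx, ny=ny)
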