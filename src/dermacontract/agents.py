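"""Agent-based cell layer: traction forces, migration, and stochastic events.

Cells are point agents with a square boundary discretization: the disc of
radius R is approximated by its circumscribing square of side 2R, and the cell
pulls the substrate inward with one point load at each side midpoint of
magnitude ``P * 2R`` (force-per-length P times segment length).  Macrophages
exert no traction.  The four loads of a cell cancel exactly, so a cell is a
force multipole with zero net force.

Migration follows overdamped Langevin dynamics (Euler-Maruyama): a chemotaxis
drift along a regularized cytokine gradient, passive convection with the
substrate velocity, an optional cell-cell interaction drift, and a Wiener
increment.  (Myo)fibroblasts are additionally steered by the local collagen
orientation tensor.  Division, differentiation, apoptosis and macrophage
influx are exponential-clock events sampled once per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .mesh import Mesh

__all__ = [
    "Cell",
    "CellEventRates",
    "MigrationParams",
    "CellPopulation",
    "cell_boundary_forces",
    "chemotaxis_weight",
    "migrate_macrophage",
    "migrate_fibroblast",
    "event_probability",
]

FIBROBLAST = "fibroblast"
MYOFIBROBLAST = "myofibroblast"
MACROPHAGE = "macrophage"


@dataclass
class Cell:
    center: np.ndarray                 # (2,)
    phenotype: str
    R: float
    alive: bool = True
    r_N: np.ndarray | None = None      # last unit active-displacement direction
    birth_time: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        if self.R <= 0:
            raise ValueError("cell radius must be positive")


@dataclass
class CellEventRates:
    """Exponential-clock rate coefficients (all >= 0).

    lambda_d scales with the local strain energy density (saturated), and
    lambda_diff with the local TGF-beta concentration; lambda_a is the plain
    apoptosis rate of myofibroblasts and macrophages; lambda_immune_random is
    the Poisson intensity of macrophage appearance per unit wound-edge length
    per unit time.
    """

    lambda_d: float = 2.0
    lambda_a: float = 10.0
    lambda_diff: float = 1.0
    lambda_immune_random: float = 0.04
    W_half: float = 1.0                # strain-energy saturation scale for division

    def __post_init__(self) -> None:
        for name in ("lambda_d", "lambda_a", "lambda_diff", "lambda_immune_random"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MigrationParams:
    s_cell: float = 1.0       # speed of biased movement
    alpha_rho: float = 1.0    # density scaling of the chemotaxis weight
    gamma: float = 1e-3       # gradient regularizer (keeps denominators positive)
    sigma_rw: float = 0.0     # random-walk amplitude
    interaction: Callable | None = None   # optional drift hook f(cell, cells) -> (2,)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.sigma_rw < 0:
            raise ValueError("sigma_rw must be non-negative")


def event_probability(rate: float, dt: float) -> float:
    """Per-step firing probability of an exponential clock: 1 - exp(-rate*dt)."""
    return -np.expm1(-rate * dt)


def cell_boundary_forces(
    cells: Sequence[Cell], magnitudes: dict[str, float]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Four inward point loads per (myo)fibroblast: [(point, force), ...].

    ``magnitudes`` maps phenotype to the traction density P (force/length);
    macrophages contribute nothing.
    """
    loads: list[tuple[np.ndarray, np.ndarray]] = []
    for cell in cells:
        if not cell.alive or cell.phenotype == MACROPHAGE:
            continue
        P = magnitudes[cell.phenotype]
        mag = P * 2.0 * cell.R
        x, y = cell.center
        R = cell.R
        loads.append((np.array([x + R, y]), np.array([-mag, 0.0])))
        loads.append((np.array([x - R, y]), np.array([mag, 0.0])))
        loads.append((np.array([x, y + R]), np.array([0.0, -mag])))
        loads.append((np.array([x, y - R]), np.array([0.0, mag])))
    return loads


def chemotaxis_weight(rho_f: float, rho_c: float, s_cell: float, alpha_rho: float):
    """mu_c = s_cell * (1 - alpha_rho*(rho_f + rho_c)/2), floored at zero."""
    return np.maximum(0.0, s_cell * (1.0 - alpha_rho * (np.asarray(rho_f) + rho_c) / 2.0))


def _reflect(point: np.ndarray, mesh: Mesh, margin: float = 0.0) -> np.ndarray:
    """Reflect a proposed centre back into the domain at the outer boundary.

    ``margin`` keeps the centre at least a cell radius away from the edge so
    the whole square boundary (and its traction points) stays inside.
    """
    out = point.copy()
    for d, half_full in ((0, mesh.x0 / 2), (1, mesh.y0 / 2)):
        half = half_full - margin
        if out[d] > half:
            out[d] = 2 * half - out[d]
        elif out[d] < -half:
            out[d] = -2 * half - out[d]
        out[d] = min(max(out[d], -half), half)
    return out


def _drift_step(
    cell: Cell,
    chemo_drift: np.ndarray,
    v_sub: np.ndarray,
    params: MigrationParams,
    dt: float,
    rng: np.random.Generator,
    cells: Sequence[Cell] | None,
    mesh: Mesh,
) -> np.ndarray:
    dr = chemo_drift * dt + v_sub * dt
    if params.interaction is not None:
        dr = dr + np.asarray(params.interaction(cell, cells)) * dt
    if params.sigma_rw > 0:
        dr = dr + params.sigma_rw * rng.normal(0.0, np.sqrt(dt), size=2)
    new = _reflect(cell.center + dr, mesh, margin=cell.R)
    # active displacement: total step minus the passive convection part
    active = (new - cell.center) - v_sub * dt
    norm = np.linalg.norm(active)
    if norm > 0:
        cell.r_N = active / norm
    cell.center = new
    return new


def migrate_macrophage(
    cell: Cell,
    grad_c_pdgf: np.ndarray,
    v_sub: np.ndarray,
    mu_c: float,
    params: MigrationParams,
    dt: float,
    rng: np.random.Generator,
    mesh: Mesh,
    cells: Sequence[Cell] | None = None,
) -> np.ndarray:
    """Euler-Maruyama step of the macrophage SDE (PDGF chemotaxis)."""
    g = np.asarray(grad_c_pdgf, float)
    drift = mu_c * g / (np.linalg.norm(g) + params.gamma)
    return _drift_step(cell, drift, v_sub, params, dt, rng, cells, mesh)


def migrate_fibroblast(
    cell: Cell,
    grad_c_tgf: np.ndarray,
    omega_c: np.ndarray,
    rho_c: float,
    v_sub: np.ndarray,
    mu_c: float,
    params: MigrationParams,
    dt: float,
    rng: np.random.Generator,
    mesh: Mesh,
    cells: Sequence[Cell] | None = None,
) -> np.ndarray:
    """(Myo)fibroblast step: TGF-beta chemotaxis steered by collagen orientation.

    The drift applies the matrix ``[1 - a_rho*rho_c] I + a_rho*rho_c*Omega_hat``
    to the regularized gradient direction, with ``Omega_hat`` the unit-trace
    normalization of the local collagen tensor (isotropic fallback when its
    trace vanishes).  For ``a_rho*rho_c`` in [0, 1] this is a convex blend of
    isotropic chemotaxis and fiber-aligned guidance.
    """
    g = np.asarray(grad_c_tgf, float)
    w = params.alpha_rho * rho_c
    tr = omega_c[0] + omega_c[1]
    mat = (1.0 - w) * np.eye(2)
    if tr > 0:
        hat = np.array([[omega_c[0], omega_c[2]], [omega_c[2], omega_c[1]]]) / tr
        mat = mat + w * hat
    drift = mu_c * (mat @ g) / (np.linalg.norm(g) + params.gamma)
    return _drift_step(cell, drift, v_sub, params, dt, rng, cells, mesh)


@dataclass
class PopulationDelta:
    divided: int = 0
    differentiated: int = 0
    died: int = 0
    immigrated: int = 0


class CellPopulation:
    """Mutable cell collection with the per-step event/migration schedule.

    Event ordering within a step is fixed (influx, differentiation, division,
    apoptosis, migration) so that runs with a shared seed are bit-reproducible.
    """

    def __init__(self, mesh: Mesh, cells: list[Cell], rates: CellEventRates,
                 migration: MigrationParams, rng: np.random.Generator):
        self.mesh = mesh
        self.cells = list(cells)
        self.rates = rates
        self.migration = migration
        self.rng = rng

    def counts(self) -> dict[str, int]:
        out = {FIBROBLAST: 0, MYOFIBROBLAST: 0, MACROPHAGE: 0}
        for c in self.cells:
            if c.alive:
                out[c.phenotype] += 1
        return out

    # -- events ------------------------------------------------------------

    def _wound_edge_points(self, n: int) -> np.ndarray:
        """Uniform random positions on the wound rectangle boundary."""
        a, b = self.mesh.xw / 2, self.mesh.yw / 2
        perim = 4 * a + 4 * b
        s = self.rng.uniform(0.0, perim, size=n)
        pts = np.empty((n, 2))
        for i, si in enumerate(s):
            if si < 2 * a:
                pts[i] = (-a + si, -b)
            elif si < 2 * a + 2 * b:
                pts[i] = (a, -b + (si - 2 * a))
            elif si < 4 * a + 2 * b:
                pts[i] = (a - (si - 2 * a - 2 * b), b)
            else:
                pts[i] = (-a, b - (si - 4 * a - 2 * b))
        return pts

    def sample_events(
        self,
        dt: float,
        t: float,
        c_tgf_at: Callable[[np.ndarray], np.ndarray] | None = None,
        energy_at: Callable[[np.ndarray], np.ndarray] | None = None,
        cell_radius: float | None = None,
    ) -> PopulationDelta:
        """Fire influx/differentiation/division/apoptosis for one step."""
        rng = self.rng
        rates = self.rates
        delta = PopulationDelta()

        # 1. macrophage influx: Poisson along the wound edge
        edge_len = 2 * (self.mesh.xw + self.mesh.yw)
        lam = rates.lambda_immune_random * dt * edge_len
        n_new = rng.poisson(lam) if lam > 0 else 0
        if n_new:
            R = cell_radius if cell_radius is not None else (
                self.cells[0].R if self.cells else min(self.mesh.hx, self.mesh.hy) / 4
            )
            for p in self._wound_edge_points(n_new):
                self.cells.append(Cell(center=p, phenotype=MACROPHAGE, R=R, birth_time=t))
            delta.immigrated = n_new

        alive = [c for c in self.cells if c.alive]

        # 2. differentiation (fibroblast -> myofibroblast), rate lambda_diff * c_TGF
        fibro = [c for c in alive if c.phenotype == FIBROBLAST]
        if fibro and rates.lambda_diff > 0 and c_tgf_at is not None:
            conc = np.maximum(0.0, c_tgf_at(np.array([c.center for c in fibro])))
            p = 1.0 - np.exp(-rates.lambda_diff * conc * dt)
            fire = rng.random(len(fibro)) < p
            for c, f in zip(fibro, fire):
                if f:
                    c.phenotype = MYOFIBROBLAST
                    delta.differentiated += 1

        # 3. division of (remaining) regular fibroblasts, rate ~ strain energy
        fibro = [c for c in alive if c.phenotype == FIBROBLAST]
        if fibro and rates.lambda_d > 0 and energy_at is not None:
            W = np.maximum(0.0, energy_at(np.array([c.center for c in fibro])))
            rate = rates.lambda_d * W / (W + rates.W_half)
            p = 1.0 - np.exp(-rate * dt)
            fire = rng.random(len(fibro)) < p
            for c, f in zip(fibro, fire):
                if f:
                    daughter = self._place_daughter(c, t)
                    self.cells.append(daughter)
                    delta.divided += 1

        # 4. apoptosis of myofibroblasts and macrophages
        mortal = [c for c in alive if c.phenotype in (MYOFIBROBLAST, MACROPHAGE)]
        if mortal and rates.lambda_a > 0:
            p = event_probability(rates.lambda_a, dt)
            fire = rng.random(len(mortal)) < p
            for c, f in zip(mortal, fire):
                if f:
                    c.alive = False
                    delta.died += 1
        self.cells = [c for c in self.cells if c.alive]
        return delta

    def _place_daughter(self, parent: Cell, t: float) -> Cell:
        for _ in range(100):
            theta = self.rng.uniform(0.0, 2 * np.pi)
            pos = parent.center + 2 * parent.R * np.array([np.cos(theta), np.sin(theta)])
            if (abs(pos[0]) <= self.mesh.x0 / 2 - parent.R
                    and abs(pos[1]) <= self.mesh.y0 / 2 - parent.R):
                return Cell(center=pos, phenotype=FIBROBLAST, R=parent.R, birth_time=t)
        return Cell(center=parent.center.copy(), phenotype=FIBROBLAST, R=parent.R, birth_time=t)
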