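"""Scenario presets and deterministic fixtures.

Two unit presets are provided, mirroring the two study settings:

* ``sensitivity_preset`` — cm-g-day units; domain 0.2 x 0.2 cm with a
  0.04 x 0.04 cm wound, time step 0.02 day; mechanics parameters E_s = 31,
  nu = 0.48, eta = 1, mu1 = mu2 = 100, rho = 1.02, alpha = 0.2, traction
  density P = 200.  Cells are identical, at fixed positions strictly inside
  the wound, exerting traction on [0, 5) day.  Used for the one-at-a-time
  parameter sweeps.

* ``comparison_preset`` — micrometre-kg-hour units; domain 120 x 80 um with a
  40 x 30 um wound, time step 0.1 h; E_s = 100, nu = 0.48, eta = 10,
  mu1 = 16.89, mu2 = 11.26, cell radius R = 2.5 um, P_f = 2.08, P_m = 10.4,
  plastic force Q = 33, alpha = 0.01/h.  Used for the two-backend comparison
  and the Monte Carlo study, with the full stochastic cell layer.

Values not fixed by either setting (cytokine diffusion/decay, migration
speeds, event-rate coefficients) are configuration defaults documented here
and in the methods note; they are deliberately diffusion-dominated and small
enough that transport stays oscillation-free on the default meshes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .agents import Cell, CellEventRates, MigrationParams, FIBROBLAST, MYOFIBROBLAST
from .chemistry import CytokineParams, PDGF, TGF, TPA

__all__ = [
    "Geometry",
    "MechanicsConfig",
    "CellLayout",
    "Scenario",
    "sensitivity_preset",
    "comparison_preset",
    "tiny_preset",
]


@dataclass
class Geometry:
    x0: float
    y0: float
    xw: float
    yw: float
    nx: int
    ny: int


@dataclass
class MechanicsConfig:
    E_s: float
    nu: float
    eta: float
    mu1: float
    mu2: float
    rho: float
    alpha: float        # morphoelastic permanent-deformation rate
    Q: float            # phenomenological plastic force magnitude
    backend: str = "morpho"   # "morpho" | "phenom"


@dataclass
class CellLayout:
    """Initial cell placement.

    ``mode = "fixed_grid"``: an n x n grid of identical non-dividing,
    non-migrating cells centred in the wound (the deterministic sensitivity
    layout).  ``mode = "stochastic"``: fibroblasts seeded on a jittered grid
    over the healthy skin at the given number; the full event/migration layer
    then runs on top.
    """

    mode: str = "fixed_grid"
    grid_n: int = 3
    radius: float = 2.5e-4
    phenotype: str = MYOFIBROBLAST
    n_fibroblasts: int = 30        # stochastic mode


@dataclass
class Scenario:
    name: str
    geometry: Geometry
    mechanics: MechanicsConfig
    cells: CellLayout
    traction: dict[str, float]              # phenotype -> P (force per length)
    dt: float
    t_final: float
    force_window: tuple[float, float] = (0.0, math.inf)
    seed: int = 0
    enable_chemistry: bool = False
    enable_fibers: bool = False
    enable_cell_dynamics: bool = False
    cytokines: dict[str, CytokineParams] = field(default_factory=dict)
    rates: CellEventRates = field(default_factory=CellEventRates)
    migration: MigrationParams = field(default_factory=MigrationParams)
    alpha_rho: float = 1.0
    delta_rho: float = 0.5
    checkpoint_time: float = 4.0            # "early" readout time for MC outputs
    polygon_points_per_side: int = 24
    stop_after_equilibrium: bool = True

    def with_overrides(self, **kw) -> "Scenario":
        mech_keys = {k: v for k, v in kw.items()
                     if k in MechanicsConfig.__dataclass_fields__}
        rest = {k: v for k, v in kw.items() if k not in mech_keys}
        sc = replace(self, **rest)
        if mech_keys:
            sc = replace(sc, mechanics=replace(self.mechanics, **mech_keys))
        return sc


def initial_cells(scenario: Scenario, rng: np.random.Generator) -> list[Cell]:
    geo = scenario.geometry
    lay = scenario.cells
    if lay.mode == "fixed_grid":
        n = lay.grid_n
        # centred grid strictly inside the wound rectangle
        xs = np.linspace(-geo.xw / 2, geo.xw / 2, n + 2)[1:-1]
        ys = np.linspace(-geo.yw / 2, geo.yw / 2, n + 2)[1:-1]
        return [
            Cell(center=np.array([x, y]), phenotype=lay.phenotype, R=lay.radius)
            for y in ys for x in xs
        ]
    if lay.mode == "stochastic":
        cells: list[Cell] = []
        count = 0
        while count < lay.n_fibroblasts:
            # keep the whole cell square (and its traction points) inside
            p = rng.uniform([-geo.x0 / 2 + lay.radius, -geo.y0 / 2 + lay.radius],
                            [geo.x0 / 2 - lay.radius, geo.y0 / 2 - lay.radius])
            if abs(p[0]) <= geo.xw / 2 and abs(p[1]) <= geo.yw / 2:
                continue       # healthy region only
            cells.append(Cell(center=p, phenotype=FIBROBLAST, R=lay.radius))
            count += 1
        return cells
    raise ValueError(f"unknown cell layout mode {lay.mode!r}")


def sensitivity_preset(**overrides) -> Scenario:
    """Deterministic cm-g-day sweep scenario (fixed cells, forces on [0, 5) day)."""
    sc = Scenario(
        name="sensitivity",
        geometry=Geometry(x0=0.2, y0=0.2, xw=0.04, yw=0.04, nx=20, ny=20),
        mechanics=MechanicsConfig(
            E_s=31.0, nu=0.48, eta=1.0, mu1=100.0, mu2=100.0,
            rho=1.02, alpha=0.2, Q=0.0, backend="morpho",
        ),
        cells=CellLayout(mode="fixed_grid", grid_n=3, radius=2.5e-4,
                         phenotype=MYOFIBROBLAST),
        traction={FIBROBLAST: 200.0, MYOFIBROBLAST: 200.0},
        dt=0.02,
        t_final=40.0,
        force_window=(0.0, 5.0),
    )
    return sc.with_overrides(**overrides)


def _micro_cytokines() -> dict[str, CytokineParams]:
    # diffusion-dominated defaults on the 120 x 80 um domain over tens of hours
    return {
        PDGF: CytokineParams(D=60.0, kappa=0.02, decay=0.05),
        TGF: CytokineParams(D=60.0, kappa=0.02, decay=0.1, k_secretion=10.0),
        TPA: CytokineParams(D=30.0, kappa=0.02, decay=0.1),
    }


def comparison_preset(**overrides) -> Scenario:
    """Stochastic um-kg-h scenario for the backend comparison and Monte Carlo."""
    sc = Scenario(
        name="comparison",
        geometry=Geometry(x0=120.0, y0=80.0, xw=40.0, yw=30.0, nx=24, ny=16),
        mechanics=MechanicsConfig(
            E_s=100.0, nu=0.48, eta=10.0, mu1=16.89, mu2=11.26,
            # Table 2's ECM density 1.02 g/cm^3 in um-kg-h units (unit thickness):
            rho=1.02e-15, alpha=0.01, Q=33.0, backend="morpho",
        ),
        cells=CellLayout(mode="stochastic", radius=2.5, n_fibroblasts=30),
        traction={FIBROBLAST: 2.08, MYOFIBROBLAST: 10.4},
        dt=0.1,
        t_final=20.0,
        enable_chemistry=True,
        enable_fibers=True,
        enable_cell_dynamics=True,
        cytokines=_micro_cytokines(),
        rates=CellEventRates(lambda_d=2.0, lambda_a=10.0, lambda_diff=2.0,
                             lambda_immune_random=0.04, W_half=1.0),
        # fibroblast biased speed ~5 um/h; gamma far below typical gradient
        # magnitudes so chemotaxis is direction- not magnitude-limited
        migration=MigrationParams(s_cell=5.0, alpha_rho=1.0, gamma=1e-6,
                                  sigma_rw=0.3),
        alpha_rho=1.0,
        delta_rho=0.5,
        checkpoint_time=4.0,
    )
    return sc.with_overrides(**overrides)


def tiny_preset(**overrides) -> Scenario:
    """Small fast scenario for tests: coarse mesh, short horizon."""
    sc = comparison_preset(t_final=2.0)
    sc = replace(sc, name="tiny",
                 geometry=Geometry(x0=120.0, y0=80.0, xw=40.0, yw=20.0, nx=12, ny=8),
                 cells=replace(sc.cells, n_fibroblasts=8))
    return sc.with_overrides(**overrides)
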