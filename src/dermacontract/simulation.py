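"""Coupled time-stepping driver binding mechanics, chemistry, fibers, agents.

One :class:`Simulation` owns a mesh, one mechanics backend (phenomenological
or morphoelastic), the cytokine fields, the fibrin/collagen tensors, the cell
population, and the tracked wound polygon.  The per-step schedule is fixed:

1. assemble cellular traction loads (only inside the force window),
2. mark plastic edges / advance the mechanics backend,
3. advance the cytokines with the substrate velocity,
4. degrade fibrin, deposit collagen along the cells' active directions,
5. fire cell events and migrate cells,
6. advect the wound polygon and record the scar series.

A run can record its per-step traction history and plastic occupancy, and a
second run can replay that history — this is how the two backends are
compared on identical force histories with a shared seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fem
from .agents import (MACROPHAGE, MYOFIBROBLAST, FIBROBLAST, CellPopulation,
                     cell_boundary_forces, chemotaxis_weight,
                     migrate_fibroblast, migrate_macrophage)
from .chemistry import PDGF, TGF, TPA, CytokineSolver, init_cytokines
from .fibers import FiberSolver, density, init_fiber_tensors
from .mechanics_morpho import MorphoMechanics, MorphoParams
from .mechanics_phenom import PhenomMechanics, PhenomParams
from .mesh import build_rect_mesh
from .observables import ScarSeries, WoundPolygon, collagen_ratio, t_end_of, t_min_of
from .scenarios import Scenario, initial_cells

__all__ = ["Simulation", "ForceHistory", "run_scenario"]


@dataclass
class ForceHistory:
    """Recorded per-step assembled traction loads and myofibroblast occupancy."""

    loads: list[np.ndarray] = field(default_factory=list)
    myofibro_elements: list[np.ndarray] = field(default_factory=list)


class Simulation:
    def __init__(self, scenario: Scenario, backend: str | None = None,
                 replay: ForceHistory | None = None, record: bool = False):
        self.sc = scenario
        geo = scenario.geometry
        self.mesh = build_rect_mesh(geo.x0, geo.y0, geo.nx, geo.ny, geo.xw, geo.yw)
        self.rng = np.random.default_rng(scenario.seed)
        mech = scenario.mechanics
        name = backend or mech.backend
        if name == "morpho":
            self.backend = MorphoMechanics(self.mesh, MorphoParams(
                E_s=mech.E_s, nu=mech.nu, eta=mech.eta, mu1=mech.mu1,
                mu2=mech.mu2, rho=mech.rho, alpha=mech.alpha, dt=scenario.dt))
        elif name == "phenom":
            self.backend = PhenomMechanics(self.mesh, PhenomParams(
                E_s=mech.E_s, nu=mech.nu, eta=mech.eta, mu1=mech.mu1,
                mu2=mech.mu2, Q=mech.Q, dt=scenario.dt))
        else:
            raise ValueError(f"unknown mechanics backend {name!r}")

        self.cells = initial_cells(scenario, self.rng)
        self.population = CellPopulation(self.mesh, self.cells, scenario.rates,
                                         scenario.migration, self.rng)
        self.polygon = WoundPolygon(
            self.mesh.wound_boundary_polygon(scenario.polygon_points_per_side))
        self.series = ScarSeries()
        self.t = 0.0
        self.step_count = 0

        self.replay = replay
        self.history = ForceHistory() if record else None

        if scenario.enable_chemistry:
            self.chem_solver = CytokineSolver(self.mesh)
            self.cytokines = init_cytokines(self.mesh, scenario.cytokines or None)
        else:
            self.chem_solver = None
            self.cytokines = None
        if scenario.enable_fibers:
            self.fiber_solver = FiberSolver(self.mesh)
            self.fibrin, self.collagen = init_fiber_tensors(self.mesh, scenario.alpha_rho)
        else:
            self.fiber_solver = None
            self.fibrin = self.collagen = None

        self._static_load: np.ndarray | None = None
        self._record_initial()

    # -- helpers -----------------------------------------------------------

    def _record_initial(self) -> None:
        rho_hat = np.nan
        if self.collagen is not None:
            rho_hat = collagen_ratio(self.mesh, self.collagen.omega, self.polygon,
                                     1.0 / self.sc.alpha_rho)
        counts = self.population.counts()
        self.series.record(0.0, self.polygon.area(), rho_hat,
                           counts[FIBROBLAST], counts[MYOFIBROBLAST], counts[MACROPHAGE])

    def _in_force_window(self) -> bool:
        lo, hi = self.sc.force_window
        return lo <= self.t < hi

    def _assemble_traction(self) -> np.ndarray:
        if not self._in_force_window():
            self._static_load = None
            return np.zeros(2 * self.mesh.n_nodes)
        static_cells = self.sc.cells.mode == "fixed_grid" and not self.sc.enable_cell_dynamics
        if static_cells and self._static_load is not None:
            return self._static_load
        F = np.zeros(2 * self.mesh.n_nodes)
        for point, force in cell_boundary_forces(self.population.cells, self.sc.traction):
            F += fem.assemble_point_load(self.mesh, point, force)
        if static_cells:
            self._static_load = F
        return F

    def _rho_total_at(self, points: np.ndarray) -> np.ndarray:
        tot = self.fibrin.omega + self.collagen.omega
        return self.mesh.interpolate(density(tot), points)

    # -- stepping ----------------------------------------------------------

    def step(self) -> None:
        sc = self.sc
        dt = sc.dt
        # 1/2. forces and mechanics
        if self.replay is not None:
            k = self.step_count
            f_t = (self.replay.loads[k] if k < len(self.replay.loads)
                   else np.zeros(2 * self.mesh.n_nodes))
            if isinstance(self.backend, PhenomMechanics) and k < len(self.replay.myofibro_elements):
                for el in self.replay.myofibro_elements[k]:
                    for e in range(3):
                        self.backend.state.active_edges.add((int(el), e))
        else:
            f_t = self._assemble_traction()
            if isinstance(self.backend, PhenomMechanics) and self.sc.mechanics.Q > 0:
                self.backend.mark_plastic_edges(self.population.cells)
        if self.history is not None:
            self.history.loads.append(f_t.copy())
            myos = [c.center for c in self.population.cells
                    if c.alive and c.phenotype == MYOFIBROBLAST]
            if myos:
                tri, _ = self.mesh.locate(np.asarray(myos))
                self.history.myofibro_elements.append(np.unique(tri))
            else:
                self.history.myofibro_elements.append(np.empty(0, int))
        self.backend.step(f_t)
        v_sub = self.backend.velocity

        # 3. cytokines
        if self.chem_solver is not None:
            macro_sources = [
                (c.center, self.cytokines[TGF].params.k_secretion)
                for c in self.population.cells
                if c.alive and c.phenotype == MACROPHAGE
            ] or None
            self.chem_solver.step(self.cytokines[PDGF], dt, v_sub)
            self.chem_solver.step(self.cytokines[TGF], dt, v_sub, macro_sources)
            self.chem_solver.step(self.cytokines[TPA], dt, v_sub)

        # 4. fibers
        if self.fiber_solver is not None:
            c_tpa = (self.cytokines[TPA].c if self.cytokines is not None
                     else np.zeros(self.mesh.n_nodes))
            self.fibrin.delta_rho = sc.delta_rho
            self.fiber_solver.step_fibrin(self.fibrin, c_tpa, dt, v_sub)
            self.fiber_solver.deposit_collagen(
                self.collagen, self.population.cells, self._rho_total_at, dt, v_sub)

        # 5. cell events and migration
        if sc.enable_cell_dynamics and self.replay is None:
            self._cell_step(v_sub, dt)

        # 6. observables
        self.t += dt
        self.step_count += 1
        self.polygon.advect(self.backend.displacement_increment_at)
        rho_hat = np.nan
        if self.collagen is not None:
            rho_hat = collagen_ratio(self.mesh, self.collagen.omega, self.polygon,
                                     1.0 / sc.alpha_rho)
        counts = self.population.counts()
        self.series.record(self.t, self.polygon.area(), rho_hat,
                           counts[FIBROBLAST], counts[MYOFIBROBLAST], counts[MACROPHAGE])

    def _cell_step(self, v_sub: np.ndarray, dt: float) -> None:
        sc = self.sc
        c_tgf_at = None
        if self.cytokines is not None:
            tgf = self.cytokines[TGF].c
            c_tgf_at = lambda pts: self.mesh.interpolate(tgf, pts)  # noqa: E731
        self.population.sample_events(
            dt, self.t,
            c_tgf_at=c_tgf_at,
            energy_at=self.backend.strain_energy_density,
            cell_radius=sc.cells.radius,
        )
        vn = v_sub.reshape(-1, 2)
        for cell in self.population.cells:
            if not cell.alive:
                continue
            v_here = self.mesh.interpolate(vn, cell.center[None])[0]
            if self.fibrin is not None:
                rho_f = self.mesh.interpolate(density(self.fibrin.omega), cell.center[None])[0]
                rho_c = self.mesh.interpolate(density(self.collagen.omega), cell.center[None])[0]
                omega_c = self.mesh.interpolate(self.collagen.omega, cell.center[None])[0]
            else:
                rho_f = rho_c = 0.0
                omega_c = np.zeros(3)
            mu_c = float(chemotaxis_weight(rho_f, rho_c, sc.migration.s_cell,
                                           sc.migration.alpha_rho))
            if cell.phenotype == MACROPHAGE:
                grad = (self.mesh.gradient_at(self.cytokines[PDGF].c, cell.center[None])[0]
                        if self.cytokines is not None else np.zeros(2))
                migrate_macrophage(cell, grad, v_here, mu_c, sc.migration, dt,
                                   self.rng, self.mesh, self.population.cells)
            else:
                grad = (self.mesh.gradient_at(self.cytokines[TGF].c, cell.center[None])[0]
                        if self.cytokines is not None else np.zeros(2))
                migrate_fibroblast(cell, grad, omega_c, rho_c, v_here, mu_c,
                                   sc.migration, dt, self.rng, self.mesh,
                                   self.population.cells)

    # -- run loop ----------------------------------------------------------

    def run(self, check_every: int = 100) -> ScarSeries:
        """Step to t_final, optionally stopping once the scar re-equilibrates."""
        n_steps = int(round(self.sc.t_final / self.sc.dt))
        for _ in range(n_steps - self.step_count):
            self.step()
            if (self.sc.stop_after_equilibrium
                    and self.step_count % check_every == 0
                    and self.t > self.sc.force_window[1]):
                t_end, converged = t_end_of(self.series)
                if converged and self.t > t_end + 2 * self.sc.dt:
                    break
        return self.series

    # -- summary -----------------------------------------------------------

    def summary(self) -> dict[str, float]:
        s = self.series
        t_min = t_min_of(s)
        t_end, converged = t_end_of(s)
        t_arr = np.asarray(s.times)
        A = np.asarray(s.areas)
        out = {
            "t_min": t_min,
            "t_end": t_end,
            "t_end_converged": float(converged),
            "area_min": float(A[np.argwhere(t_arr == t_min)[0, 0]]),
            "area_final": float(A[np.argwhere(t_arr == t_end)[0, 0]]),
            "r_min": float(A[np.argwhere(t_arr == t_min)[0, 0]] / A[0]),
            "r_final": float(A[np.argwhere(t_arr == t_end)[0, 0]] / A[0]),
        }
        # early checkpoint
        tc = min(self.sc.checkpoint_time, t_arr[-1])
        ic = int(np.argmin(np.abs(t_arr - tc)))
        out["area_checkpoint"] = float(A[ic])
        rho = np.asarray(s.rho_hat)
        if np.isfinite(rho).any():
            out["rho_hat_final"] = float(rho[np.argwhere(t_arr == t_end)[0, 0]])
            out["rho_hat_min"] = float(rho[np.argwhere(t_arr == t_min)[0, 0]])
            out["rho_hat_checkpoint"] = float(rho[ic])
            for thr in (0.5, 0.8):
                above = np.flatnonzero(rho > thr)
                if len(above):
                    out[f"t_rho_{thr}"] = float(t_arr[above[0]])
                    out[f"area_rho_{thr}"] = float(A[above[0]])
                else:
                    out[f"t_rho_{thr}"] = float("nan")
                    out[f"area_rho_{thr}"] = float("nan")
        return out


def run_scenario(scenario: Scenario, backend: str | None = None) -> tuple[ScarSeries, dict]:
    sim = Simulation(scenario, backend=backend)
    sim.run()
    return sim.series, sim.summary()
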