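import numpy as np
import pytest

from dermacontract.agents import (Cell, CellEventRates, CellPopulation,
                                  MigrationParams, cell_boundary_forces,
                                  chemotaxis_weight, event_probability,
                                  migrate_fibroblast, migrate_macrophage)
from dermacontract.mesh import build_rect_mesh


@pytest.fixture(scope="module")
def micro_mesh():
    return build_rect_mesh(120.0, 80.0, 24, 16, 40.0, 30.0)


TRACTION = {"fibroblast": 2.08, "myofibroblast": 10.4}


class TestBoundaryForces:
    def test_fibroblast_four_loads_of_p_times_side(self):
        cell = Cell(center=[0.0, 0.0], phenotype="fibroblast", R=2.5)
        loads = cell_boundary_forces([cell], TRACTION)
        assert len(loads) == 4
        for _, f in loads:
            assert np.linalg.norm(f) == pytest.approx(2.08 * 5.0)  # = 10.4

    def test_loads_point_inward_and_cancel(self):
        cell = Cell(center=[3.0, -2.0], phenotype="myofibroblast", R=2.5)
        loads = cell_boundary_forces([cell], TRACTION)
        total = sum(f for _, f in loads)
        assert np.allclose(total, 0.0, atol=1e-12)
        for p, f in loads:
            inward = cell.center - p
            assert np.dot(f, inward) > 0

    def test_macrophage_exerts_no_force(self):
        cell = Cell(center=[0.0, 0.0], phenotype="macrophage", R=2.5)
        assert cell_boundary_forces([cell], TRACTION) == []

    def test_dead_cells_skipped(self):
        cell = Cell(center=[0.0, 0.0], phenotype="fibroblast", R=2.5, alive=False)
        assert cell_boundary_forces([cell], TRACTION) == []


class TestChemotaxisWeight:
    def test_zero_density_full_speed(self):
        assert chemotaxis_weight(0.0, 0.0, 3.0, 1.0) == 3.0

    def test_initial_total_density_halves_speed(self):
        # rho_f + rho_c = 1/alpha_rho at t = 0 (trace of the initial tensors)
        alpha_rho = 2.0
        assert chemotaxis_weight(0.25, 0.25, 3.0, alpha_rho) == pytest.approx(1.5)

    def test_saturation_clips_to_zero(self):
        assert chemotaxis_weight(1.5, 0.6, 3.0, 1.0) == 0.0


class TestMigration:
    def test_all_terms_zero_center_unchanged(self, micro_mesh, rng):
        cell = Cell(center=[10.0, 5.0], phenotype="macrophage", R=2.5)
        p = MigrationParams(sigma_rw=0.0)
        migrate_macrophage(cell, np.zeros(2), np.zeros(2), 1.0, p, 0.1, rng, micro_mesh)
        assert np.allclose(cell.center, [10.0, 5.0])

    def test_pure_convection_step(self, micro_mesh, rng):
        cell = Cell(center=[0.0, 0.0], phenotype="macrophage", R=2.5)
        p = MigrationParams(sigma_rw=0.0)
        migrate_macrophage(cell, np.zeros(2), np.array([3.0, -1.0]), 1.0, p, 0.1,
                           rng, micro_mesh)
        assert np.allclose(cell.center, [0.3, -0.1], atol=1e-14)

    def test_pure_convection_keeps_previous_direction(self, micro_mesh, rng):
        cell = Cell(center=[0.0, 0.0], phenotype="fibroblast", R=2.5,
                    r_N=np.array([0.0, 1.0]))
        p = MigrationParams(sigma_rw=0.0)
        migrate_fibroblast(cell, np.zeros(2), np.zeros(3), 0.0,
                           np.array([2.0, 0.0]), 1.0, p, 0.1, rng, micro_mesh)
        assert np.allclose(cell.r_N, [0.0, 1.0])   # active displacement was zero

    def test_strong_gradient_saturates_to_mu_c(self, micro_mesh, rng):
        cell = Cell(center=[0.0, 0.0], phenotype="macrophage", R=2.5)
        p = MigrationParams(gamma=1e-6, sigma_rw=0.0)
        grad = np.array([1e4, 0.0])
        mu_c, dt = 2.0, 0.1
        migrate_macrophage(cell, grad, np.zeros(2), mu_c, p, dt, rng, micro_mesh)
        assert np.allclose(cell.center, [mu_c * dt, 0.0], rtol=1e-6)
        assert np.allclose(cell.r_N, [1.0, 0.0])

    def test_collagen_matrix_projects_step(self, micro_mesh, rng):
        """alpha_rho*rho_c = 1 with Omega_hat = e1 e1^T projects onto e1."""
        cell = Cell(center=[0.0, 0.0], phenotype="fibroblast", R=2.5)
        p = MigrationParams(alpha_rho=1.0, gamma=1e-6, sigma_rw=0.0)
        omega_c = np.array([5.0, 0.0, 0.0])         # trace 5, pure-xx
        grad = np.array([1.0, 1.0]) * 1e3
        migrate_fibroblast(cell, grad, omega_c, 1.0, np.zeros(2), 1.0, p, 0.1,
                           rng, micro_mesh)
        assert abs(cell.center[1]) < 1e-9           # e2 component suppressed
        assert cell.center[0] > 0

    def test_zero_collagen_reduces_to_isotropic(self, micro_mesh, rng):
        cell_a = Cell(center=[0.0, 0.0], phenotype="fibroblast", R=2.5)
        cell_b = Cell(center=[0.0, 0.0], phenotype="macrophage", R=2.5)
        p = MigrationParams(gamma=1e-6, sigma_rw=0.0)
        grad = np.array([10.0, -4.0])
        migrate_fibroblast(cell_a, grad, np.zeros(3), 0.0, np.zeros(2), 1.5, p,
                           0.1, rng, micro_mesh)
        migrate_macrophage(cell_b, grad, np.zeros(2), 1.5, p, 0.1, rng, micro_mesh)
        assert np.allclose(cell_a.center, cell_b.center, atol=1e-14)

    def test_reflection_keeps_cell_square_inside(self, micro_mesh, rng):
        cell = Cell(center=[59.0, 0.0], phenotype="macrophage", R=2.5)
        p = MigrationParams(sigma_rw=0.0)
        migrate_macrophage(cell, np.zeros(2), np.array([100.0, 0.0]), 1.0, p,
                           0.1, rng, micro_mesh)
        assert cell.center[0] <= 60.0 - 2.5


class TestEvents:
    def test_event_probability_closed_form(self):
        assert event_probability(10.0, 0.1) == pytest.approx(1 - np.exp(-1), abs=1e-12)
        assert event_probability(0.0, 0.1) == 0.0

    def test_zero_rates_nothing_happens(self, micro_mesh):
        cells = [Cell(center=[0.0, 0.0], phenotype="myofibroblast", R=2.5)]
        pop = CellPopulation(
            micro_mesh, cells,
            CellEventRates(lambda_d=0, lambda_a=0, lambda_diff=0,
                           lambda_immune_random=0),
            MigrationParams(), np.random.default_rng(0))
        delta = pop.sample_events(0.1, 0.0)
        assert (delta.divided, delta.differentiated, delta.died, delta.immigrated) \
            == (0, 0, 0, 0)
        assert len(pop.cells) == 1

    def test_population_accounting(self, micro_mesh):
        rng = np.random.default_rng(5)
        cells = [Cell(center=rng.uniform(-30, 30, 2), phenotype="myofibroblast",
                      R=2.5) for _ in range(50)]
        pop = CellPopulation(micro_mesh, cells,
                             CellEventRates(lambda_a=3.0, lambda_d=0,
                                            lambda_diff=0,
                                            lambda_immune_random=0.04),
                             MigrationParams(), rng)
        for step in range(20):
            before = len(pop.cells)
            d = pop.sample_events(0.1, 0.1 * step)
            assert len(pop.cells) == before + d.immigrated + d.divided - d.died

    def test_seeded_runs_bit_reproducible(self, micro_mesh):
        def run(seed):
            rng = np.random.default_rng(seed)
            cells = [Cell(center=[5.0, 5.0], phenotype="myofibroblast", R=2.5)]
            pop = CellPopulation(micro_mesh, cells, CellEventRates(),
                                 MigrationParams(sigma_rw=0.5), rng)
            traj = []
            for k in range(50):
                pop.sample_events(0.1, 0.1 * k)
                for c in pop.cells:
                    migrate_macrophage(c, np.zeros(2), np.zeros(2), 0.0,
                                       pop.migration, 0.1, rng, micro_mesh)
                traj.append(sorted((c.phenotype, *c.center) for c in pop.cells))
            return traj
        assert run(42) == run(42)
        assert run(42) != run(43)

    def test_immigration_death_equilibrium(self, micro_mesh):
        """Macrophage count fluctuates around (influx * edge length)/lambda_a."""
        rates = CellEventRates(lambda_d=0, lambda_diff=0, lambda_a=2.0,
                               lambda_immune_random=0.01)
        rng = np.random.default_rng(7)
        pop = CellPopulation(micro_mesh, [], rates, MigrationParams(), rng)
        counts = []
        for k in range(6000):
            pop.sample_events(0.05, 0.05 * k, cell_radius=2.5)
            if k > 1000:
                counts.append(len(pop.cells))
        edge = 2 * (micro_mesh.xw + micro_mesh.yw)
        expected = rates.lambda_immune_random * edge / rates.lambda_a
        assert np.mean(counts) == pytest.approx(expected, rel=0.15)
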