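"""Phenomenological viscoelastic backend with permanent plastic edge forces.

Solves the quasi-static balance ``-div sigma = f_t + f_p`` for the
displacement u with homogeneous Dirichlet data, where sigma carries an elastic
part and an ``eta``-weighted viscous part acting on the displacement rate.
Plastic forces are constant-magnitude point loads on the edges of every mesh
element whose interior has ever contained a myofibroblast centre; once an
(element, edge) pair is activated it stays active — this permanence is what
leaves a residual (plastic) deformation after all cells have gone.

Backward-Euler in time: with elastic stiffness K_e and viscous stiffness K_v,

    (K_e + (eta/dt) K_v) u^{n+1} = F_t + F_p + (eta/dt) K_v u^n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fem
from .mesh import Mesh

__all__ = ["PhenomParams", "PhenomMechanics", "plastic_force_field"]


@dataclass
class PhenomParams:
    E_s: float          # Young's modulus of the ECM
    nu: float           # Poisson ratio
    eta: float          # weight of viscosity in viscoelasticity (dimensionless)
    mu1: float          # shear viscosity
    mu2: float          # bulk viscosity
    Q: float            # plastic force magnitude per edge length (>= 0)
    dt: float

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError("plastic force magnitude Q must be non-negative")
        for name in ("E_s", "eta", "mu1", "mu2", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def plastic_force_field(mesh: Mesh, active_edges, Q: float) -> np.ndarray:
    """Assembled load of the permanent plastic forces.

    Each active (element, edge) pair contributes one point load of magnitude
    ``Q * edge_length`` at the edge midpoint, directed along the inward normal
    (towards the element centroid).  An edge shared by two elements can carry
    two opposing loads, one per element, exactly as the elementwise double sum
    is written.
    """
    F = np.zeros(2 * mesh.n_nodes)
    for elem, edge in sorted(active_edges):
        a, b = mesh.element_edges(elem)[edge]
        pa, pb = mesh.nodes[a], mesh.nodes[b]
        mid = 0.5 * (pa + pb)
        tang = pb - pa
        length = float(np.hypot(*tang))
        centroid = mesh.nodes[mesh.triangles[elem]].mean(axis=0)
        normal = np.array([-tang[1], tang[0]]) / length
        if np.dot(normal, centroid - mid) < 0:     # orient towards centroid
            normal = -normal
        F += fem.assemble_point_load(mesh, mid, Q * length * normal)
    return F


@dataclass
class PhenomState:
    u: np.ndarray
    u_prev: np.ndarray
    active_edges: set = field(default_factory=set)  # {(element, edge_index)}


class PhenomMechanics:
    """Quasi-static viscoelastic solver with plastic edge-force bookkeeping."""

    backend_name = "phenom"

    def __init__(self, mesh: Mesh, params: PhenomParams):
        self.mesh = mesh
        self.params = params
        self.K_e = fem.elastic_stiffness(mesh, params.E_s, params.nu)
        self.K_v = params.eta * fem.viscous_stiffness(mesh, params.mu1, params.mu2)
        fixed = fem.vector_dirichlet_dofs(mesh)
        self._sys = fem.DirichletSystem(self.K_e + self.K_v / params.dt, fixed)
        self.state = PhenomState(
            u=np.zeros(2 * mesh.n_nodes), u_prev=np.zeros(2 * mesh.n_nodes)
        )
        self._fp_cache: np.ndarray | None = None
        self._fp_count = -1

    # -- plastic bookkeeping ----------------------------------------------

    def mark_plastic_edges(self, cells) -> None:
        """Activate all three edges of every element containing a myofibroblast.

        Activation is permanent: the set only ever grows.
        """
        centers = [c.center for c in cells if c.alive and c.phenotype == "myofibroblast"]
        if not centers:
            return
        tri, _ = self.mesh.locate(np.asarray(centers))
        for t in tri:
            for e in range(3):
                self.state.active_edges.add((int(t), e))

    def plastic_load(self) -> np.ndarray:
        if self.params.Q == 0 or not self.state.active_edges:
            return np.zeros(2 * self.mesh.n_nodes)
        if len(self.state.active_edges) != self._fp_count:
            self._fp_cache = plastic_force_field(
                self.mesh, self.state.active_edges, self.params.Q
            )
            self._fp_count = len(self.state.active_edges)
        return self._fp_cache

    # -- time stepping -----------------------------------------------------

    def step(self, f_t: np.ndarray, f_p: np.ndarray | None = None) -> np.ndarray:
        """Advance one backward-Euler step; returns the new displacement."""
        if f_p is None:
            f_p = self.plastic_load()
        rhs = f_t + f_p + (self.K_v / self.params.dt) @ self.state.u
        u_new = self._sys.solve(rhs)
        self.state.u_prev = self.state.u
        self.state.u = u_new
        return u_new

    # -- field queries used by the coupled model ---------------------------

    @property
    def displacement(self) -> np.ndarray:
        return self.state.u

    @property
    def velocity(self) -> np.ndarray:
        """Substrate velocity: backward difference of the displacement."""
        return (self.state.u - self.state.u_prev) / self.params.dt

    def displacement_increment_at(self, points: np.ndarray) -> np.ndarray:
        du = (self.state.u - self.state.u_prev).reshape(-1, 2)
        return self.mesh.interpolate(du, points)

    def strain_energy_density(self, points: np.ndarray) -> np.ndarray:
        """W = 1/2 sigma_elas : eps at given points (piecewise constant)."""
        tri, _ = self.mesh.locate(points)
        un = self.state.u.reshape(-1, 2)
        vals = un[self.mesh.triangles[tri]]                      # (n,3,2)
        grad = np.einsum("nkd,nke->nde", vals, self.mesh.grads[tri])  # (n,2,2) = grad u^T? see below
        # grad[n,d,e] = d u_d / d x_e
        eps11 = grad[:, 0, 0]
        eps22 = grad[:, 1, 1]
        eps12 = 0.5 * (grad[:, 0, 1] + grad[:, 1, 0])
        p = self.params
        Ep = p.E_s / (1 + p.nu)
        nup = p.nu / (1 - 2 * p.nu)
        tr = eps11 + eps22
        s11 = Ep * (eps11 + nup * tr)
        s22 = Ep * (eps22 + nup * tr)
        s12 = Ep * eps12
        return 0.5 * (s11 * eps11 + s22 * eps22 + 2 * s12 * eps12)
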