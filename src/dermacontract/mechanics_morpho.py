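"""Morphoelastic backend: momentum balance for the velocity coupled to an
evolution equation for the effective strain.

The solved system is

    rho [ Dv/Dt + v (div v) ] - div sigma = f_t,        v = 0 on the boundary,
    De/Dt + e skw(L) - skw(L) e + [tr(e) - 1] sym(L) = -alpha e,

with L = grad v, sigma = sigma_elas(e) + eta [mu1 sym(L) + mu2 tr(sym(L)) I].
The effective strain e does not equal the symmetric displacement gradient; the
relaxation rate alpha sets the degree of permanent (plastic) deformation, and
alpha = 0 recovers a damped viscoelastic solid with inertia whose wound
returns to its original size after force removal.

Discretization: P1 for velocity and for each strain component; backward Euler
in time; the nonlinear products (convection, the e-L coupling) are lagged in a
Picard fixed-point loop inside every time step.  The non-standard inertial
term ``v (div v)`` is kept verbatim rather than rewritten in conservative
form.  Displacement is accumulated as ``u += dt * v`` (rectangle rule,
consistent with backward Euler).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .mesh import Mesh

__all__ = ["MorphoParams", "MorphoMechanics", "PicardDivergenceError"]


class PicardDivergenceError(RuntimeError):
    pass


@dataclass
class MorphoParams:
    E_s: float
    nu: float
    eta: float
    mu1: float
    mu2: float
    rho: float              # ECM density (mass per area via unit thickness)
    alpha: float            # permanent-deformation rate, 1/time
    dt: float
    picard_tol: float = 1e-8
    picard_max_iter: int = 50

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("ECM density must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass
class MorphoState:
    v: np.ndarray           # (2N,) interleaved velocity
    eps: np.ndarray         # (N, 3) Voigt (11, 22, 12)
    u_accum: np.ndarray     # (2N,) time-integrated velocity


class MorphoMechanics:
    backend_name = "morpho"

    def __init__(self, mesh: Mesh, params: MorphoParams):
        self.mesh = mesh
        self.params = params
        p = params
        self.M_v = fem.vector_mass(mesh, p.rho)
        self.A_visc = p.eta * fem.viscous_stiffness(mesh, p.mu1, p.mu2)
        self.K_ev = fem.elastic_coupling(mesh, p.E_s, p.nu)
        self.M_s = fem.mass_matrix(mesh)
        self._fixed = fem.vector_dirichlet_dofs(mesh)
        self._vel_sys = fem.DirichletSystem(self.M_v / p.dt + self.A_visc, self._fixed)
        self._lumped = fem.lumped_mass(mesh)
        self.state = MorphoState(
            v=np.zeros(2 * mesh.n_nodes),
            eps=np.zeros((mesh.n_nodes, 3)),
            u_accum=np.zeros(2 * mesh.n_nodes),
        )
        self._warned_tr = False

    # -- kinematic helpers -------------------------------------------------

    def _nodal_velocity_gradient(self, v: np.ndarray) -> np.ndarray:
        """Lumped L2 projection of the elementwise-constant grad v to nodes.

        Returns (N, 2, 2) with L[n, i, j] = d v_i / d x_j.
        """
        mesh = self.mesh
        vn = v.reshape(-1, 2)
        vals = vn[mesh.triangles]                                   # (M,3,2)
        Le = np.einsum("mkd,mke->mde", vals, mesh.grads)            # (M,2,2)
        out = np.zeros((mesh.n_nodes, 2, 2))
        w = (mesh.element_areas / 3.0)[:, None, None] * Le          # (M,2,2)
        for k in range(3):
            np.add.at(out, mesh.triangles[:, k], w)
        return out / self._lumped[:, None, None]

    def _inertial_rhs(self, v: np.ndarray) -> np.ndarray:
        """Weak form of rho [v.grad v + v (div v)] with centroid quadrature."""
        mesh = self.mesh
        vn = v.reshape(-1, 2)
        vals = vn[mesh.triangles]                                   # (M,3,2)
        Le = np.einsum("mkd,mke->mde", vals, mesh.grads)            # dv_d/dx_e
        vc = vals.mean(axis=1)                                      # (M,2)
        conv = np.einsum("me,mde->md", vc, Le)                      # v.grad v
        divv = Le[:, 0, 0] + Le[:, 1, 1]
        term = conv + vc * divv[:, None]                            # (M,2)
        F = np.zeros(2 * mesh.n_nodes)
        w = self.params.rho * (mesh.element_areas / 3.0)[:, None] * term
        for k in range(3):
            np.add.at(F, 2 * mesh.triangles[:, k], w[:, 0])
            np.add.at(F, 2 * mesh.triangles[:, k] + 1, w[:, 1])
        return F

    @staticmethod
    def _coupling_terms(eps: np.ndarray, L: np.ndarray) -> np.ndarray:
        """Pointwise G = e skw(L) - skw(L) e + [tr(e) - 1] sym(L), Voigt (11,22,12)."""
        a, b, c = eps[:, 0], eps[:, 1], eps[:, 2]
        w = 0.5 * (L[:, 0, 1] - L[:, 1, 0])                         # skw(L) = [[0,w],[-w,0]]
        s11 = L[:, 0, 0]
        s22 = L[:, 1, 1]
        s12 = 0.5 * (L[:, 0, 1] + L[:, 1, 0])
        G = np.empty_like(eps)
        tr1 = a + b - 1.0
        G[:, 0] = -2.0 * c * w + tr1 * s11
        G[:, 1] = 2.0 * c * w + tr1 * s22
        G[:, 2] = (a - b) * w + tr1 * s12
        return G

    def _weak_coupling_rhs(self, eps: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Galerkin source ``int phi_a G`` with elementwise-constant grad v.

        Assembling G against the test functions with the untouched P1 velocity
        gradient (one-point quadrature, element averages of eps) keeps the
        strain production adjoint to the elastic momentum coupling, so strain
        modes relax at the physical viscoelastic rates instead of leaving a
        weakly-coupled residue.
        """
        mesh = self.mesh
        vn = v.reshape(-1, 2)
        vals = vn[mesh.triangles]                                   # (M,3,2)
        Le = np.einsum("mkd,mke->mde", vals, mesh.grads)            # (M,2,2)
        eps_bar = eps[mesh.triangles].mean(axis=1)                  # (M,3)
        Ge = self._coupling_terms(eps_bar, Le)                      # (M,3)
        out = np.zeros_like(eps)
        w = (mesh.element_areas / 3.0)[:, None] * Ge
        for k in range(3):
            np.add.at(out, mesh.triangles[:, k], w)
        return out

    def strain_step(
        self, eps_n: np.ndarray, v: np.ndarray, eps_star: np.ndarray | None = None
    ) -> np.ndarray:
        """One backward-Euler step of the strain evolution at given velocity.

        The advection and the e-L coupling use the supplied iterate
        ``eps_star`` (defaults to eps_n); relaxation -alpha*e is implicit.
        With v = 0 this reduces per node to e^{n+1} = e^n / (1 + alpha dt).
        """
        p = self.params
        if eps_star is None:
            eps_star = eps_n
        if np.any(np.abs(v) > 0):
            G_rhs = self._weak_coupling_rhs(eps_star, v)
            N = fem.advection_matrix(self.mesh, v)
            A = (1.0 / p.dt + p.alpha) * self.M_s + N
            lu = spla.splu(A.tocsc())
            rhs = self.M_s @ (eps_n / p.dt) - G_rhs
            out = np.column_stack([lu.solve(rhs[:, k]) for k in range(3)])
        else:
            out = eps_n / (1.0 + p.alpha * p.dt)
        tr = out[:, 0] + out[:, 1]
        if not self._warned_tr and np.any(tr >= 1.0):
            warnings.warn(
                "tr(eps) reached 1: the [tr(eps)-1] factor in the strain "
                "evolution vanishes locally",
                RuntimeWarning,
            )
            self._warned_tr = True
        return out

    # -- time stepping -----------------------------------------------------

    def step(self, f_t: np.ndarray) -> np.ndarray:
        """Advance one time step by Picard iteration; returns the new velocity."""
        p = self.params
        st = self.state
        v_star = st.v.copy()
        eps_star = st.eps.copy()
        Mdt = self.M_v / p.dt
        for it in range(p.picard_max_iter):
            rhs = f_t + Mdt @ st.v - self.K_ev @ eps_star.ravel() - self._inertial_rhs(v_star)
            v_new = self._vel_sys.solve(rhs)
            eps_new = self.strain_step(st.eps, v_new, eps_star)
            dv = np.max(np.abs(v_new - v_star))
            de = np.max(np.abs(eps_new - eps_star))
            v_star, eps_star = v_new, eps_new
            if dv < p.picard_tol and de < p.picard_tol:
                break
        else:
            if max(dv, de) > 1e3 * p.picard_tol:
                raise PicardDivergenceError(
                    f"Picard iteration did not converge: residual {max(dv, de):.3e} "
                    f"after {p.picard_max_iter} iterations"
                )
        st.v = v_star
        st.eps = eps_star
        st.u_accum = st.u_accum + p.dt * st.v
        return st.v

    # -- field queries -----------------------------------------------------

    @property
    def displacement(self) -> np.ndarray:
        """u(t) = int_0^t v ds accumulated by the rectangle rule."""
        return self.state.u_accum

    @property
    def velocity(self) -> np.ndarray:
        return self.state.v

    def displacement_increment_at(self, points: np.ndarray) -> np.ndarray:
        v = self.state.v.reshape(-1, 2)
        return self.params.dt * self.mesh.interpolate(v, points)

    def strain_energy_density(self, points: np.ndarray) -> np.ndarray:
        """W = 1/2 sigma_elas(e) : e interpolated at points."""
        eps = self.mesh.interpolate(self.state.eps, points)         # (n,3)
        p = self.params
        Ep = p.E_s / (1 + p.nu)
        nup = p.nu / (1 - 2 * p.nu)
        tr = eps[:, 0] + eps[:, 1]
        s11 = Ep * (eps[:, 0] + nup * tr)
        s22 = Ep * (eps[:, 1] + nup * tr)
        s12 = Ep * eps[:, 2]
        return 0.5 * (s11 * eps[:, 0] + s22 * eps[:, 1] + 2 * s12 * eps[:, 2])


def morpho_stress(mesh: Mesh, eps: np.ndarray, v: np.ndarray, params: MorphoParams) -> np.ndarray:
    """Pointwise nodal stress sigma = sigma_elas(eps) + eta sigma_visc(grad v).

    Returns (N, 3) Voigt (11, 22, 12).  The velocity gradient is projected to
    nodes by the same lumped projection the strain equation uses.
    """
    p = params
    Ep = p.E_s / (1 + p.nu)
    nup = p.nu / (1 - 2 * p.nu)
    tr = eps[:, 0] + eps[:, 1]
    s = np.empty_like(eps)
    s[:, 0] = Ep * (eps[:, 0] + nup * tr)
    s[:, 1] = Ep * (eps[:, 1] + nup * tr)
    s[:, 2] = Ep * eps[:, 2]
    if np.any(v):
        helper = MorphoMechanics.__new__(MorphoMechanics)
        helper.mesh = mesh
        helper._lumped = fem.lumped_mass(mesh)
        L = MorphoMechanics._nodal_velocity_gradient(helper, v)
        symL11 = L[:, 0, 0]
        symL22 = L[:, 1, 1]
        symL12 = 0.5 * (L[:, 0, 1] + L[:, 1, 0])
        trL = symL11 + symL22
        s[:, 0] += p.eta * (p.mu1 * symL11 + p.mu2 * trL)
        s[:, 1] += p.eta * (p.mu1 * symL22 + p.mu2 * trL)
        s[:, 2] += p.eta * p.mu1 * symL12
    return s
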