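"""P1 finite-element assembly shared by both mechanics backends and transport.

All bilinear forms are assembled over the crossed-diagonal triangulation of
:mod:`dermacontract.mesh`.  Vector fields use interleaved degrees of freedom
``dof = 2*node + component``; symmetric 2x2 tensor fields store components
``(11, 22, 12)`` per node.

The elastic operator is the 2D restriction of the isotropic law

    sigma_elas = E_s/(1+nu) * { eps + tr(eps) * [nu/(1-2nu)] * I },

used exactly in this form (no plane-stress conversion).  The viscous operator
is the weak form of ``mu1*sym(grad .) + mu2*tr(sym(grad .))*I``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import Mesh

__all__ = [
    "mass_matrix",
    "lumped_mass",
    "vector_mass",
    "stiffness_scalar",
    "boundary_mass",
    "convection_conservative",
    "advection_matrix",
    "elastic_stiffness",
    "viscous_stiffness",
    "elastic_coupling",
    "assemble_operator",
    "assemble_point_load",
    "assemble_point_source",
    "DirichletSystem",
]


def _accumulate(rows, cols, vals, shape) -> sp.csr_matrix:
    return sp.coo_matrix((vals.ravel(), (rows.ravel(), cols.ravel())), shape=shape).tocsr()


def mass_matrix(mesh: Mesh) -> sp.csr_matrix:
    """Consistent scalar P1 mass matrix."""
    M = mesh.n_elements
    local = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]]) / 12.0
    vals = mesh.element_areas[:, None, None] * local                # (M,3,3)
    t = mesh.triangles
    rows = np.repeat(t[:, :, None], 3, axis=2)
    cols = np.repeat(t[:, None, :], 3, axis=1)
    return _accumulate(rows, cols, vals, (mesh.n_nodes, mesh.n_nodes))


def lumped_mass(mesh: Mesh) -> np.ndarray:
    """Row-sum lumped scalar mass: nodal control areas, sums to the domain area."""
    m = np.zeros(mesh.n_nodes)
    np.add.at(m, mesh.triangles.ravel(),
              np.repeat(mesh.element_areas / 3.0, 3))
    return m


def vector_mass(mesh: Mesh, density: float = 1.0) -> sp.csr_matrix:
    """Consistent vector mass matrix scaled by a constant density."""
    # kron(Ms, I2) is node-major/component-minor, i.e. already interleaved
    Ms = mass_matrix(mesh) * density
    return sp.kron(Ms, sp.identity(2), format="csr")


def stiffness_scalar(mesh: Mesh, coeff: float = 1.0) -> sp.csr_matrix:
    """Scalar diffusion stiffness ``coeff * int grad(phi_i).grad(phi_j)``."""
    g = mesh.grads                                                  # (M,3,2)
    vals = coeff * mesh.element_areas[:, None, None] * np.einsum("mkd,mld->mkl", g, g)
    t = mesh.triangles
    rows = np.repeat(t[:, :, None], 3, axis=2)
    cols = np.repeat(t[:, None, :], 3, axis=1)
    return _accumulate(rows, cols, vals, (mesh.n_nodes, mesh.n_nodes))


def boundary_mass(mesh: Mesh) -> sp.csr_matrix:
    """1D P1 mass matrix along the outer boundary (for Robin terms)."""
    bset = set(mesh.boundary_nodes.tolist())
    rows, cols, vals = [], [], []
    # boundary edges of the structured grid: consecutive nodes along each side
    n1 = mesh.nx + 1
    idx = np.arange(mesh.n_nodes).reshape(mesh.ny + 1, n1)
    sides = [idx[0, :], idx[-1, :], idx[:, 0], idx[:, -1]]
    for side in sides:
        for a, b in zip(side[:-1], side[1:]):
            assert a in bset and b in bset
            ell = np.linalg.norm(mesh.nodes[a] - mesh.nodes[b])
            loc = ell / 6.0 * np.array([[2, 1], [1, 2]])
            rows += [a, a, b, b]
            cols += [a, b, a, b]
            vals += [loc[0, 0], loc[0, 1], loc[1, 0], loc[1, 1]]
    return sp.coo_matrix((vals, (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()


def _centroid_velocity(mesh: Mesh, v: np.ndarray) -> np.ndarray:
    """Element-centroid values of an interleaved nodal vector field: (M, 2)."""
    vn = v.reshape(-1, 2)
    return vn[mesh.triangles].mean(axis=1)


def convection_conservative(mesh: Mesh, v: np.ndarray) -> sp.csr_matrix:
    """Weak conservative convection ``int phi_a div(c v)`` = ``-int c v.grad(phi_a)``.

    The boundary flux term vanishes because the substrate velocity satisfies
    v = 0 on the outer boundary.  One-point (centroid) quadrature.
    """
    vc = _centroid_velocity(mesh, v)                                # (M,2)
    g = mesh.grads                                                  # (M,3,2)
    w = np.einsum("md,mkd->mk", vc, g)                              # v.grad(phi_a)
    vals = -(mesh.element_areas[:, None, None] / 3.0) * w[:, :, None] * np.ones((1, 1, 3))
    # entry [a, j]: -int phi_j v.grad(phi_a) ~ -(area/3) * v.grad(phi_a) per vertex j
    t = mesh.triangles
    rows = np.repeat(t[:, :, None], 3, axis=2)
    cols = np.repeat(t[:, None, :], 3, axis=1)
    return _accumulate(rows, cols, vals, (mesh.n_nodes, mesh.n_nodes))


def advection_matrix(mesh: Mesh, v: np.ndarray) -> sp.csr_matrix:
    """Non-conservative advection ``int phi_a (v . grad c)`` (material derivative)."""
    vc = _centroid_velocity(mesh, v)
    g = mesh.grads
    w = np.einsum("md,mjd->mj", vc, g)                              # v.grad(phi_j)
    vals = (mesh.element_areas[:, None, None] / 3.0) * np.ones((1, 3, 1)) * w[:, None, :]
    t = mesh.triangles
    rows = np.repeat(t[:, :, None], 3, axis=2)
    cols = np.repeat(t[:, None, :], 3, axis=1)
    return _accumulate(rows, cols, vals, (mesh.n_nodes, mesh.n_nodes))


def _vector_form(mesh: Mesh, D: np.ndarray) -> sp.csr_matrix:
    """Assemble ``int (D eps(u)) : eps(w)`` with D a 3x3 Voigt matrix."""
    g = mesh.grads                                                  # (M,3,2)
    M = mesh.n_elements
    B = np.zeros((M, 3, 6))                                         # Voigt (e11,e22,g12)
    B[:, 0, 0::2] = g[:, :, 0]
    B[:, 1, 1::2] = g[:, :, 1]
    B[:, 2, 0::2] = g[:, :, 1]
    B[:, 2, 1::2] = g[:, :, 0]
    K = np.einsum("mki,kl,mlj->mij", B, D, B) * mesh.element_areas[:, None, None]
    t = mesh.triangles
    dofs = np.empty((M, 6), int)
    dofs[:, 0::2] = 2 * t
    dofs[:, 1::2] = 2 * t + 1
    rows = np.repeat(dofs[:, :, None], 6, axis=2)
    cols = np.repeat(dofs[:, None, :], 6, axis=1)
    return _accumulate(rows, cols, K, (2 * mesh.n_nodes, 2 * mesh.n_nodes))


def elastic_stiffness(mesh: Mesh, E_s: float, nu: float) -> sp.csr_matrix:
    """Weak form of ``-div sigma_elas`` for the printed 2D constitutive law."""
    if E_s <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0 < nu < 0.5:
        raise ValueError("Poisson ratio must lie in (0, 0.5); the 1-2nu factor degenerates")
    Ep = E_s / (1 + nu)
    nup = nu / (1 - 2 * nu)
    D = Ep * np.array([[1 + nup, nup, 0.0], [nup, 1 + nup, 0.0], [0.0, 0.0, 0.5]])
    return _vector_form(mesh, D)


def viscous_stiffness(mesh: Mesh, mu1: float, mu2: float) -> sp.csr_matrix:
    """Weak form of ``-div [mu1 sym(grad .) + mu2 tr(sym(grad .)) I]``."""
    D = np.array([[mu1 + mu2, mu2, 0.0], [mu2, mu1 + mu2, 0.0], [0.0, 0.0, mu1 / 2]])
    return _vector_form(mesh, D)


def elastic_coupling(mesh: Mesh, E_s: float, nu: float) -> sp.csr_matrix:
    """Map nodal effective strain (N,3 Voigt (11,22,12)) to velocity-test residual.

    Returns the matrix of ``int sigma_elas(eps_h) : grad(phi_a e_d)`` with
    ``eps_h`` interpolated P1; used by the morphoelastic momentum balance.
    """
    Ep = E_s / (1 + nu)
    nup = nu / (1 - 2 * nu)
    # sigma components from strain components (s11, s22, s12)
    C = Ep * np.array([[1 + nup, nup, 0.0], [nup, 1 + nup, 0.0], [0.0, 0.0, 1.0]])
    g = mesh.grads                                                  # (M,3,2)
    t = mesh.triangles
    M = mesh.n_elements
    # For test function phi_a e_d:  int sigma : grad = area * mean(sigma) : grad(phi_a e_d)
    # mean(sigma)_pq = C[p, c] * mean over vertices j of eps_c(j)
    rows = np.empty((M, 3, 2, 3, 3), int)
    cols = np.empty((M, 3, 2, 3, 3), int)
    vals = np.empty((M, 3, 2, 3, 3))
    area = mesh.element_areas
    for a in range(3):
        for d in range(2):
            # sigma : grad(phi_a e_d) = sigma[d,0]*g[a,0] + sigma[d,1]*g[a,1]
            for j in range(3):
                for c in range(3):
                    if d == 0:
                        w = C[0, c] * g[:, a, 0] + C[2, c] * g[:, a, 1]
                    else:
                        w = C[2, c] * g[:, a, 0] + C[1, c] * g[:, a, 1]
                    vals[:, a, d, j, c] = area * w / 3.0
                    rows[:, a, d, j, c] = 2 * t[:, a] + d
                    cols[:, a, d, j, c] = 3 * t[:, j] + c
    return _accumulate(rows, cols, vals, (2 * mesh.n_nodes, 3 * mesh.n_nodes))


def assemble_operator(
    mesh: Mesh, E_s: float, nu: float, mu1: float, mu2: float, eta: float = 1.0
) -> tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix]:
    """(elastic stiffness, eta-scaled viscous stiffness, vector mass)."""
    return (
        elastic_stiffness(mesh, E_s, nu),
        eta * viscous_stiffness(mesh, mu1, mu2),
        vector_mass(mesh),
    )


def assemble_point_source(mesh: Mesh, x: np.ndarray, rate: float = 1.0) -> np.ndarray:
    """P1 discretization of ``rate * delta(x - x0)``: nodal vector summing to rate."""
    tri, lam = mesh.locate(np.asarray(x, float))
    b = np.zeros(mesh.n_nodes)
    np.add.at(b, mesh.triangles[tri[0]], rate * lam[0])
    return b


def assemble_point_load(mesh: Mesh, x: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Dirac point load at x discretized by P1 basis values (immersed boundary).

    The nodal loads sum exactly to ``f`` (partition of unity).  Points on an
    inter-element edge are assigned to the lowest-indexed containing triangle.
    """
    tri, lam = mesh.locate(np.asarray(x, float))
    F = np.zeros(2 * mesh.n_nodes)
    f = np.asarray(f, float)
    nodes = mesh.triangles[tri[0]]
    np.add.at(F, 2 * nodes, lam[0] * f[0])
    np.add.at(F, 2 * nodes + 1, lam[0] * f[1])
    return F


class DirichletSystem:
    """Symmetric elimination of homogeneous Dirichlet dofs with a cached LU.

    ``fixed_dofs`` are indices into the full dof vector; the reduced operator
    is factorized once (direct sparse LU) and reused for every right-hand side.
    """

    def __init__(self, A: sp.spmatrix, fixed_dofs: np.ndarray, n_dofs: int | None = None):
        n = A.shape[0] if n_dofs is None else n_dofs
        mask = np.ones(n, bool)
        mask[np.asarray(fixed_dofs, int)] = False
        self.free = np.flatnonzero(mask)
        self.n = n
        self._Ared = A.tocsr()[self.free, :][:, self.free].tocsc()
        self._lu = spla.splu(self._Ared) if self._Ared.shape[0] else None

    def solve(self, b: np.ndarray) -> np.ndarray:
        x = np.zeros(self.n)
        if self._lu is not None:
            x[self.free] = self._lu.solve(b[self.free])
        return x


def vector_dirichlet_dofs(mesh: Mesh) -> np.ndarray:
    """Interleaved dof indices clamped by u = 0 (or v = 0) on the outer boundary."""
    bn = mesh.boundary_nodes
    return np.concatenate([2 * bn, 2 * bn + 1])
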