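"""Tensor-valued fibrin and collagen bundle fields.

The state of each tissue type k in {fibrin, collagen} is a symmetric
positive-semidefinite 2x2 orientation tensor per node, stored Voigt-style as
(11, 22, 12).  Its trace is the bundle density rho^k; initially both tissues
are isotropic with rho^f + rho^c = 1/alpha_rho everywhere (fibrin inside the
wound, collagen outside), which makes the density saturation of the
chemotaxis weight and of collagen secretion exact at t = 0.

Fibrin is degraded with rate delta_rho * c_tPA; collagen is deposited by
migrating (myo)fibroblasts as rank-one point sources aligned with each cell's
active displacement direction, with a secretion prefactor
``1 - alpha_rho (rho^f + rho^c)`` floored at zero.  Both tensors are advected
conservatively with the substrate velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .mesh import Mesh

__all__ = [
    "FiberTensorField",
    "init_fiber_tensors",
    "FiberSolver",
    "spd_clip",
    "density",
]


@dataclass
class FiberTensorField:
    kind: str                 # "fibrin" | "collagen"
    omega: np.ndarray         # (N, 3) Voigt (11, 22, 12)
    alpha_rho: float
    delta_rho: float = 0.0    # fibrin degradation rate (per concentration per time)


def density(omega: np.ndarray) -> np.ndarray:
    """Bundle density rho^k = tr(Omega^k) per node."""
    return omega[..., 0] + omega[..., 1]


def spd_clip(omega: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Project each nodal 2x2 tensor onto the PSD cone (closed-form eigenclip)."""
    a, b, c = omega[:, 0], omega[:, 1], omega[:, 2]
    half = 0.5 * (a + b)
    rad = np.sqrt(0.25 * (a - b) ** 2 + c**2)
    l1, l2 = half + rad, half - rad
    need = l2 < -tol
    if not np.any(need):
        return omega
    out = omega.copy()
    idx = np.flatnonzero(need)
    for i in idx:
        m = np.array([[a[i], c[i]], [c[i], b[i]]])
        w, V = np.linalg.eigh(m)
        w = np.maximum(w, 0.0)
        m2 = V @ np.diag(w) @ V.T
        out[i] = (m2[0, 0], m2[1, 1], m2[0, 1])
    return out


def init_fiber_tensors(mesh: Mesh, alpha_rho: float) -> tuple[FiberTensorField, FiberTensorField]:
    """Isotropic initial tensors: fibrin = 1_wound/(2 a_rho) I, collagen the complement."""
    if alpha_rho <= 0:
        raise ValueError("alpha_rho must be positive")
    ind = mesh.wound_indicator
    omega_f = np.zeros((mesh.n_nodes, 3))
    omega_c = np.zeros((mesh.n_nodes, 3))
    omega_f[:, 0] = omega_f[:, 1] = ind / (2 * alpha_rho)
    omega_c[:, 0] = omega_c[:, 1] = (1.0 - ind) / (2 * alpha_rho)
    return (
        FiberTensorField("fibrin", omega_f, alpha_rho),
        FiberTensorField("collagen", omega_c, alpha_rho),
    )


class FiberSolver:
    """Conservative transport + reaction stepper for the tensor components.

    The time derivative and the reaction terms use the lumped mass matrix:
    with zero velocity the degradation is then exactly pointwise, so an
    indicator-valued fibrin tensor under uniform tPA decays without any
    spurious smearing across the wound edge.
    """

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.Ml = fem.lumped_mass(mesh)

    def _system(self, dt: float, v_sub: np.ndarray | None, sink: np.ndarray | None):
        A = sp.diags(self.Ml / dt)
        if v_sub is not None and np.any(v_sub):
            A = A + fem.convection_conservative(self.mesh, v_sub)
        if sink is not None and np.any(sink):
            A = A + sp.diags(self.Ml * sink)   # lumped implicit sink, nodal coeff
        return A

    def step_fibrin(
        self,
        field: FiberTensorField,
        c_tpa: np.ndarray,
        dt: float,
        v_sub: np.ndarray | None = None,
    ) -> FiberTensorField:
        """Advance the fibrin tensor: transport with sink delta_rho * c_tPA."""
        sink = field.delta_rho * np.maximum(c_tpa, 0.0)
        A = self._system(dt, v_sub, sink)
        rhs = self.Ml[:, None] * (field.omega / dt)
        if v_sub is not None and np.any(v_sub):
            lu = spla.splu(A.tocsc())
            out = np.column_stack([lu.solve(rhs[:, k]) for k in range(3)])
        else:
            out = rhs / A.diagonal()[:, None]
        field.omega = spd_clip(out)
        return field

    def deposit_collagen(
        self,
        field: FiberTensorField,
        cells,
        rho_total_at,
        dt: float,
        v_sub: np.ndarray | None = None,
    ) -> FiberTensorField:
        """Transport the collagen tensor and add cellwise rank-one deposition.

        ``rho_total_at(points)`` returns rho^f + rho^c at cell centres.  Point
        sources use lumped-mass scaling, so the deposited integrated density
        equals the source rate times dt independent of the mesh resolution.
        Cells with undefined active-displacement direction are skipped.
        """
        if v_sub is not None and np.any(v_sub):
            A = self._system(dt, v_sub, None)
            lu = spla.splu(A.tocsc())
            rhs = self.Ml[:, None] * (field.omega / dt)
            omega = np.column_stack([lu.solve(rhs[:, k]) for k in range(3)])
        else:
            omega = field.omega.copy()
        contributors = [c for c in cells
                        if c.alive and c.phenotype != "macrophage" and c.r_N is not None]
        if contributors:
            centers = np.array([c.center for c in contributors])
            rho_tot = np.asarray(rho_total_at(centers), float)
            pref = np.maximum(0.0, 1.0 - field.alpha_rho * rho_tot)
            for cell, w in zip(contributors, pref):
                if w <= 0:
                    continue
                b = fem.assemble_point_source(self.mesh, cell.center, 1.0) / self.Ml
                r = cell.r_N
                rr = np.array([r[0] * r[0], r[1] * r[1], r[0] * r[1]])
                omega = omega + dt * w * b[:, None] * rr[None, :]
        field.omega = spd_clip(omega)
        return field
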