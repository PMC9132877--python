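"""Cytokine transport: convection-diffusion-reaction with Robin leakage.

Each signalling species c in {PDGF, TGF-beta, tPA} obeys

    dc/dt + div(c v) - D laplace(c) = F,      dc/dn + kappa_c c = 0 on the edge,

where v is the substrate velocity from the active mechanics backend.  PDGF
starts high inside the wound (attracting macrophages), TGF-beta starts at zero
and is secreted by macrophages (driving fibroblast chemotaxis and
differentiation), and tPA starts in a one-element band along the wound border
(driving fibrin degradation).  Reaction terms beyond macrophage TGF-beta
secretion are linear decay with configurable rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from . import fem
from .mesh import Mesh

__all__ = ["CytokineField", "CytokineParams", "init_cytokines", "step_cytokine"]

PDGF = "PDGF"
TGF = "TGF"
TPA = "tPA"


@dataclass
class CytokineParams:
    D: float = 1.0            # diffusion rate, area/time
    kappa: float = 0.1        # Robin leakage coefficient, 1/length
    decay: float = 0.1        # linear decay rate, 1/time
    k_secretion: float = 0.0  # Dirac secretion rate per secreting cell (TGF only)

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("diffusion rate must be positive")
        if self.kappa < 0:
            raise ValueError("Robin coefficient must be non-negative")


@dataclass
class CytokineField:
    species: str
    c: np.ndarray             # nodal concentrations (nondimensional)
    params: CytokineParams
    clipped_mass: float = 0.0  # cumulative negative mass removed by clipping

    def total_mass(self, mesh: Mesh) -> float:
        return float(fem.lumped_mass(mesh) @ self.c)


def _tpa_band(mesh: Mesh) -> np.ndarray:
    """Nodes on the edge between wound and undamaged skin.

    The band is the set of nodes strictly closer than one element layer to the
    wound rectangle boundary; on the aligned structured grids this is exactly
    the polyline of wound-boundary nodes, so the wound interior stays at zero.
    """
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    hw = max(mesh.hx, mesh.hy)
    a, b = mesh.xw / 2, mesh.yw / 2
    # signed rectangle "distance": 0 on the wound boundary, <0 inside
    d = np.maximum(np.abs(x) - a, np.abs(y) - b)
    return (np.abs(d) < hw - 1e-12 * max(mesh.x0, mesh.y0)).astype(float)


def init_cytokines(
    mesh: Mesh, params: dict[str, CytokineParams] | None = None
) -> dict[str, CytokineField]:
    """The stated initial conditions on the three species.

    PDGF = 1 on wound nodes; TGF-beta = 0 everywhere; tPA = 1 on the
    one-element band around the wound boundary.
    """
    if params is None:
        params = {PDGF: CytokineParams(), TGF: CytokineParams(), TPA: CytokineParams()}
    return {
        PDGF: CytokineField(PDGF, mesh.wound_indicator.copy(), params[PDGF]),
        TGF: CytokineField(TGF, np.zeros(mesh.n_nodes), params[TGF]),
        TPA: CytokineField(TPA, _tpa_band(mesh), params[TPA]),
    }


class CytokineSolver:
    """Backward-Euler transport stepper with cached mesh operators."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.M = fem.mass_matrix(mesh)
        self.K = fem.stiffness_scalar(mesh)
        self.Mb = fem.boundary_mass(mesh)
        self._cached_v: np.ndarray | None = None
        self._C = None

    def _convection(self, v: np.ndarray | None):
        if v is None or not np.any(v):
            return None
        if self._cached_v is None or not np.array_equal(v, self._cached_v):
            self._C = fem.convection_conservative(self.mesh, v)
            self._cached_v = v.copy()
        return self._C

    def step(
        self,
        field: CytokineField,
        dt: float,
        v_sub: np.ndarray | None = None,
        sources: list[tuple[np.ndarray, float]] | None = None,
    ) -> CytokineField:
        """One backward-Euler step; negative nodal values are clipped (logged)."""
        if dt <= 0:
            raise ValueError("time step must be positive")
        p = field.params
        A = self.M / dt + p.D * self.K + p.decay * self.M + p.D * p.kappa * self.Mb
        C = self._convection(v_sub)
        if C is not None:
            A = A + C
        rhs = self.M @ (field.c / dt)
        if sources:
            for point, rate in sources:
                rhs = rhs + fem.assemble_point_source(self.mesh, point, rate)
        c_new = spla.spsolve(A.tocsc(), rhs)
        if np.any(np.isnan(c_new)):
            raise FloatingPointError(f"NaN in {field.species} transport step")
        neg = c_new < 0
        if np.any(neg):
            field.clipped_mass += float(-(fem.lumped_mass(self.mesh)[neg] @ c_new[neg]))
            c_new = np.maximum(c_new, 0.0)
        field.c = c_new
        return field


def step_cytokine(
    mesh: Mesh,
    field: CytokineField,
    dt: float,
    v_sub: np.ndarray | None = None,
    sources: list[tuple[np.ndarray, float]] | None = None,
) -> CytokineField:
    """Convenience single-shot wrapper around :class:`CytokineSolver`."""
    return CytokineSolver(mesh).step(field, dt, v_sub, sources)
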