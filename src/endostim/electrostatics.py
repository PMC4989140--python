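"""Steady conduction solve: div(sigma grad phi) = 0 on the structured grid.

Finite-volume discretization with a 5-point stencil. Face conductances use
the harmonic mean of the adjacent cell conductivities (the exact
series-resistor value for piecewise-constant sigma), electrode cells carry
Dirichlet potentials, and the outer boundary is insulating (zero normal
current). The reduced system over non-electrode cells is symmetric positive
definite and is factorized directly (sparse LU).

The electric field is reconstructed per cell from the face current
densities, |E| = |J| / sigma, rather than by differencing the potential:
the normal current is continuous across material interfaces, so this
reconstruction reproduces the physical field jump at the blood/wall
conductivity step instead of smearing it over neighboring cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import SolverError
from .geometry import DomainModel


@dataclass(frozen=True)
class LinearSystem:
    """Reduced SPD system over non-electrode cells."""

    domain: DomainModel
    matrix: sp.csr_matrix          # (n_free, n_free)
    rhs: np.ndarray                # (n_free,)
    free_index: np.ndarray         # (ny, nx) int, -1 on electrode cells
    face_gx: np.ndarray            # (ny, nx-1) conductance of vertical faces
    face_gy: np.ndarray            # (ny-1, nx) conductance of horizontal faces


@dataclass(frozen=True)
class FieldSolution:
    """Potential and derived field on the grid."""

    domain: DomainModel
    potential: np.ndarray          # (ny, nx), V at cell centers
    ex: np.ndarray                 # (ny, nx), V/m
    ey: np.ndarray                 # (ny, nx), V/m
    pulse_potential: float

    @cached_property
    def field_magnitude(self) -> np.ndarray:
        return np.hypot(self.ex, self.ey)

    @cached_property
    def current_density(self) -> np.ndarray:
        sigma = self.domain.property_map("electrical_conductivity")
        return sigma * self.field_magnitude


def face_conductances(domain: DomainModel) -> tuple[np.ndarray, np.ndarray]:
    """Conductance (S per unit depth) of interior x- and y-faces.

    The face between two cells is the series combination of their half-cell
    resistances: G = w_face / (0.5 d1/s1 + 0.5 d2/s2).
    """
    sigma = domain.property_map("electrical_conductivity")
    dx, dy = domain.x.widths, domain.y.widths
    rx = 0.5 * dx[None, :] / sigma                       # half-resistances * w
    gx = dy[:, None] / (rx[:, :-1] + rx[:, 1:])
    ry = 0.5 * dy[:, None] / sigma
    gy = dx[None, :] / (ry[:-1, :] + ry[1:, :])
    return gx, gy


def assemble_system(domain: DomainModel) -> LinearSystem:
    """Assemble the reduced conduction system with Dirichlet electrodes.

    Electrode cells are eliminated: their known potentials move to the
    right-hand side, keeping the free-cell matrix symmetric positive
    definite. Raises :class:`~endostim.errors.SolverError` when no
    electrode cell exists (floating-potential, singular problem).
    """
    fixed = domain.electrode_mask
    if not fixed.any():
        raise SolverError("no Dirichlet (electrode) cell: system is singular")
    ny, nx = domain.shape
    gx, gy = face_conductances(domain)
    pot = domain.electrode_potential

    free_index = np.full((ny, nx), -1, dtype=np.int64)
    free = ~fixed
    n_free = int(free.sum())
    free_index[free] = np.arange(n_free)

    rows, cols, vals = [], [], []
    diag = np.zeros(n_free)
    rhs = np.zeros(n_free)

    def couple(ia, ib, g, fixed_a, fixed_b, pot_a, pot_b):
        both_free = (ia >= 0) & (ib >= 0)
        diag_add = np.zeros(n_free)
        np.add.at(diag_add, ia[ia >= 0], g[ia >= 0])
        np.add.at(diag_add, ib[ib >= 0], g[ib >= 0])
        diag[:] += diag_add
        rows.append(ia[both_free]); cols.append(ib[both_free])
        vals.append(-g[both_free])
        rows.append(ib[both_free]); cols.append(ia[both_free])
        vals.append(-g[both_free])
        a_free_b_fixed = (ia >= 0) & fixed_b
        np.add.at(rhs, ia[a_free_b_fixed],
                  g[a_free_b_fixed] * pot_b[a_free_b_fixed])
        b_free_a_fixed = (ib >= 0) & fixed_a
        np.add.at(rhs, ib[b_free_a_fixed],
                  g[b_free_a_fixed] * pot_a[b_free_a_fixed])

    # x-direction faces
    ia = free_index[:, :-1].ravel()
    ib = free_index[:, 1:].ravel()
    couple(ia, ib, gx.ravel(), fixed[:, :-1].ravel(), fixed[:, 1:].ravel(),
           pot[:, :-1].ravel(), pot[:, 1:].ravel())
    # y-direction faces
    ia = free_index[:-1, :].ravel()
    ib = free_index[1:, :].ravel()
    couple(ia, ib, gy.ravel(), fixed[:-1, :].ravel(), fixed[1:, :].ravel(),
           pot[:-1, :].ravel(), pot[1:, :].ravel())

    idx = np.arange(n_free)
    rows.append(idx); cols.append(idx); vals.append(diag)
    matrix = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_free, n_free))
    return LinearSystem(domain, matrix, rhs, free_index, gx, gy)


def solve_potential(system: LinearSystem,
                    check_residual: bool = True) -> FieldSolution:
    """Solve the reduced system and reconstruct the field.

    A relative residual above 1e-10 or a violation of the discrete maximum
    principle raises :class:`~endostim.errors.SolverError`.
    """
    domain = system.domain
    try:
        lu = spla.splu(system.matrix.tocsc())
        phi_free = lu.solve(system.rhs)
    except RuntimeError as exc:    # pragma: no cover - splu failure path
        raise SolverError(f"direct solve failed: {exc}") from exc
    if check_residual:
        denom = np.linalg.norm(system.rhs)
        if denom > 0:
            res = np.linalg.norm(system.matrix @ phi_free - system.rhs) / denom
            if res > 1e-10:
                raise SolverError(f"relative residual {res:.2e} > 1e-10")

    pot = domain.electrode_potential
    phi = np.where(domain.electrode_mask, pot, 0.0)
    phi[system.free_index >= 0] = phi_free[
        system.free_index[system.free_index >= 0]]

    vmin, vmax = np.nanmin(pot), np.nanmax(pot)
    tol = 1e-9 * max(1.0, abs(vmax), abs(vmin))
    if phi.min() < vmin - tol or phi.max() > vmax + tol:
        raise SolverError("discrete maximum principle violated")

    ex, ey = _field_from_fluxes(domain, phi, system.face_gx, system.face_gy)
    vp = float(np.nanmax(np.abs(pot)))
    return FieldSolution(domain, phi, ex, ey, vp)


def _field_from_fluxes(domain, phi, gx, gy):
    """Cell-centered E from face current densities, E = J / sigma."""
    sigma = domain.property_map("electrical_conductivity")
    dx, dy = domain.x.widths, domain.y.widths
    # current density through each interior face (A/m^2, unit depth)
    jx_face = gx * (phi[:, :-1] - phi[:, 1:]) / dy[:, None]
    jy_face = gy * (phi[:-1, :] - phi[1:, :]) / dx[None, :]
    jx = _average_faces(jx_face, axis=1)
    jy = _average_faces(jy_face, axis=0)
    return jx / sigma, jy / sigma


def _average_faces(jf: np.ndarray, axis: int) -> np.ndarray:
    """Average the two faces of each cell; one-sided at domain boundaries."""
    if axis == 1:
        left = np.concatenate([jf[:, :1], jf], axis=1)
        right = np.concatenate([jf, jf[:, -1:]], axis=1)
    else:
        left = np.concatenate([jf[:1, :], jf], axis=0)
        right = np.concatenate([jf, jf[-1:, :]], axis=0)
    return 0.5 * (left + right)


def solve(domain: DomainModel) -> FieldSolution:
    """Assemble and solve in one call."""
    return solve_potential(assemble_system(domain))


def electrode_currents(solution: FieldSolution) -> dict[float, float]:
    """Net current (A per unit depth) leaving the electrodes, by potential.

    Positive values mean current flows out of the electrode group into the
    tissue. Summed from the face conductances between electrode and
    non-electrode cells; used for charge-conservation checks and terminal
    power (P = sum_k V_k I_k).
    """
    domain = solution.domain
    gx, gy = face_conductances(domain)
    phi = solution.potential
    fixed = domain.electrode_mask
    pot = domain.electrode_potential

    currents: dict[float, float] = {}

    def add(mask_a, mask_b, g, phi_a, phi_b, pot_a):
        # faces where side a is electrode and side b is not
        sel = mask_a & ~mask_b
        if sel.any():
            flow = g[sel] * (phi_a[sel] - phi_b[sel])
            for v in np.unique(pot_a[sel]):
                currents[float(v)] = currents.get(float(v), 0.0) + \
                    float(flow[pot_a[sel] == v].sum())

    add(fixed[:, :-1], fixed[:, 1:], gx, phi[:, :-1], phi[:, 1:], pot[:, :-1])
    add(fixed[:, 1:], fixed[:, :-1], gx, phi[:, 1:], phi[:, :-1], pot[:, 1:])
    add(fixed[:-1, :], fixed[1:, :], gy, phi[:-1, :], phi[1:, :], pot[:-1, :])
    add(fixed[1:, :], fixed[:-1, :], gy, phi[1:, :], phi[:-1, :], pot[1:, :])
    return currents


def dense_reference_solve(domain: DomainModel) -> np.ndarray:
    """Brute-force dense solve of the full (unreduced) system.

    Builds the complete n_cells x n_cells matrix with explicit identity
    rows for electrode cells and inverts it with LAPACK. Intended as an
    independent oracle on toy grids (<= a few thousand cells).
    """
    ny, nx = domain.shape
    n = ny * nx
    if n > 10_000:
        raise SolverError("dense reference solve limited to toy grids")
    gx, gy = face_conductances(domain)
    a = np.zeros((n, n))
    b = np.zeros(n)
    fixed = domain.electrode_mask.ravel()
    pot = domain.electrode_potential.ravel()

    def lin(j, i):
        return j * nx + i

    for j in range(ny):
        for i in range(nx - 1):
            p, q, g = lin(j, i), lin(j, i + 1), gx[j, i]
            a[p, p] += g; a[q, q] += g; a[p, q] -= g; a[q, p] -= g
    for j in range(ny - 1):
        for i in range(nx):
            p, q, g = lin(j, i), lin(j + 1, i), gy[j, i]
            a[p, p] += g; a[q, q] += g; a[p, q] -= g; a[q, p] -= g
    for p in np.flatnonzero(fixed):
        a[p, :] = 0.0
        a[p, p] = 1.0
        b[p] = pot[p]
    if not fixed.any():
        raise SolverError("no Dirichlet cell in reference problem")
    phi = np.linalg.solve(a, b)
    return phi.reshape(ny, nx)
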