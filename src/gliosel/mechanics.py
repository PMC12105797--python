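"""Quasi-static tissue mechanics driven by tumour burden.

The tumour acts as a body force proportional to the gradient of total
normalized density in the linear-elastic equilibrium equation

    div(G grad u) + grad( G/(1-2*nu) div u ) = lambda2 * grad(N_E + N_N),

solved for the displacement ``u`` on the brain mask with a slip boundary
(zero normal displacement, free tangential displacement) at the brain
surface. The stress tensor follows from isotropic Hooke's law and its
deviatoric part yields the von Mises stress, which in turn damps tumour
cell diffusion:  D(x) = D0(x) * exp(-lambda1 * sigma_vm(x)).

Discretization is cell-centred finite differences with ghost voxels:
across a boundary face the normal displacement component is odd
(vanishes on the face) and tangential components are even (stress free).
The stiffness matrix depends only on the anatomy, so it is assembled and
LU-factorized once and reused for every solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .constants import DEFAULT_CONSTANTS, ModelConstants
from .grid import GREY, WHITE, Grid

_AXES = (0, 1, 2)


@dataclass
class MechanicsState:
    """Displacement (mm), stress tensor (kPa, Voigt order) and von Mises field."""

    displacement: np.ndarray    # dims + (3,)
    stress: np.ndarray          # dims + (6,): xx, yy, zz, yz, xz, xy
    von_mises: np.ndarray       # dims
    residual: float = 0.0


def shear_modulus_flat(grid: Grid, constants: ModelConstants) -> np.ndarray:
    g = np.where(grid.labels_flat == WHITE, constants.G_white, 0.0)
    g[grid.labels_flat == GREY] = constants.G_grey
    return g


def _central_diff(grid: Grid, axis: int, mode: str) -> sparse.csr_matrix:
    """Central-difference matrix along ``axis`` with boundary ghost rule.

    mode "antisym": missing neighbour takes value -v_i (odd extension,
    zero on the face); mode "sym": missing neighbour takes value +v_i
    (even extension, zero gradient).
    """
    n = grid.n_inside
    h = grid.spacing[axis]
    fwd = grid.neighbours(axis, +1)
    bwd = grid.neighbours(axis, -1)
    rows, cols, data = [], [], []
    idx = np.arange(n)
    ghost = -1.0 if mode == "antisym" else 1.0

    have_f = fwd >= 0
    rows.append(idx[have_f]); cols.append(fwd[have_f]); data.append(np.full(have_f.sum(), 0.5 / h))
    rows.append(idx[~have_f]); cols.append(idx[~have_f]); data.append(np.full((~have_f).sum(), ghost * 0.5 / h))
    have_b = bwd >= 0
    rows.append(idx[have_b]); cols.append(bwd[have_b]); data.append(np.full(have_b.sum(), -0.5 / h))
    rows.append(idx[~have_b]); cols.append(idx[~have_b]); data.append(np.full((~have_b).sum(), -ghost * 0.5 / h))

    return sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )


def _component_laplacian(grid: Grid, g_flat: np.ndarray, component: int) -> sparse.csr_matrix:
    """div(G grad u_c) with slip ghosts: odd across faces normal to c, even otherwise."""
    n = grid.n_inside
    rows, cols, datas = [], [], []
    diag = np.zeros(n)
    for ax in _AXES:
        inv_h2 = 1.0 / grid.spacing[ax] ** 2
        i, j = grid.interior_edges(ax)
        w = 0.5 * (g_flat[i] + g_flat[j]) * inv_h2
        rows.extend([i, j]); cols.extend([j, i]); datas.extend([w, w])
        np.add.at(diag, i, -w)
        np.add.at(diag, j, -w)
        if ax == component:
            # boundary faces: ghost u_c = -u_c  ->  extra -2 G_i / h^2 on the diagonal
            for direction in (+1, -1):
                missing = grid.neighbours(ax, direction) < 0
                diag[missing] -= 2.0 * g_flat[missing] * inv_h2
    idx = np.arange(n)
    rows.append(idx); cols.append(idx); datas.append(diag)
    return sparse.csr_matrix(
        (np.concatenate(datas), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )


class ElasticitySystem:
    """Assembled and factorized equilibrium system for one anatomy."""

    def __init__(self, grid: Grid, constants: ModelConstants = DEFAULT_CONSTANTS):
        self.grid = grid
        self.constants = constants
        self.g_flat = shear_modulus_flat(grid, constants)
        self.kappa = self.g_flat / (1.0 - 2.0 * constants.nu)
        self.lame = 2.0 * self.g_flat * constants.nu / (1.0 - 2.0 * constants.nu)
        # derivative of component c along axis d: odd ghost iff d == c
        self.du = [
            [_central_diff(grid, d, "antisym" if d == c else "sym") for d in _AXES]
            for c in _AXES
        ]
        self.d_sym = [_central_diff(grid, ax, "sym") for ax in _AXES]
        self.matrix = self._assemble()
        self._lu = None

    def _assemble(self) -> sparse.csc_matrix:
        kap = sparse.diags(self.kappa)
        blocks = []
        for c in _AXES:
            row = []
            for d in _AXES:
                block = self.d_sym[c] @ kap @ self.du[d][d]
                if c == d:
                    block = block + _component_laplacian(self.grid, self.g_flat, c)
                row.append(block)
            blocks.append(row)
        return sparse.bmat(blocks, format="csc")

    @property
    def strain_operator(self) -> sparse.csr_matrix:
        """Sparse map from stacked displacement (3n,) to stacked strain (6n,)
        in Voigt order xx, yy, zz, yz, xz, xy."""
        if not hasattr(self, "_strain_op"):
            du = self.du
            n = self.grid.n_inside
            z = sparse.csr_matrix((n, n))
            self._strain_op = sparse.bmat(
                [
                    [du[0][0], z, z],
                    [z, du[1][1], z],
                    [z, z, du[2][2]],
                    [z, 0.5 * du[1][2], 0.5 * du[2][1]],
                    [0.5 * du[0][2], z, 0.5 * du[2][0]],
                    [0.5 * du[0][1], 0.5 * du[1][0], z],
                ],
                format="csr",
            )
        return self._strain_op

    @property
    def density_strain_map(self) -> np.ndarray:
        """Dense (6n, n) map: total density -> strain, with lambda2 folded in.

        The equilibrium problem is linear, so strain is a fixed linear
        function of the tumour density; precomputing it turns the daily
        mechanics refresh into one matrix-vector product.
        """
        if not hasattr(self, "_density_strain_map"):
            g3 = sparse.vstack([self.d_sym[c] for c in _AXES], format="csc")
            rhs = self.constants.lambda2 * np.asarray(g3.todense())
            disp = self.lu.solve(rhs)
            # single precision: the map is memory-bound in the hot loop and
            # ~1e-7 relative error in sigma_vm is far below physical noise
            self._density_strain_map = np.asarray(
                self.strain_operator @ disp, dtype=np.float32
            )
        return self._density_strain_map

    def von_mises_flat(self, total_density_flat: np.ndarray) -> np.ndarray:
        """Fast von Mises stress of the density-loaded equilibrium state.

        The deviatoric stress is 2G * deviatoric strain (the Lame term is
        hydrostatic), so sigma_vm = 2G * sqrt(3/2 * dev(eps):dev(eps)).
        """
        n = self.grid.n_inside
        eps = (
            self.density_strain_map @ np.asarray(total_density_flat, dtype=np.float32)
        ).astype(float).reshape(6, n)
        mean = (eps[0] + eps[1] + eps[2]) / 3.0
        j2 = (
            (eps[0] - mean) ** 2 + (eps[1] - mean) ** 2 + (eps[2] - mean) ** 2
            + 2.0 * (eps[3] ** 2 + eps[4] ** 2 + eps[5] ** 2)
        )
        vm = 2.0 * self.g_flat * np.sqrt(1.5 * j2)
        if not np.all(np.isfinite(vm)):
            raise RuntimeError("mechanics fast path produced non-finite stress")
        return vm

    @property
    def lu(self):
        if self._lu is None:
            try:
                self._lu = splu(self.matrix)
            except RuntimeError as exc:  # pragma: no cover - singular anatomy
                raise RuntimeError(f"mechanics stiffness matrix is singular: {exc}") from exc
        return self._lu

    def solve_flat(self, total_density_flat: np.ndarray):
        """Return (u, von_mises, stress) as flat mask vectors.

        u has shape (3, n); stress has shape (6, n) in Voigt order
        xx, yy, zz, yz, xz, xy.
        """
        rho = np.asarray(total_density_flat, dtype=float)
        if not np.all(np.isfinite(rho)):
            raise ValueError("total density field contains non-finite values")
        lam2 = self.constants.lambda2
        rhs = np.concatenate([lam2 * (self.d_sym[c] @ rho) for c in _AXES])
        sol = self.lu.solve(rhs)
        if not np.all(np.isfinite(sol)):
            raise RuntimeError("mechanics solve returned non-finite displacement")
        res = self.matrix @ sol - rhs
        rhs_norm = np.linalg.norm(rhs)
        residual = float(np.linalg.norm(res) / max(rhs_norm, 1e-300))
        if rhs_norm > 0 and residual > 1e-6:
            raise RuntimeError(
                f"mechanics linear solve did not converge: relative residual {residual:.3e}"
            )
        n = self.grid.n_inside
        u = sol.reshape(3, n)
        eps = [[None] * 3 for _ in _AXES]
        for c in _AXES:
            for d in range(c, 3):
                gcd = self.du[c][d] @ u[c]
                gdc = self.du[d][c] @ u[d]
                eps[c][d] = 0.5 * (gcd + gdc)
        tr = eps[0][0] + eps[1][1] + eps[2][2]
        two_g = 2.0 * self.g_flat
        sxx = two_g * eps[0][0] + self.lame * tr
        syy = two_g * eps[1][1] + self.lame * tr
        szz = two_g * eps[2][2] + self.lame * tr
        syz = two_g * eps[1][2]
        sxz = two_g * eps[0][2]
        sxy = two_g * eps[0][1]
        mean = (sxx + syy + szz) / 3.0
        vm = np.sqrt(
            1.5 * ((sxx - mean) ** 2 + (syy - mean) ** 2 + (szz - mean) ** 2
                   + 2.0 * (syz ** 2 + sxz ** 2 + sxy ** 2))
        )
        stress = np.stack([sxx, syy, szz, syz, sxz, sxy])
        return u, vm, stress, residual


def solve_mechanics(
    total_density_field: np.ndarray,
    grid: Grid,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    system: ElasticitySystem | None = None,
) -> MechanicsState:
    """Solve the tumour-loaded equilibrium equation on ``grid``.

    ``total_density_field`` is the full 3-D field N_E + N_N (zero outside
    the brain mask). Returns displacement, Hooke stress and von Mises
    stress as full 3-D arrays.
    """
    rho = np.asarray(total_density_field, dtype=float)
    if rho.shape != grid.dims:
        raise ValueError("density field shape does not match grid dims")
    if not np.all(np.isfinite(rho)):
        raise ValueError("density field contains non-finite values")
    if np.any(rho[~grid.brain_mask] != 0):
        raise ValueError("tumour density must be zero outside the brain mask")
    if system is None:
        system = ElasticitySystem(grid, constants)
    u, vm, stress, residual = system.solve_flat(grid.flatten(rho))
    disp = np.zeros(grid.dims + (3,))
    for c in _AXES:
        disp[..., c] = grid.unflatten(u[c])
    stress3d = np.zeros(grid.dims + (6,))
    for k in range(6):
        stress3d[..., k] = grid.unflatten(stress[k])
    return MechanicsState(
        displacement=disp,
        stress=stress3d,
        von_mises=grid.unflatten(vm),
        residual=residual,
    )


def damp_diffusion(d0_field: np.ndarray, von_mises: np.ndarray, lambda1: float) -> np.ndarray:
    """Stress-damped diffusivity D = D0 * exp(-lambda1 * sigma_vm)."""
    if lambda1 < 0:
        raise ValueError("lambda1 must be non-negative")
    return np.asarray(d0_field) * np.exp(-lambda1 * np.asarray(von_mises))
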