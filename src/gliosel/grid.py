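"""Voxel grid, tissue labels and finite-difference index machinery.

The computational domain is a small stack of axial MRI slices (default
in-plane resolution 0.5 x 0.5 mm, slice thickness 2 mm, three slices).
Voxels are labelled white matter, grey matter or outside the brain; all
tumour fields live on the brain mask and are zero outside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

OUTSIDE = 0
WHITE = 1
GREY = 2

_AXES = (0, 1, 2)


@dataclass(eq=False)
class Grid:
    """Voxelized brain domain.

    Parameters
    ----------
    dims : tuple of int
        Grid shape ``(nx, ny, nz)``.
    spacing : tuple of float
        Voxel spacing in mm, default ``(0.5, 0.5, 2.0)``.
    brain_mask : ndarray of bool, shape ``dims``
        True inside the brain.
    tissue_labels : ndarray of uint8, shape ``dims``
        ``WHITE``/``GREY`` inside the mask, ``OUTSIDE`` elsewhere.
    """

    dims: tuple
    spacing: tuple = (0.5, 0.5, 2.0)
    brain_mask: np.ndarray = None
    tissue_labels: np.ndarray = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.dims) != 3 or any(d <= 0 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.dims, dtype=bool)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.dims:
            raise ValueError("brain_mask shape does not match dims")
        if self.tissue_labels is None:
            self.tissue_labels = np.where(self.brain_mask, WHITE, OUTSIDE).astype(np.uint8)
        self.tissue_labels = np.asarray(self.tissue_labels, dtype=np.uint8)
        if self.tissue_labels.shape != self.dims:
            raise ValueError("tissue_labels shape does not match dims")
        inside = self.tissue_labels != OUTSIDE
        if not np.array_equal(inside, self.brain_mask):
            raise ValueError("white/grey voxels must coincide with brain_mask")
        if self.n_inside == 0:
            raise ValueError("brain mask is empty")

    # -- index machinery -------------------------------------------------

    @property
    def n_inside(self) -> int:
        return int(self.brain_mask.sum())

    @property
    def index_map(self) -> np.ndarray:
        """``dims``-shaped int array: flat index inside the mask, -1 outside."""
        if "index_map" not in self._cache:
            im = -np.ones(self.dims, dtype=np.int64)
            im[self.brain_mask] = np.arange(self.n_inside)
            self._cache["index_map"] = im
        return self._cache["index_map"]

    @property
    def inside_ijk(self) -> np.ndarray:
        if "inside_ijk" not in self._cache:
            self._cache["inside_ijk"] = np.argwhere(self.brain_mask)
        return self._cache["inside_ijk"]

    def flatten(self, field3d: np.ndarray) -> np.ndarray:
        """Restrict a full 3-D field to the flat inside-mask vector."""
        return np.asarray(field3d)[self.brain_mask]

    def unflatten(self, flat: np.ndarray, fill=0.0) -> np.ndarray:
        out = np.full(self.dims, fill, dtype=float)
        out[self.brain_mask] = flat
        return out

    def neighbours(self, axis: int, direction: int):
        """Flat indices of each inside voxel's neighbour along ``axis``.

        Returns an int array of length ``n_inside`` with -1 where the
        neighbour is outside the mask (or off the grid).
        """
        key = ("nb", axis, direction)
        if key not in self._cache:
            ijk = self.inside_ijk.copy()
            ijk[:, axis] += direction
            valid = (ijk[:, axis] >= 0) & (ijk[:, axis] < self.dims[axis])
            nb = -np.ones(self.n_inside, dtype=np.int64)
            v = ijk[valid]
            nb[valid] = self.index_map[v[:, 0], v[:, 1], v[:, 2]]
            self._cache[key] = nb
        return self._cache[key]

    def interior_edges(self, axis: int):
        """Pairs ``(i, j)`` of flat indices of inside voxels adjacent along axis."""
        key = ("edges", axis)
        if key not in self._cache:
            nb = self.neighbours(axis, +1)
            i = np.nonzero(nb >= 0)[0]
            self._cache[key] = (i.astype(np.int64), nb[i])
        return self._cache[key]

    @property
    def labels_flat(self) -> np.ndarray:
        if "labels_flat" not in self._cache:
            self._cache["labels_flat"] = self.flatten(self.tissue_labels).astype(np.uint8)
        return self._cache["labels_flat"]


def diffusion_structure(grid: Grid):
    """Precompute the COO structure of the zero-flux diffusion operator."""
    rows, cols = [], []
    edge_slices = []
    n = grid.n_inside
    pos = 0
    for ax in _AXES:
        i, j = grid.interior_edges(ax)
        rows.extend([i, j])
        cols.extend([j, i])
        edge_slices.append((i, j))
        pos += 2 * len(i)
    diag = np.arange(n)
    rows.append(diag)
    cols.append(diag)
    return np.concatenate(rows), np.concatenate(cols), edge_slices


class DiffusionAssembler:
    """Re-assembles div(D grad .) cheaply as the diffusivity field evolves.

    The sparsity pattern depends only on the grid, so the CSR matrix is
    built once and subsequent updates just rewrite its ``data`` array.
    """

    def __init__(self, grid: Grid):
        self.grid = grid
        self.structure = diffusion_structure(grid)
        rows, cols, _ = self.structure
        nnz = len(rows)
        template = sparse.csr_matrix(
            (np.arange(1.0, nnz + 1.0), (rows, cols)), shape=(grid.n_inside,) * 2
        )
        if template.nnz != nnz:
            raise AssertionError("duplicate entries in diffusion structure")
        self._perm = (template.data - 1.0).astype(np.int64)
        self._matrix = template
        self._inv_h2 = [1.0 / grid.spacing[ax] ** 2 for ax in _AXES]
        # flattened canonical edge arrays for jit-compiled assembly:
        # canonical data layout is [w_fwd, w_bwd per axis ..., diag block]
        ei, ej, inv = [], [], []
        for ax in _AXES:
            i, j = self.structure[2][ax]
            ei.extend([i, j])
            ej.extend([j, i])
            inv.append(np.full(2 * len(i), self._inv_h2[ax]))
        self.edge_i = np.concatenate(ei).astype(np.int64)
        self.edge_j = np.concatenate(ej).astype(np.int64)
        self.edge_inv_h2 = np.concatenate(inv)
        self.perm = self._perm

    @property
    def matrix(self) -> sparse.csr_matrix:
        return self._matrix

    def _data(self, d_flat: np.ndarray) -> np.ndarray:
        n = self.grid.n_inside
        datas = []
        diag = np.zeros(n)
        for ax in _AXES:
            i, j = self.structure[2][ax]
            w = 0.5 * (d_flat[i] + d_flat[j]) * self._inv_h2[ax]
            datas.extend([w, w])
            diag -= np.bincount(i, weights=w, minlength=n)
            diag -= np.bincount(j, weights=w, minlength=n)
        datas.append(diag)
        return np.concatenate(datas)

    def update(self, d_flat: np.ndarray) -> sparse.csr_matrix:
        self._matrix.data = self._data(d_flat)[self._perm]
        return self._matrix


def diffusion_operator(grid: Grid, d_flat: np.ndarray, structure=None) -> sparse.csr_matrix:
    """Sparse operator L with ``(L @ n)`` = div(D grad n), zero-flux boundaries.

    Face diffusivity is the arithmetic mean of the two adjacent voxels;
    faces on the mask boundary carry no flux.
    """
    if structure is None:
        structure = diffusion_structure(grid)
    rows, cols, edge_slices = structure
    n = grid.n_inside
    inv_h2 = [1.0 / grid.spacing[ax] ** 2 for ax in _AXES]
    datas = []
    diag = np.zeros(n)
    for ax in _AXES:
        i, j = edge_slices[ax]
        w = 0.5 * (d_flat[i] + d_flat[j]) * inv_h2[ax]
        datas.extend([w, w])
        np.add.at(diag, i, -w)
        np.add.at(diag, j, -w)
    datas.append(diag)
    data = np.concatenate(datas)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
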