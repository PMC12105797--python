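"""Hot inner loop of the reaction-diffusion integrator.

A numba kernel advances both species through the sub-daily Euler steps
(CSR Laplacian matvec fused with the logistic-competition reaction and
the clip to the admissible range). The non-enhancing operator is the
enhancing one scaled by f_NE, since D_N = f_NE * D_E voxelwise. A pure
numpy fallback with identical semantics is used if numba is missing;
unit tests pin both paths to the public single-step reference.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _integrate_day_numba(
    n_e, n_n, indptr, indices, data, f_ne,
    kp_e, kp_n, beta_ne, beta_en, theta_e, theta_n, dt, n_steps,
):  # pragma: no cover - compiled
    nv = n_e.shape[0]
    lap_e = np.empty(nv)
    lap_n = np.empty(nv)
    clipped = 0
    for _ in range(n_steps):
        for i in range(nv):
            se = 0.0
            sn = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                j = indices[k]
                se += data[k] * n_e[j]
                sn += data[k] * n_n[j]
            lap_e[i] = se
            lap_n[i] = f_ne * sn
        for i in range(nv):
            ge = kp_e[i] * n_e[i] * (1.0 - (n_e[i] + beta_ne * n_n[i]) / theta_e)
            gn = kp_n[i] * n_n[i] * (1.0 - (n_n[i] + beta_en * n_e[i]) / theta_n)
            a = n_e[i] + dt * (lap_e[i] + ge)
            b = n_n[i] + dt * (lap_n[i] + gn)
            if a < 0.0:
                if a < -1e-12:
                    clipped += 1
                a = 0.0
            elif a > theta_e:
                if a > theta_e + 1e-12:
                    clipped += 1
                a = theta_e
            if b < 0.0:
                if b < -1e-12:
                    clipped += 1
                b = 0.0
            elif b > theta_n:
                if b > theta_n + 1e-12:
                    clipped += 1
                b = theta_n
            n_e[i] = a
            n_n[i] = b
    return clipped


def _integrate_day_numpy(
    n_e, n_n, indptr, indices, data, f_ne,
    kp_e, kp_n, beta_ne, beta_en, theta_e, theta_n, dt, n_steps,
):
    from scipy import sparse

    nv = n_e.shape[0]
    op = sparse.csr_matrix((data, indices, indptr), shape=(nv, nv))
    clipped = 0
    for _ in range(n_steps):
        lap_e = op @ n_e
        lap_n = f_ne * (op @ n_n)
        ge = kp_e * n_e * (1.0 - (n_e + beta_ne * n_n) / theta_e)
        gn = kp_n * n_n * (1.0 - (n_n + beta_en * n_e) / theta_n)
        a = n_e + dt * (lap_e + ge)
        b = n_n + dt * (lap_n + gn)
        clipped += int(np.count_nonzero(
            (a < -1e-12) | (a > theta_e + 1e-12)
            | (b < -1e-12) | (b > theta_n + 1e-12)
        ))
        np.clip(a, 0.0, theta_e, out=n_e)
        np.clip(b, 0.0, theta_n, out=n_n)
    return clipped


integrate_day = _integrate_day_numba if HAVE_NUMBA else _integrate_day_numpy


@njit(cache=True)
def _assemble_and_integrate_numba(
    n_e, n_n, d_flat, edge_i, edge_j, edge_inv_h2, perm, data,
    f_ne, kp_e, kp_n, beta_ne, beta_en, theta_e, theta_n, dt, n_steps,
    indptr, indices,
):  # pragma: no cover - compiled
    """Rebuild the CSR diffusion data from the diffusivity field, then step.

    Canonical data layout: one weight per directed edge (face flux),
    followed by the per-voxel diagonal; ``perm`` maps canonical order to
    the CSR data order.
    """
    nv = n_e.shape[0]
    ne_edges = edge_i.shape[0]
    can = np.zeros(ne_edges + nv)
    for e in range(ne_edges):
        w = 0.5 * (d_flat[edge_i[e]] + d_flat[edge_j[e]]) * edge_inv_h2[e]
        can[e] = w
        can[ne_edges + edge_i[e]] -= w
    for s in range(ne_edges + nv):  # perm maps CSR slot -> canonical slot
        data[s] = can[perm[s]]
    return _integrate_day_numba(
        n_e, n_n, indptr, indices, data, f_ne,
        kp_e, kp_n, beta_ne, beta_en, theta_e, theta_n, dt, n_steps,
    )


def _assemble_and_integrate_numpy(
    n_e, n_n, d_flat, edge_i, edge_j, edge_inv_h2, perm, data,
    f_ne, kp_e, kp_n, beta_ne, beta_en, theta_e, theta_n, dt, n_steps,
    indptr, indices,
):
    nv = n_e.shape[0]
    w = 0.5 * (d_flat[edge_i] + d_flat[edge_j]) * edge_inv_h2
    can = np.concatenate([w, -np.bincount(edge_i, weights=w, minlength=nv)])
    data[:] = can[perm]
    return _integrate_day_numpy(
        n_e, n_n, indptr, indices, data, f_ne,
        kp_e, kp_n, beta_ne, beta_en, theta_e, theta_n, dt, n_steps,
    )


assemble_and_integrate = (
    _assemble_and_integrate_numba if HAVE_NUMBA else _assemble_and_integrate_numpy
)
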