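"""Planted per-task ROI correlation structure.

The four task matrices share a common connectivity pattern plus
task-specific deviations.  The shared/idiosyncratic mixing is built from
exactly orthonormalized centered vectors, so the pairwise Pearson
correlation between any two tasks' off-diagonal entries equals the
requested similarity exactly (Pearson is invariant to the positive
affine map onto the correlation scale).
"""

from __future__ import annotations

import numpy as np

from execsim.core import TASK_TYPES, as_rng

DEFAULT_BASE_R = 0.25
DEFAULT_SPREAD = 0.16  # rms of the per-entry task deviations (r scale)
MAX_ABS_DEVIATION = 0.45
PD_SHRINK = 0.92
PD_MAX_RETRIES = 60
PD_EIG_FLOOR = 1e-4


def _orthonormal_centered(n_vectors: int, length: int, rng) -> np.ndarray:
    """Columns: centered, mutually orthonormal random vectors."""
    m = rng.standard_normal((length, n_vectors))
    m -= m.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(m)
    # fix signs for reproducibility across LAPACK variants
    q *= np.sign(np.diag(r))
    return q


def vector_to_matrix(offdiag: np.ndarray, n_rois: int) -> np.ndarray:
    mat = np.eye(n_rois)
    iu = np.triu_indices(n_rois, 1)
    mat[iu] = offdiag
    mat[(iu[1], iu[0])] = offdiag
    return mat


def matrix_to_vector(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], 1)
    return mat[iu]


def _make_positive_definite(mat: np.ndarray) -> np.ndarray:
    out = mat.copy()
    for _ in range(PD_MAX_RETRIES):
        if np.linalg.eigvalsh(out).min() > PD_EIG_FLOOR:
            return out
        off = out - np.diag(np.diag(out))
        out = np.eye(out.shape[0]) + PD_SHRINK * off
    raise RuntimeError("could not reach positive definiteness by shrinking")


def _common_shrink_factor(matrices: list) -> float:
    """Smallest uniform off-diagonal shrink making every matrix PD.

    A single factor for all tasks preserves the cross-task geometry
    (per-task shrinking would distort the planted profile alignment).
    """
    factor = 1.0
    for _ in range(PD_MAX_RETRIES):
        ok = True
        for mat in matrices:
            off = mat - np.diag(np.diag(mat))
            test = np.eye(mat.shape[0]) + factor * off
            if np.linalg.eigvalsh(test).min() <= PD_EIG_FLOOR:
                ok = False
                break
        if ok:
            return factor
        factor *= PD_SHRINK
    raise RuntimeError("could not reach positive definiteness by shrinking")


def make_connectivity_structure(
    s: float,
    n_rois: int = 8,
    rng_seed=0,
    base_r: float = DEFAULT_BASE_R,
    spread: float = DEFAULT_SPREAD,
    task_profile_weight: float = 0.18,
):
    """Four positive-definite ROI correlation matrices with pairwise
    off-diagonal similarity ``s``.

    On top of the shared/idiosyncratic mixture, every connection receives
    the same task-varying offset (a common task-modulation profile,
    weighted by ``task_profile_weight``).  Per-task constants leave the
    cross-task Pearson similarity untouched, but they align the
    connections' 4-task profiles; since the idiosyncratic part scales
    with sqrt(1 - s), higher similarity yields more aligned profiles and
    hence a tighter connection-similarity MDS embedding.

    Returns
    -------
    matrices : dict of task type -> (n_rois, n_rois) correlation matrix
    realized : (4, 4) pairwise Pearson similarities of off-diagonal entries
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("similarity target s must lie in [0, 1]")
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    rng = as_rng(rng_seed)
    m = n_rois * (n_rois - 1) // 2
    n_tasks = len(TASK_TYPES)

    q = _orthonormal_centered(n_tasks + 1, m, rng)
    shared, idio = q[:, 0], q[:, 1:]
    vecs = np.sqrt(s) * shared[:, None] + np.sqrt(1.0 - s) * idio

    dev = spread * vecs * np.sqrt(m)  # unit-norm columns -> entry rms = spread
    dev = np.clip(dev, -MAX_ABS_DEVIATION, MAX_ABS_DEVIATION)

    # fixed, centered, unit-norm task-modulation profile; s = 1 means the
    # tasks do not differ at all, common profile included
    profile = np.array([0.5, 0.5, -0.5, -0.5])
    offsets = (task_profile_weight if s < 1.0 else 0.0) * profile

    offdiags = np.clip(base_r + dev + offsets[None, :], -0.98, 0.98)

    raw = [vector_to_matrix(offdiags[:, k], n_rois) for k in range(n_tasks)]
    factor = _common_shrink_factor(raw)
    matrices = {}
    for k, task in enumerate(TASK_TYPES):
        off = raw[k] - np.diag(np.diag(raw[k]))
        matrices[task] = np.eye(n_rois) + factor * off

    realized = np.eye(n_tasks)
    stacked = np.column_stack([matrix_to_vector(matrices[t]) for t in TASK_TYPES])
    for i in range(n_tasks):
        for j in range(i + 1, n_tasks):
            r = np.corrcoef(stacked[:, i], stacked[:, j])[0, 1]
            realized[i, j] = realized[j, i] = r
    if np.abs(realized[np.triu_indices(n_tasks, 1)] - s).max() > 0.05:
        raise RuntimeError("realized cross-task similarity missed its target")
    return matrices, realized
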