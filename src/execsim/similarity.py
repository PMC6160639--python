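"""Cross-task similarity of connectivity patterns, classical MDS and
labeled distance tables.

Two similarity objects are used: the 4x4 task-by-task correlation of a
participant's 28 connectivity values, and the 28x28 connection-by-
connection correlation of cohort-averaged values across the four task
types.  Dissimilarity for embedding is d = 1 - r.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from execsim.core import TASK_TYPES, as_rng

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Similarity matrices
# ---------------------------------------------------------------------------


def participant_task_similarity(vectors: dict) -> pd.DataFrame:
    """4x4 Pearson correlations of one participant's z vectors across tasks."""
    missing = [t for t in TASK_TYPES if t not in vectors]
    if missing:
        raise ValueError(f"missing task vectors: {missing}")
    data = {}
    length = None
    for t in TASK_TYPES:
        v = vectors[t]
        z = np.asarray(getattr(v, "z", v), dtype=float)
        if length is None:
            length = len(z)
        elif len(z) != length:
            raise ValueError("task vectors differ in length")
        data[t] = z
    mat = np.eye(len(TASK_TYPES))
    for i, a in enumerate(TASK_TYPES):
        for j in range(i + 1, len(TASK_TYPES)):
            r = np.corrcoef(data[a], data[TASK_TYPES[j]])[0, 1]
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=TASK_TYPES, columns=TASK_TYPES)


def cohort_connection_similarity(z_table: pd.DataFrame) -> pd.DataFrame:
    """28x28 correlations of connections' 4-task profiles.

    ``z_table``: rows = connections, columns = the four task types
    (cohort-averaged z values).  Zero-variance profiles correlate 0.
    """
    cols = [t for t in TASK_TYPES if t in z_table.columns]
    if len(cols) != len(TASK_TYPES):
        raise ValueError("z table must have all four task columns")
    x = z_table[list(TASK_TYPES)].to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    dead = norms == 0
    if dead.any():
        logger.warning(
            "%d connections have zero variance across tasks; correlations set to 0",
            int(dead.sum()),
        )
    safe = np.where(dead, 1.0, norms)
    unit = centered / safe[:, None]
    mat = unit @ unit.T
    mat[dead, :] = 0.0
    mat[:, dead] = 0.0
    np.fill_diagonal(mat, 1.0)
    idx = z_table.index
    return pd.DataFrame(mat, index=idx, columns=idx)


def cohort_connection_z_table(long_table: pd.DataFrame) -> pd.DataFrame:
    """Average a long connectivity table into connections x tasks."""
    df = long_table.copy()
    df["connection"] = df["roi_i"].astype(str) + "--" + df["roi_j"].astype(str)
    wide = df.pivot_table(index="connection", columns="task", values="z", aggfunc="mean")
    return wide


# ---------------------------------------------------------------------------
# Matrix comparison tests
# ---------------------------------------------------------------------------


@dataclass
class MatrixTestResult:
    r: float
    p_similarity: float
    p_difference: float = None
    n_perm: int = 0
    statistic_difference: float = None


def _triu(mat) -> np.ndarray:
    a = np.asarray(mat, dtype=float)
    return a[np.triu_indices(a.shape[0], 1)]


def _permute_matrix(mat: np.ndarray, perm: np.ndarray) -> np.ndarray:
    return mat[np.ix_(perm, perm)]


def matrix_similarity_test(
    a, b, n_perm: int = 999, rng_seed=0, z_tables=None
) -> MatrixTestResult:
    """Compare two similarity matrices.

    ``r`` is the Pearson correlation of upper triangles.  The similarity
    p-value permutes connection identities of one matrix (does the
    observed alignment exceed chance?).  If ``z_tables`` — a pair of
    per-participant z stacks, each of shape (n_participants,
    n_connections, n_tasks) — is given, a difference p-value is computed
    by permuting participants between the two cohorts and recomputing
    the matrices (statistic: sum of squared upper-triangle differences).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value resolution")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    rng = as_rng(rng_seed)
    ta, tb = _triu(a), _triu(b)
    r_obs = float(np.corrcoef(ta, tb)[0, 1])

    n = a.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = np.corrcoef(_triu(_permute_matrix(b, perm)), ta)[0, 1]
        if r_perm >= r_obs:
            count += 1
    p_similarity = (count + 1) / (n_perm + 1)

    p_difference = stat_diff = None
    if z_tables is not None:
        stack_a = np.asarray(z_tables[0], dtype=float)
        stack_b = np.asarray(z_tables[1], dtype=float)
        stat_diff, p_difference = _participant_permutation_difference(
            stack_a, stack_b, n_perm, rng
        )
    return MatrixTestResult(
        r=r_obs,
        p_similarity=p_similarity,
        p_difference=p_difference,
        n_perm=n_perm,
        statistic_difference=stat_diff,
    )


def _connection_matrix_from_stack(stack: np.ndarray) -> np.ndarray:
    """stack: (participants, connections, tasks) -> 28x28 correlation."""
    mean = stack.mean(axis=0)  # connections x tasks
    centered = mean - mean.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    unit = centered / norms[:, None]
    mat = unit @ unit.T
    np.fill_diagonal(mat, 1.0)
    return mat


def _participant_permutation_difference(stack_a, stack_b, n_perm, rng):
    obs = np.sum(
        (_triu(_connection_matrix_from_stack(stack_a))
         - _triu(_connection_matrix_from_stack(stack_b))) ** 2
    )
    na = stack_a.shape[0]
    pooled = np.concatenate([stack_a, stack_b], axis=0)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        pa, pb = pooled[perm[:na]], pooled[perm[na:]]
        stat = np.sum(
            (_triu(_connection_matrix_from_stack(pa))
             - _triu(_connection_matrix_from_stack(pb))) ** 2
        )
        if stat >= obs:
            count += 1
    return float(obs), (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------


@dataclass
class MDSResult:
    coords: np.ndarray  # n x dim
    eigenvalues: np.ndarray  # sorted descending, full spectrum
    truncated_mass: float  # |negative eigenvalue| mass dropped
    node_names: list = None


def mds_embed(similarity, dim: int = 2, is_dissimilarity: bool = False) -> MDSResult:
    """Torgerson (classical) MDS of d = 1 - r.

    Double-centers -d^2/2 and keeps the top ``dim`` eigenvectors scaled
    by the square roots of their eigenvalues; negative eigenvalues are
    truncated and their mass logged.
    """
    names = None
    if isinstance(similarity, pd.DataFrame):
        names = list(similarity.index)
        similarity = similarity.to_numpy(dtype=float)
    s = np.asarray(similarity, dtype=float)
    n = s.shape[0]
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if dim > n - 1:
        raise ValueError(f"dim must be <= n - 1 = {n - 1}")
    d = s if is_dissimilarity else 1.0 - s
    j = np.eye(n) - np.ones((n, n)) / n
    bmat = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(bmat)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    neg_mass = float(np.abs(w[w < 0]).sum())
    pos_total = float(np.clip(w, 0, None).sum())
    if neg_mass > 0:
        logger.info(
            "mds: truncated negative eigenvalue mass %.3g (positive mass %.3g)",
            neg_mass,
            pos_total,
        )
    lam = np.clip(w[:dim], 0.0, None)
    coords = v[:, :dim] * np.sqrt(lam)
    return MDSResult(
        coords=coords, eigenvalues=w, truncated_mass=neg_mass, node_names=names
    )


# ---------------------------------------------------------------------------
# Distance tables
# ---------------------------------------------------------------------------


def distance_table(
    coords: np.ndarray, labels, cohort: str = None, node_names=None
) -> pd.DataFrame:
    """All pairwise Euclidean distances between embedded connection nodes.

    ``labels``: per-node dicts with ``connection``, ``hemisphere_type``
    and ``range_type`` keys (see :func:`execsim.rois.connection_labels`).
    A pair inherits a single hemisphere/range type only when both
    endpoints agree; otherwise the pair is labeled ``mixed``.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("need one label per embedded node")
    rows = []
    for i, j in combinations(range(n), 2):
        li, lj = labels[i], labels[j]
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        hemi_i, hemi_j = li["hemisphere_type"], lj["hemisphere_type"]
        range_i, range_j = li["range_type"], lj["range_type"]
        rows.append(
            dict(
                node_i=li["connection"],
                node_j=lj["connection"],
                distance=dist,
                hemisphere_type_i=hemi_i,
                hemisphere_type_j=hemi_j,
                hemisphere_type=hemi_i if hemi_i == hemi_j else "mixed",
                range_type_i=range_i,
                range_type_j=range_j,
                range_type=range_i if range_i == range_j else "mixed",
                cohort=cohort,
            )
        )
    return pd.DataFrame(rows)


def procrustes_residual(x: np.ndarray, y: np.ndarray) -> float:
    """Residual after optimally rotating/reflecting+translating y onto x
    (no scaling mismatch beyond a global factor)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    u, _, vt = np.linalg.svd(yc.T @ xc)
    rot = u @ vt
    aligned = yc @ rot
    denom = np.linalg.norm(xc)
    if denom == 0:
        return float(np.linalg.norm(aligned))
    return float(np.linalg.norm(aligned - xc) / denom)
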