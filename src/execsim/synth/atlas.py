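"""Planted activation maps with controlled pairwise overlap.

Each executive contrast gets one Gaussian blob.  At the amplitude
threshold the suprathreshold set of a blob is a ball, so the pairwise
voxel-overlap fraction is a monotone function of the distance between
blob centers; target overlaps are converted to center distances
analytically, the four centers are embedded in 3D, and the distances are
then refined against voxel counts on the actual grid.
"""

from __future__ import annotations

import numpy as np

from execsim.core import TASK_TYPES, AcquisitionSpec, voxel_centers_mm

DEFAULT_BLOB_SIGMA_MM = 10.0
DEFAULT_THRESHOLD_FRAC = 0.5
OVERLAP_TOL = 0.03


def ball_radius_mm(sigma_mm: float, threshold_frac: float) -> float:
    """Radius of the suprathreshold ball of a unit-peak Gaussian blob."""
    return sigma_mm * np.sqrt(2.0 * np.log(1.0 / threshold_frac))


def overlap_fraction_of_distance(d: float, radius: float) -> float:
    """Lens volume of two equal balls over one ball volume (continuous)."""
    if d <= 0:
        return 1.0
    if d >= 2 * radius:
        return 0.0
    return (4 * radius + d) * (2 * radius - d) ** 2 / (16 * radius**3)


def distance_for_overlap(target: float, radius: float, margin_mm: float = 4.5) -> float:
    """Invert the overlap curve by bisection (monotone decreasing in d)."""
    if not 0.0 <= target <= 1.0:
        raise ValueError("overlap targets must lie in [0, 1]")
    if target >= 1.0:
        return 0.0
    if target <= 0.0:
        return 2 * radius + margin_mm
    lo, hi = 0.0, 2 * radius
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if overlap_fraction_of_distance(mid, radius) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _embed_distances(dist: np.ndarray, dim: int = 3) -> np.ndarray:
    """Classical MDS of a small distance matrix; raises if not embeddable."""
    n = dist.shape[0]
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if np.any(w[:dim] < -1e-6 * max(w.max(), 1.0)):
        raise ValueError("overlap targets are metrically inconsistent")
    coords = v[:, :dim] * np.sqrt(np.clip(w[:dim], 0.0, None))
    # residual mass outside `dim` dimensions means the targets conflict
    resid = np.sqrt(np.clip(w[dim:], 0.0, None) ** 2).sum()
    total = np.clip(w, 0.0, None).sum()
    if total > 0 and w[dim:].clip(0.0, None).sum() > 0.02 * total:
        raise ValueError(
            "overlap targets cannot be realized by 4 blob centers in 3D "
            "(triangle-type inconsistency)"
        )
    return coords


def _gaussian_blob(coords_mm: np.ndarray, center: np.ndarray, sigma: float) -> np.ndarray:
    r2 = ((coords_mm - center) ** 2).sum(axis=-1)
    return np.exp(-r2 / (2.0 * sigma**2))


def _realized_overlaps(masks: list) -> np.ndarray:
    n = len(masks)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = masks[i].sum(), masks[j].sum()
            inter = np.logical_and(masks[i], masks[j]).sum()
            if a == 0 and b == 0:
                f = 0.0
            else:
                fa = inter / a if a else 0.0
                fb = inter / b if b else 0.0
                f = 0.5 * (fa + fb)
            out[i, j] = out[j, i] = f
    return out


def make_activation_atlas(
    targets,
    acq: AcquisitionSpec = None,
    amplitude: float = 1.0,
    sigma_mm: float = DEFAULT_BLOB_SIGMA_MM,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    center_mm=None,
    max_iter: int = 12,
    tol: float = OVERLAP_TOL,
):
    """Build one amplitude map per executive contrast.

    Parameters
    ----------
    targets : float or (4, 4) array
        Pairwise overlap fractions; a scalar applies to every pair.
    amplitude : float
        Peak amplitude, in percent signal change.

    Returns
    -------
    maps : dict of task type -> 3D array
    realized : (4, 4) array of voxel-counted overlap fractions
    centers : (4, 3) blob centers in mm
    """
    if acq is None:
        acq = AcquisitionSpec.attention()
    n = len(TASK_TYPES)
    t = np.asarray(targets, dtype=float)
    if t.ndim == 0:
        t = np.full((n, n), float(t))
        np.fill_diagonal(t, 1.0)
    if t.shape != (n, n):
        raise ValueError("targets must be scalar or 4x4")
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("overlap targets must lie in [0, 1]")
    if not np.allclose(t, t.T):
        raise ValueError("target matrix must be symmetric")

    radius = ball_radius_mm(sigma_mm, threshold_frac)
    coords_mm = voxel_centers_mm(acq.grid_shape, acq.affine)
    if center_mm is None:
        center_mm = coords_mm.reshape(-1, 3).mean(axis=0)
    center_mm = np.asarray(center_mm, dtype=float)

    iu = np.triu_indices(n, 1)
    # continuous-model initialization
    dist = np.zeros((n, n))
    for i, j in zip(*iu):
        dist[i, j] = dist[j, i] = distance_for_overlap(t[i, j], radius)

    identical = np.allclose(t[iu], 1.0)
    best = None
    for _ in range(max_iter):
        if identical:
            centers = np.tile(center_mm, (n, 1))
        else:
            centers = _embed_distances(dist) + center_mm
        maps = {
            name: amplitude * _gaussian_blob(coords_mm, centers[k], sigma_mm)
            for k, name in enumerate(TASK_TYPES)
        }
        masks = [maps[name] > threshold_frac * amplitude for name in TASK_TYPES]
        realized = _realized_overlaps(masks)
        err = np.abs(realized - t)[iu]
        if best is None or err.max() < best[0]:
            best = (err.max(), maps, realized, centers)
        if err.max() <= tol or identical:
            break
        # correct each pair's distance through the continuous inverse
        for i, j in zip(*iu):
            want = np.clip(2 * t[i, j] - realized[i, j], 0.0, 1.0)
            blend = 0.5 * (
                distance_for_overlap(want, radius)
                + distance_for_overlap(t[i, j], radius)
            )
            dist[i, j] = dist[j, i] = 0.5 * dist[i, j] + 0.5 * blend

    err_max, maps, realized, centers = best
    if err_max > tol:
        raise RuntimeError(
            f"could not realize overlap targets on this grid "
            f"(worst error {err_max:.3f} > {tol})"
        )
    return maps, realized, centers
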