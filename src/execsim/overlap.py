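"""Height + extent thresholding, cluster labeling, activation overlap,
conjunction maps and conjunction-derived spherical ROIs.

Both inequalities are strict: a voxel survives when t > t_min and a
cluster survives when its size > k_min.  The primary overlap measure is
the mean of the two directional percentages; Jaccard and the directional
fractions are always co-emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from execsim.core import TASK_TYPES
from execsim.glm import ContrastMap
from execsim.rois import ROI, ROISet

logger = logging.getLogger(__name__)

DEFAULT_GROUP_THRESHOLD = (2.7, 250)
DEFAULT_PARTICIPANT_THRESHOLD = (1.3, 100)
DEFAULT_CONNECTIVITY = 26


@dataclass(frozen=True)
class ThresholdSpec:
    t_min: float
    k_min: int
    connectivity: int = DEFAULT_CONNECTIVITY
    level: str = "group"

    def __post_init__(self):
        if self.k_min < 0:
            raise ValueError("k_min must be non-negative")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @classmethod
    def group(cls, t_min=None, k_min=None, connectivity=DEFAULT_CONNECTIVITY):
        t0, k0 = DEFAULT_GROUP_THRESHOLD
        return cls(t0 if t_min is None else t_min, k0 if k_min is None else k_min,
                   connectivity, "group")

    @classmethod
    def participant(cls, t_min=None, k_min=None, connectivity=DEFAULT_CONNECTIVITY):
        t0, k0 = DEFAULT_PARTICIPANT_THRESHOLD
        return cls(t0 if t_min is None else t_min, k0 if k_min is None else k_min,
                   connectivity, "participant")


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterMap:
    labels: np.ndarray  # 3D int, 0 = background
    table: pd.DataFrame  # label, size, com mm, peak t, peak mm
    affine: np.ndarray
    spec: ThresholdSpec = None

    @property
    def retained(self) -> np.ndarray:
        return self.labels > 0

    def n_voxels(self) -> int:
        return int(self.retained.sum())


def label_components(binary: np.ndarray, connectivity: int = 26):
    """Connected-component labeling of a 3D binary map."""
    labels, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    return labels, n


def threshold_and_cluster(cmap: ContrastMap, spec: ThresholdSpec) -> ClusterMap:
    """Suprathreshold (t > t_min) components; drop those with size <= k_min."""
    mask = cmap.mask
    if mask is None or not mask.any():
        raise ValueError("contrast map has an empty mask")
    t = np.where(mask, cmap.t, -np.inf)
    binary = t > spec.t_min
    raw_labels, n = label_components(binary, spec.connectivity)

    out = np.zeros_like(raw_labels)
    rows = []
    next_label = 0
    sizes = ndimage.sum_labels(binary, raw_labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]  # largest first -> labels contiguous from 1
    for idx in order:
        lab = idx + 1
        size = int(sizes[idx])
        if size <= spec.k_min:
            continue
        next_label += 1
        sel = raw_labels == lab
        out[sel] = next_label
        ijk = np.argwhere(sel)
        com_vox = ijk.mean(axis=0)
        com_mm = (cmap.affine @ np.append(com_vox, 1.0))[:3]
        tv = cmap.t[sel]
        peak_vox = ijk[np.argmax(tv)]
        peak_mm = (cmap.affine @ np.append(peak_vox, 1.0))[:3]
        rows.append(
            dict(
                label=next_label,
                size=size,
                com_x=com_mm[0], com_y=com_mm[1], com_z=com_mm[2],
                peak_t=float(tv.max()),
                peak_x=peak_mm[0], peak_y=peak_mm[1], peak_z=peak_mm[2],
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["label", "size", "com_x", "com_y", "com_z", "peak_t",
                 "peak_x", "peak_y", "peak_z"],
    )
    return ClusterMap(labels=out, table=table, affine=cmap.affine, spec=spec)


# ---------------------------------------------------------------------------
# Overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    percent: float  # mean of the two directional percentages
    jaccard: float
    percent_a_in_b: float
    percent_b_in_a: float
    n_a: int
    n_b: int
    n_intersection: int


def overlap_percentage(a: ClusterMap, b: ClusterMap) -> OverlapResult:
    """Overlap between two retained suprathreshold voxel sets."""
    if a.labels.shape != b.labels.shape or not np.allclose(a.affine, b.affine):
        raise ValueError("cluster maps are not on the same grid")
    sa, sb = a.retained, b.retained
    na, nb = int(sa.sum()), int(sb.sum())
    ni = int(np.logical_and(sa, sb).sum())
    fa = 100.0 * ni / na if na else 0.0
    fb = 100.0 * ni / nb if nb else 0.0
    if na == 0 and nb == 0:
        percent = 0.0
    else:
        percent = 0.5 * (fa + fb) if (na and nb) else 0.0
    union = na + nb - ni
    jac = 100.0 * ni / union if union else 0.0
    return OverlapResult(
        percent=percent,
        jaccard=jac,
        percent_a_in_b=fa,
        percent_b_in_a=fb,
        n_a=na,
        n_b=nb,
        n_intersection=ni,
    )


def overlap_matrix(maps: dict) -> pd.DataFrame:
    """Symmetric 4x4 percentage matrix over the executive contrasts."""
    names = [t for t in TASK_TYPES if t in maps]
    if len(names) != len(maps):
        names = list(maps)
    out = pd.DataFrame(100.0 * np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            res = overlap_percentage(maps[a], maps[b])
            out.loc[a, b] = out.loc[b, a] = res.percent
    return out


def conjunction_count_map(maps) -> np.ndarray:
    """Voxelwise count of contrasts whose retained set contains the voxel."""
    if isinstance(maps, dict):
        maps = list(maps.values())
    counts = np.zeros(maps[0].labels.shape, dtype=int)
    for m in maps:
        if m.labels.shape != counts.shape:
            raise ValueError("conjunction inputs are not on a common grid")
        counts += m.retained.astype(int)
    return counts


# ---------------------------------------------------------------------------
# ROI derivation
# ---------------------------------------------------------------------------


def derive_executive_rois(
    cohort_conjunctions,
    affine,
    min_cohorts: int = 2,
    radius_mm: float = 7.0,
    k_min: int = 10,
    connectivity: int = DEFAULT_CONNECTIVITY,
    prototypes: dict = None,
) -> ROISet:
    """Spheres at the centers of clusters where all four contrasts overlap
    in at least ``min_cohorts`` cohorts.

    ``cohort_conjunctions`` are binary 3D maps (count == 4 per cohort);
    ``prototypes`` maps region-class names to mm centers for labeling.
    """
    stacked = np.stack([np.asarray(m, dtype=bool) for m in cohort_conjunctions])
    agreement = stacked.sum(axis=0) >= min_cohorts
    labels, n = label_components(agreement, connectivity)
    rois = []
    idx = 0
    sizes = ndimage.sum_labels(agreement, labels, index=np.arange(1, n + 1)) if n else []
    order = np.argsort(sizes)[::-1] if n else []
    for oi in order:
        lab = oi + 1
        if sizes[oi] <= k_min:
            continue
        ijk = np.argwhere(labels == lab)
        com = ijk.mean(axis=0)
        center = tuple((np.asarray(affine) @ np.append(com, 1.0))[:3])
        hemisphere = "L" if center[0] < 0 else "R"
        region_class = None
        if prototypes:
            dists = {
                cls: np.linalg.norm(np.asarray(center) - np.asarray(c))
                for cls, c in prototypes.items()
            }
            region_class = min(dists, key=dists.get)
        idx += 1
        rois.append(
            ROI(
                name=f"roi{idx:02d}_{hemisphere}{region_class or ''}",
                center_mm=center,
                radius_mm=radius_mm,
                hemisphere=hemisphere,
                region_class=region_class,
            )
        )
    if not rois:
        logger.warning("ROI derivation found no clusters; returning empty set")
    return ROISet(rois)


# ---------------------------------------------------------------------------
# Participant-level overlap analysis
# ---------------------------------------------------------------------------


def participant_overlap_analysis(
    contrast_maps: dict, spec: ThresholdSpec = None
) -> dict:
    """Liberal-threshold per-participant voxel counts and overlaps.

    ``contrast_maps`` maps the four contrast names to participant-level
    :class:`ContrastMap` objects.  Returns active-voxel counts per
    contrast and the six pairwise overlap percentages.
    """
    if spec is None:
        spec = ThresholdSpec.participant()
    clusters = {
        name: threshold_and_cluster(cmap, spec) for name, cmap in contrast_maps.items()
    }
    counts = {name: cm.n_voxels() for name, cm in clusters.items()}
    overlaps = {}
    names = list(clusters)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            overlaps[f"{a}--{b}"] = overlap_percentage(clusters[a], clusters[b]).percent
    return dict(active_voxels=counts, overlap_percent=overlaps)
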