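"""QC, confound regression and taskwise ROI-to-ROI connectivity.

Connectivity is computed on within-task frames of confound-regressed ROI
time courses: block frames are shifted by a hemodynamic lag (default two
frames, 5 s at TR 2.5 s) and concatenated across runs; the modality
switch "task" uses short windows after each post-switch trial.  Pearson
correlations per ROI pair are Fisher z-transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from execsim.core import (
    COND_DIVIDED,
    DISTRACTED_CONDITIONS,
    TASK_TYPES,
    Volume4D,
    block_intervals,
)
from execsim.rois import ROISet

logger = logging.getLogger(__name__)

DEFAULT_HRF_LAG_FRAMES = 2
MODSWI_WINDOW_FRAMES = 3
FD_ROTATION_RADIUS_MM = 50.0
DEFAULT_FD_MAX_MM = 0.9
DEFAULT_GLOBAL_Z_MAX = 5.0
MOTION_EXCLUSION_MM = 3.0
MOTION_EXCLUSION_FRACTION = 0.25
ATANH_CLIP = 1.0 - 1e-7
MIN_TASK_FRAMES = 8

TASK_BLOCK_CONDITIONS = {
    "DivA": {COND_DIVIDED},
    "DistrA": set(DISTRACTED_CONDITIONS),
    "WM": {"2back"},
}


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    dvars: np.ndarray
    outlier_flags: np.ndarray
    max_abs_motion_mm: np.ndarray
    excluded: bool
    reason: str = ""

    def to_jsonable(self):
        return dict(
            dvars_mean=float(self.dvars.mean()) if len(self.dvars) else 0.0,
            dvars_max=float(self.dvars.max()) if len(self.dvars) else 0.0,
            n_outliers=int(self.outlier_flags.sum()),
            max_abs_motion_mm=float(self.max_abs_motion_mm.max())
            if len(self.max_abs_motion_mm)
            else 0.0,
            excluded=bool(self.excluded),
            reason=self.reason,
        )


def _mode_intensity(values: np.ndarray, bins: int = 100) -> float:
    counts, edges = np.histogram(values, bins=bins)
    k = int(np.argmax(counts))
    return 0.5 * (edges[k] + edges[k + 1])


def compute_dvars(vol: Volume4D) -> np.ndarray:
    """RMS frame-to-frame signal change over the mask, mode-1000 scaled."""
    if vol.n_frames < 2:
        raise ValueError("DVARS needs at least 2 frames")
    if not vol.mask.any():
        raise ValueError("empty mask")
    y = vol.data[vol.mask]  # V x T
    mode = _mode_intensity(y.ravel())
    scale = 1000.0 / mode if mode != 0 else 1.0
    diffs = np.diff(y * scale, axis=1)
    return np.sqrt((diffs**2).mean(axis=0))


def framewise_displacement(
    motion: np.ndarray, rotation_radius_mm: float = FD_ROTATION_RADIUS_MM
) -> np.ndarray:
    """Sum of absolute backward differences; rotations mapped to mm on a
    sphere.  First frame gets 0."""
    motion = np.asarray(motion, dtype=float)
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def detect_outliers(
    motion: np.ndarray,
    global_signal: np.ndarray,
    fd_max_mm: float = DEFAULT_FD_MAX_MM,
    global_z_max: float = DEFAULT_GLOBAL_Z_MAX,
) -> np.ndarray:
    """Frame flags from framewise displacement and global-signal z."""
    fd = framewise_displacement(motion)
    g = np.asarray(global_signal, dtype=float)
    sd = g.std()
    gz = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)
    return (fd > fd_max_mm) | (np.abs(gz) > global_z_max)


def motion_exclusion(motion: np.ndarray) -> bool:
    """Exclude iff any-axis |translation| > 3 mm on strictly more than 25%
    of frames (both inequalities strict)."""
    motion = np.asarray(motion, dtype=float)
    violating = (np.abs(motion[:, :3]) > MOTION_EXCLUSION_MM).any(axis=1)
    return bool(violating.mean() > MOTION_EXCLUSION_FRACTION)


def qc_report(vol: Volume4D, motion: np.ndarray, **outlier_kw) -> QCReport:
    dvars = compute_dvars(vol)
    global_signal = vol.data[vol.mask].mean(axis=0)
    flags = detect_outliers(motion, global_signal, **outlier_kw)
    excluded = motion_exclusion(motion)
    return QCReport(
        dvars=dvars,
        outlier_flags=flags,
        max_abs_motion_mm=np.abs(np.asarray(motion)[:, :3]).max(axis=1),
        excluded=excluded,
        reason="head motion > 3 mm in over 25% of frames" if excluded else "",
    )


# ---------------------------------------------------------------------------
# Extraction and denoising
# ---------------------------------------------------------------------------


def extract_roi_timecourses(vol: Volume4D, rois: ROISet) -> pd.DataFrame:
    """Unweighted mean series per ROI; columns are ROI names."""
    member = rois.membership(vol.data.shape[:3], vol.affine, vol.mask)
    series = {}
    for name, m in member.items():
        if not m.any():
            raise ValueError(f"ROI {name!r} contains no masked voxels")
        series[name] = vol.data[m].mean(axis=0)
    return pd.DataFrame(series)


@dataclass
class ConfoundSet:
    """Nuisance series for denoising; all columns share the frame count."""

    motion: np.ndarray = None  # T x 6
    wm: np.ndarray = None
    csf: np.ndarray = None
    task_columns: pd.DataFrame = None  # HRF-convolved task/rest effects
    outlier_flags: np.ndarray = None

    def matrix(self, n_frames: int) -> np.ndarray:
        cols = []
        if self.motion is not None:
            cols.append(np.asarray(self.motion, float))
        for series in (self.wm, self.csf):
            if series is not None:
                cols.append(np.asarray(series, float)[:, None])
        if self.task_columns is not None:
            cols.append(self.task_columns.to_numpy(dtype=float))
        if self.outlier_flags is not None:
            flags = np.flatnonzero(self.outlier_flags)
            for f in flags:
                col = np.zeros((n_frames, 1))
                col[f] = 1.0
                cols.append(col)
        cols.append(np.ones((n_frames, 1)))
        out = np.hstack(cols)
        if out.shape[0] != n_frames:
            raise ValueError("confound column length mismatch")
        return out


def regress_confounds(roi_series: pd.DataFrame, confounds: ConfoundSet) -> pd.DataFrame:
    """Per-ROI OLS residuals against the confound matrix (+ intercept)."""
    y = roi_series.to_numpy(dtype=float)
    x = confounds.matrix(y.shape[0])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return pd.DataFrame(resid, columns=roi_series.columns)


# ---------------------------------------------------------------------------
# Frame selection
# ---------------------------------------------------------------------------


def task_frame_indices(
    events: pd.DataFrame,
    task: str,
    n_frames: int,
    tr: float,
    hrf_lag_frames: int = DEFAULT_HRF_LAG_FRAMES,
    modswi_window: int = MODSWI_WINDOW_FRAMES,
) -> np.ndarray:
    """Frames belonging to one executive task type, lag-shifted."""
    if task not in TASK_TYPES:
        raise ValueError(f"unknown task type {task!r}")
    if task == "ModSwi":
        sel = events[
            (events["condition"].isin(["1back", "2back"]))
            & (events["switch"] == "post_switch")
        ]
        frames = []
        for onset in sel["onset"].to_numpy(float):
            base = int(np.floor(onset / tr)) + hrf_lag_frames
            frames.extend(range(base, base + modswi_window))
    else:
        conditions = TASK_BLOCK_CONDITIONS[task]
        blocks = block_intervals(events)
        blocks = blocks[blocks["condition"].isin(conditions)]
        frames = []
        for _, row in blocks.iterrows():
            first = int(np.ceil(row["start"] / tr))
            last = int(np.ceil(row["end"] / tr))  # exclusive
            frames.extend(range(first + hrf_lag_frames, last + hrf_lag_frames))
    return np.unique([f for f in frames if 0 <= f < n_frames]).astype(int)


def frame_task_assignment(
    events: pd.DataFrame,
    n_frames: int,
    tr: float,
    hrf_lag_frames: int = DEFAULT_HRF_LAG_FRAMES,
) -> np.ndarray:
    """Per-frame task label (object array, None where unassigned).

    Modality-switch windows take precedence over the block task so the
    generator can inject switch-specific structure inside n-back blocks.
    """
    assignment = np.array([None] * n_frames, dtype=object)
    for task in ("DistrA", "DivA", "WM", "ModSwi"):
        idx = task_frame_indices(events, task, n_frames, tr, hrf_lag_frames)
        assignment[idx] = task
    return assignment


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


def fisher_z(r) -> np.ndarray:
    """atanh with |r| clipped away from 1 to keep z finite."""
    r = np.clip(np.asarray(r, dtype=float), -ATANH_CLIP, ATANH_CLIP)
    return np.arctanh(r)


@dataclass
class ConnectivityVector:
    participant: str
    task: str
    pair_labels: list  # list of (roi_i, roi_j)
    r: np.ndarray
    z: np.ndarray
    n_frames: int = 0

    def __len__(self):
        return len(self.z)


def taskwise_connectivity(
    runs,
    task: str,
    rois: ROISet,
    participant: str = "sub-00",
    hrf_lag_frames: int = DEFAULT_HRF_LAG_FRAMES,
) -> ConnectivityVector:
    """Fisher-z ROI-pair connectivity for one task type.

    ``runs`` is a list of ``(residual_roi_series, events, tr)`` tuples;
    frames of the task's blocks are concatenated across runs.
    """
    pieces = []
    for series, events, tr in runs:
        frames = task_frame_indices(
            events, task, len(series), tr, hrf_lag_frames=hrf_lag_frames
        )
        if len(frames):
            pieces.append(series.iloc[frames][rois.names])
    if not pieces:
        raise ValueError(f"no frames selected for task {task}")
    data = pd.concat(pieces, axis=0).to_numpy(dtype=float)
    if data.shape[0] < MIN_TASK_FRAMES:
        raise ValueError(
            f"only {data.shape[0]} frames selected for task {task}; need "
            f">= {MIN_TASK_FRAMES}"
        )
    sds = data.std(axis=0)
    dead = [rois.names[i] for i in np.flatnonzero(sds == 0)]
    if dead:
        raise ValueError(f"zero-variance ROI series: {dead}")
    corr = np.corrcoef(data.T)
    iu = np.triu_indices(len(rois), 1)
    r = corr[iu]
    return ConnectivityVector(
        participant=participant,
        task=task,
        pair_labels=rois.pairs(),
        r=r,
        z=fisher_z(r),
        n_frames=data.shape[0],
    )


def connectivity_long_table(vectors, cohort: str = None) -> pd.DataFrame:
    """Long-format table: participant, task, roi_i, roi_j, r, z."""
    rows = []
    for vec in vectors:
        for (a, b), r, z in zip(vec.pair_labels, vec.r, vec.z):
            rows.append(
                dict(
                    participant=vec.participant,
                    cohort=cohort,
                    task=vec.task,
                    roi_i=a,
                    roi_j=b,
                    r=float(r),
                    z=float(z),
                )
            )
    return pd.DataFrame(rows)
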