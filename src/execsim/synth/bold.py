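"""Forward BOLD simulation on a desk-scale grid.

Voxel signal = baseline * (1 + sum(condition regressor x planted
amplitude) / 100) + ROI-structured noise + white noise + slow drift.
The condition regressors are built by the same design-matrix code the
GLM uses, so with zero noise the GLM recovers planted amplitudes
exactly.  ROI-structured noise is injected blockwise: frames belonging
to an executive task type receive a latent multivariate draw with that
task's planted ROI correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from execsim.connectivity import frame_task_assignment
from execsim.core import (
    COND_DIVIDED,
    DISTRACTED_CONDITIONS,
    TASK_TYPES,
    AcquisitionSpec,
    CohortConfig,
    Volume4D,
    as_rng,
)
from execsim.glm import build_design_matrix
from execsim.rois import ROI, ROISet
from execsim.synth.connstruct import (
    matrix_to_vector,
    vector_to_matrix,
    _make_positive_definite,
)

BASELINE = 100.0

#: planted desk-scale executive ROI centers (mm on the centered grid)
DESK_ROI_CENTERS_MM = {
    "rMFG": (21.0, 18.0, 15.0),
    "lMFG": (-21.0, 18.0, 15.0),
    "rSMA": (9.0, 9.0, 24.0),
    "lSMA": (-9.0, 9.0, 24.0),
    "rPrc": (9.0, -27.0, 21.0),
    "lPrc": (-9.0, -27.0, 21.0),
    "rSPL": (21.0, -24.0, 12.0),
    "lSPL": (-21.0, -24.0, 12.0),
}

#: fractional grid positions of the background proxy regions
PROXY_REGION_FRACTIONS = {
    "wm_proxy": (0.18, 0.85, 0.18),
    "csf_proxy": (0.82, 0.85, 0.18),
}
PROXY_RADIUS_MM = 6.0


def default_roi_set(radius_mm: float = 7.0) -> ROISet:
    """Planted desk-grid executive ROIs (4 region classes x 2 hemispheres)."""
    rois = []
    for name, center in DESK_ROI_CENTERS_MM.items():
        rois.append(
            ROI(
                name=name,
                center_mm=center,
                radius_mm=radius_mm,
                hemisphere="R" if name.startswith("r") else "L",
                region_class=name[1:],
            )
        )
    return ROISet(rois)


def proxy_region_masks(acq: AcquisitionSpec) -> dict:
    """Background regions standing in for white-matter / CSF masks.

    Centers are placed at fixed fractional grid positions so any grid
    size gets non-empty proxies (falling back to the nearest voxel)."""
    from execsim.core import voxel_centers_mm

    coords = voxel_centers_mm(acq.grid_shape, acq.affine)
    lo = coords.reshape(-1, 3).min(axis=0)
    hi = coords.reshape(-1, 3).max(axis=0)
    out = {}
    for name, frac in PROXY_REGION_FRACTIONS.items():
        center = lo + np.asarray(frac) * (hi - lo)
        d2 = ((coords - center) ** 2).sum(axis=-1)
        mask = d2 <= PROXY_RADIUS_MM**2
        if not mask.any():
            mask = d2 == d2.min()
        out[name] = mask
    return out


def perturb_connectivity(conn_matrices: dict, pattern_noise_sd: float, rng) -> dict:
    """Participant-level idiosyncrasy: jitter planted matrices on the z scale."""
    if pattern_noise_sd <= 0:
        return conn_matrices
    out = {}
    for task, mat in conn_matrices.items():
        v = matrix_to_vector(mat)
        z = np.arctanh(np.clip(v, -0.98, 0.98))
        z = z + pattern_noise_sd * rng.standard_normal(z.shape)
        out[task] = _make_positive_definite(vector_to_matrix(np.tanh(z), mat.shape[0]))
    return out


def _condition_amplitudes(labels, atlas: dict, grid_shape) -> np.ndarray:
    """P x (voxels) planted amplitude per design column (percent)."""
    zero = np.zeros(grid_shape)

    def amp_for(label):
        parts = label.split("|")
        cond = parts[0]
        if cond == COND_DIVIDED:
            return atlas["DivA"] + atlas["DistrA"]
        if cond in DISTRACTED_CONDITIONS:
            return atlas["DistrA"]
        if cond in ("1back", "2back"):
            if parts[1] == "post":
                return atlas["WM"] + atlas["ModSwi"]
            return atlas["WM"]
        return zero

    return np.stack([amp_for(lab).ravel() for lab in labels], axis=0)


@dataclass
class SimulatedRun:
    volume: Volume4D
    motion: np.ndarray  # n_volumes x 6
    events: "object"
    spike_frames: list


def simulate_motion(n_frames: int, motion_sd: float, rng, n_spikes: int = 0):
    """Random-walk realignment parameters; optional planted jumps."""
    steps = rng.standard_normal((n_frames, 6))
    steps[:, :3] *= motion_sd
    steps[:, 3:] *= motion_sd * 0.02  # radians
    motion = np.cumsum(steps, axis=0)
    motion -= motion[0]
    spikes = []
    if n_spikes:
        frames = rng.choice(np.arange(5, n_frames - 1), size=n_spikes, replace=False)
        for f in sorted(int(x) for x in frames):
            motion[f:, 0] += 2.0  # 2 mm translation jump
            spikes.append(f)
    return motion, spikes


def simulate_bold(
    schedule,
    atlas: dict,
    conn_matrices: dict,
    acq: AcquisitionSpec,
    cohort: CohortConfig = None,
    rng_seed=0,
    baseline: float = BASELINE,
    noise_sd: float = None,
    roi_noise_sd: float = 1.2,
    drift_sd: float = 0.5,
    roi_set: ROISet = None,
    hrf_lag_frames: int = 2,
    n_motion_spikes: int = 0,
) -> SimulatedRun:
    """Simulate one run.  ``atlas`` maps the four contrast names to 3D
    amplitude maps (percent signal change); ``conn_matrices`` maps task
    types to planted ROI correlation matrices (may be empty)."""
    rng = as_rng(rng_seed)
    if cohort is not None and noise_sd is None:
        noise_sd = cohort.noise_sd
    if noise_sd is None:
        noise_sd = 1.0
    n_frames = acq.n_volumes
    grid = tuple(acq.grid_shape)
    n_vox = int(np.prod(grid))

    design = build_design_matrix(schedule, (n_frames, acq.tr_seconds))
    cond_labels = [lab for lab, conv in design.convolved.items() if conv and "|" in lab]

    signal = np.full((n_frames, n_vox), baseline)
    if atlas and cond_labels:
        amps = _condition_amplitudes(cond_labels, atlas, grid)
        x = design.values[cond_labels].to_numpy(dtype=float)
        signal = signal * (1.0 + (x @ amps) / 100.0)

    noise = rng.standard_normal((n_frames, n_vox)) * noise_sd

    if drift_sd > 0:
        t = np.arange(n_frames) / n_frames
        drift = np.zeros(n_frames)
        for k in (1, 2):
            drift += rng.standard_normal() * np.cos(np.pi * k * t)
        drift_map = rng.standard_normal(n_vox) * drift_sd
        noise += np.outer(drift, drift_map)

    if conn_matrices:
        if roi_set is None:
            roi_set = default_roi_set()
        member = roi_set.membership(grid, acq.affine)
        flat_members = [np.flatnonzero(member[n].ravel()) for n in roi_set.names]
        assignment = frame_task_assignment(
            schedule, n_frames, acq.tr_seconds, hrf_lag_frames=hrf_lag_frames
        )
        chol = {
            task: np.linalg.cholesky(conn_matrices[task])
            for task in TASK_TYPES
            if task in conn_matrices
        }
        latent = np.zeros((n_frames, len(roi_set)))
        for f in range(n_frames):
            task = assignment[f]
            if task in chol:
                latent[f] = chol[task] @ rng.standard_normal(len(roi_set))
        latent *= roi_noise_sd
        for k, vox in enumerate(flat_members):
            noise[:, vox] += latent[:, [k]]

    data = (signal + noise).T.reshape(grid + (n_frames,))
    if not np.all(np.isfinite(data)):
        raise FloatingPointError("simulated volume contains non-finite values")

    motion, spikes = simulate_motion(
        n_frames, cohort.motion_sd if cohort else 0.05, rng, n_spikes=n_motion_spikes
    )
    vol = Volume4D(data, acq.affine.copy(), acq.tr_seconds)
    return SimulatedRun(volume=vol, motion=motion, events=schedule, spike_frames=spikes)
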