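"""Core data structures shared across the pipeline.

Volumes are plain numpy arrays wrapped with their affine and repetition
time; event tables are pandas DataFrames with a fixed column contract
(BIDS-like ``onset``/``duration`` plus task annotations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Condition vocabulary
# ---------------------------------------------------------------------------

COND_ATT_AUD = "attend_auditory"
COND_ATT_VIS = "attend_visual"
COND_DIS_TEXT = "attend_auditory_text_distractor"
COND_DIS_SPEECH = "attend_visual_speech_distractor"
COND_DIS_MUSIC = "attend_visual_music_distractor"
COND_DIVIDED = "divided_attention"
COND_REST = "rest"
COND_INSTRUCTION = "instruction"

UNDISTRACTED_CONDITIONS = (COND_ATT_AUD, COND_ATT_VIS)
DISTRACTED_CONDITIONS = (COND_DIS_TEXT, COND_DIS_SPEECH, COND_DIS_MUSIC)
ATTENTION_TASK_CONDITIONS = (
    COND_ATT_AUD,
    COND_ATT_VIS,
    COND_DIS_TEXT,
    COND_DIS_SPEECH,
    COND_DIS_MUSIC,
    COND_DIVIDED,
)

NBACK_LEVELS = ("0back", "1back", "2back")
SWITCH_FLAGS = ("pre_switch", "post_switch", "nonswitch", "n/a")

#: the four executive analysis task types
TASK_TYPES = ("DivA", "DistrA", "WM", "ModSwi")

COHORT_LABELS = ("middle_adolescent", "late_adolescent", "young_adult")

EVENT_COLUMNS = (
    "onset",
    "duration",
    "task",
    "condition",
    "modality",
    "switch",
    "congruent",
    "block",
    "correct",
)


# ---------------------------------------------------------------------------
# Acquisition geometry
# ---------------------------------------------------------------------------


def centered_affine(grid_shape, voxel_size_mm) -> np.ndarray:
    """Affine that puts the geometric center of the grid at mm (0, 0, 0).

    Keeps left/right placement meaningful: x < 0 is the left hemisphere.
    """
    grid_shape = np.asarray(grid_shape, dtype=float)
    voxel = np.asarray(voxel_size_mm, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(voxel)
    affine[:3, 3] = -(grid_shape - 1) / 2.0 * voxel
    return affine


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and timing of one functional run."""

    tr_seconds: float = 2.5
    n_volumes: int = 222
    n_dummy: int = 4
    grid_shape: tuple = (24, 28, 24)
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    affine: np.ndarray = None

    def __post_init__(self):
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_volumes <= 0:
            raise ValueError("n_volumes must be positive")
        if self.n_dummy < 0 or self.n_dummy >= self.n_volumes:
            raise ValueError("n_dummy must satisfy 0 <= n_dummy < n_volumes")
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.affine is None:
            object.__setattr__(
                self, "affine", centered_affine(self.grid_shape, self.voxel_size_mm)
            )
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
                raise ValueError("affine must be invertible")
            object.__setattr__(self, "affine", aff)

    @property
    def run_seconds(self) -> float:
        """Total scan time including dummy frames."""
        return self.n_volumes * self.tr_seconds

    @property
    def task_seconds(self) -> float:
        """Usable time after dummy removal."""
        return (self.n_volumes - self.n_dummy) * self.tr_seconds

    @property
    def dummy_seconds(self) -> float:
        return self.n_dummy * self.tr_seconds

    @classmethod
    def attention(cls, **kw) -> "AcquisitionSpec":
        return cls(n_volumes=kw.pop("n_volumes", 222), **kw)

    @classmethod
    def nback(cls, **kw) -> "AcquisitionSpec":
        return cls(n_volumes=kw.pop("n_volumes", 155), **kw)


# ---------------------------------------------------------------------------
# 4D volumes
# ---------------------------------------------------------------------------


@dataclass
class Volume4D:
    """Gridded BOLD series with affine, TR and a spatial mask."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (X, Y, Z, T)")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match spatial shape")

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr_seconds

    def voxel_centers_mm(self) -> np.ndarray:
        """(X, Y, Z, 3) array of voxel-center coordinates in mm."""
        return voxel_centers_mm(self.data.shape[:3], self.affine)

    def copy(self) -> "Volume4D":
        return Volume4D(
            self.data.copy(), self.affine.copy(), self.tr_seconds, self.mask.copy()
        )


def voxel_centers_mm(grid_shape, affine) -> np.ndarray:
    nx, ny, nz = grid_shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    return np.einsum("ab,xyzb->xyza", np.asarray(affine, float), vox)[..., :3]


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------


def empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset": pd.Series(dtype=float),
            "duration": pd.Series(dtype=float),
            "task": pd.Series(dtype=object),
            "condition": pd.Series(dtype=object),
            "modality": pd.Series(dtype=object),
            "switch": pd.Series(dtype=object),
            "congruent": pd.Series(dtype=object),
            "block": pd.Series(dtype=object),
            "correct": pd.Series(dtype=object),
        }
    )


def validate_events(events: pd.DataFrame, run_seconds: float = None) -> None:
    """Check the event-table contract; raise ``ValueError`` on violation."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")
    onsets = events["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise ValueError("event onsets must be non-decreasing")
    if run_seconds is not None:
        ends = onsets + events["duration"].to_numpy(dtype=float)
        if len(ends) and ends.max() > run_seconds + 1e-9:
            over = ends.max() - run_seconds
            raise ValueError(
                f"schedule exceeds run length by {over:.2f} s "
                f"(last event ends at {ends.max():.2f} s, run is {run_seconds:.2f} s)"
            )
    bad = events[
        (events["switch"] != "n/a") & (~events["condition"].isin(NBACK_LEVELS))
    ]
    if len(bad):
        raise ValueError("switch flags are only defined for n-back trials")


def shift_event_onsets(events: pd.DataFrame, shift_seconds: float) -> pd.DataFrame:
    out = events.copy()
    out["onset"] = out["onset"] - shift_seconds
    return out


#: seconds a trial occupies past stimulus offset (response/retention window)
TRIAL_TAIL_SECONDS = {"attention": 2.5, "nback": 2.5}


def block_intervals(events: pd.DataFrame) -> pd.DataFrame:
    """Start/end time in seconds for every non-instruction block."""
    ev = events[events["task"] != "instruction"]
    grouped = ev.groupby("block", sort=False)
    out = grouped.agg(
        start=("onset", "min"),
        condition=("condition", "first"),
        task=("task", "first"),
    )
    ends = grouped.apply(
        lambda g: float((g["onset"] + g["duration"]).max()), include_groups=False
    )
    tail = out["task"].map(TRIAL_TAIL_SECONDS).fillna(0.0)
    out["end"] = ends + tail
    return out.reset_index()


# ---------------------------------------------------------------------------
# Cohorts and planted ground truth
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """One simulated age cohort."""

    label: str = "young_adult"
    n_participants: int = 12
    female_fraction: float = 0.5
    noise_sd: float = 1.0
    motion_sd: float = 0.05
    seed: int = 0
    #: target pairwise activation-map overlap fraction (all pairs)
    overlap_target: float = 0.4
    #: target cross-task connectivity-pattern similarity
    similarity_target: float = 0.6
    #: multiplicative between-participant spread of activation amplitude
    amplitude_jitter: float = 0.15
    #: sd of participant-level task-pattern idiosyncrasy on the z scale
    pattern_noise_sd: float = 0.12

    def __post_init__(self):
        if self.label not in COHORT_LABELS:
            raise ValueError(f"unknown cohort label {self.label!r}")
        if self.n_participants < 2:
            raise ValueError("cohorts need n_participants >= 2")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth emitted with every simulated cohort."""

    overlap_fractions: np.ndarray = None  # 4x4 symmetric, diagonal 1
    connectivity_similarity: float = None
    activation_amplitude: float = None  # percent signal change
    roi_centers_mm: dict = None
    behavior_means: dict = None  # task type -> mean percent correct
    behavior_sds: dict = None
    realized_overlaps: np.ndarray = None
    realized_similarities: np.ndarray = None
    spike_frames: dict = field(default_factory=dict)
    seed: int = None

    def to_jsonable(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {k: conv(v) for k, v in self.__dict__.items()}


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, or a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def substream(master_seed: int, *key) -> np.random.Generator:
    """Counter-based substream: stable under changes elsewhere in the tree."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    )
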