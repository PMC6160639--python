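"""Behavioral accuracy simulation.

Block accuracies are drawn from a truncated normal in [0, 100] around a
task-family mean plus cohort, gender and participant offsets; trials are
Bernoulli within the block.  Within n-back blocks the trial mean also
depends on load level and switch status so that the four analysis scores
(DivA, DistrA, WM, ModSwi) have distinct planted means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr, ndtri

from execsim.core import (
    COND_DIVIDED,
    DISTRACTED_CONDITIONS,
    UNDISTRACTED_CONDITIONS,
    CohortConfig,
    as_rng,
)

#: default task-family accuracy means / SDs (percent correct)
DEFAULT_TASK_MEANS = {"DivA": 73.82, "DistrA": 88.33, "WM": 86.23, "ModSwi": 90.08}
DEFAULT_TASK_SDS = {"DivA": 8.78, "DistrA": 8.29, "WM": 9.72, "ModSwi": 8.24}

#: qualitative cohort offsets: middle adolescents lowest
DEFAULT_COHORT_OFFSETS = {
    "middle_adolescent": -5.5,
    "late_adolescent": 2.0,
    "young_adult": 3.0,
}


@dataclass
class BehaviorParams:
    task_means: dict = field(default_factory=lambda: dict(DEFAULT_TASK_MEANS))
    task_sds: dict = field(default_factory=lambda: dict(DEFAULT_TASK_SDS))
    cohort_offsets: dict = field(default_factory=lambda: dict(DEFAULT_COHORT_OFFSETS))
    gender_offset_female: float = 0.9
    participant_sd: float = 6.0
    block_sd: float = 5.0
    undistracted_bonus: float = 4.0
    zero_back_mean: float = 95.0
    one_back_bonus: float = 3.0
    pre_switch_bonus: float = 2.0


def default_behavior_params() -> BehaviorParams:
    return BehaviorParams()


def trial_means(events, p: BehaviorParams) -> np.ndarray:
    """Planted mean percent correct per trial row (vectorized)."""
    cond = events["condition"].to_numpy()
    switch = events["switch"].to_numpy()
    out = np.full(len(events), np.nan)
    out[cond == COND_DIVIDED] = p.task_means["DivA"]
    out[np.isin(cond, DISTRACTED_CONDITIONS)] = p.task_means["DistrA"]
    out[np.isin(cond, UNDISTRACTED_CONDITIONS)] = (
        p.task_means["DistrA"] + p.undistracted_bonus
    )
    out[cond == "0back"] = p.zero_back_mean
    nback = np.isin(cond, ("1back", "2back"))
    out[nback] = p.task_means["WM"]
    out[nback & (cond == "1back")] += p.one_back_bonus
    out[nback & (switch == "pre_switch")] += p.pre_switch_bonus
    out[nback & (switch == "post_switch")] = p.task_means["ModSwi"]
    return out


def _truncnorm_draw(mean: float, sd: float, rng) -> float:
    """Truncated-normal draw on [0, 100] via inverse-CDF sampling."""
    if sd <= 0:
        return float(np.clip(mean, 0.0, 100.0))
    lo = ndtr((0.0 - mean) / sd)
    hi = ndtr((100.0 - mean) / sd)
    u = lo + (hi - lo) * rng.random()
    return float(mean + sd * ndtri(u))


def simulate_behavior(
    cohort: CohortConfig,
    schedule,
    rng_seed=0,
    params: BehaviorParams = None,
    gender: str = "female",
    participant_offset: float = None,
):
    """Return a copy of ``schedule`` with the ``correct`` column filled."""
    p = params or default_behavior_params()
    rng = as_rng(rng_seed)
    offset = p.cohort_offsets.get(cohort.label, 0.0) if cohort is not None else 0.0
    if gender == "female":
        offset += p.gender_offset_female
    if participant_offset is None:
        participant_offset = p.participant_sd * rng.standard_normal()
    offset += participant_offset

    out = schedule.copy()
    trial_mask = (
        out["task"].isin(["attention", "nback"]) & (out["condition"] != "rest")
    ).to_numpy()
    means_all = trial_means(out, p)
    blocks = out["block"].to_numpy()
    correct = np.array([None] * len(out), dtype=object)

    for block in pd.unique(blocks[trial_mask]):
        idx = np.flatnonzero(trial_mask & (blocks == block))
        means = means_all[idx]
        center = float(np.nanmean(means))
        block_score = _truncnorm_draw(center + offset, p.block_sd, rng)
        trial_p = np.clip(block_score + (means - center), 0.0, 100.0) / 100.0
        correct[idx] = rng.random(len(idx)) < trial_p
    out["correct"] = correct
    return out
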