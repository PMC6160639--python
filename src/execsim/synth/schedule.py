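"""Event schedules for the two task paradigms.

An attention run holds one rest block plus seven task blocks (five
conditions once, divided attention twice), twelve 2.5 s sentences per
block, each followed by a 2.5 s response window.  An n-back run holds
one block per load level (0-, 1-, 2-back), 32 vowels per block
(0.5 s stimulus + 2.5 s retention), with the stimulus modality switching
after runs of 3, 4, 5 or 7 trials.

Onsets are expressed in raw scan time: the first instruction starts when
the dummy frames end, and everything must fit inside the run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from execsim.core import (
    ATTENTION_TASK_CONDITIONS,
    COND_DIVIDED,
    COND_INSTRUCTION,
    COND_REST,
    DISTRACTED_CONDITIONS,
    NBACK_LEVELS,
    AcquisitionSpec,
    as_rng,
    validate_events,
)

SENTENCE_SECONDS = 2.5
RESPONSE_WINDOW_SECONDS = 2.5
SENTENCES_PER_BLOCK = 12
VOWEL_SECONDS = 0.5
RETENTION_SECONDS = 2.5
VOWELS_PER_BLOCK = 32
RUN_START_INSTRUCTION_SECONDS = 6.0
BLOCK_GAP_SECONDS = 2.5
MODALITY_RUN_LENGTHS = (3, 4, 5, 7)
VOWELS = ("a", "e", "u", "y")

_ATT_TRIAL_SECONDS = SENTENCE_SECONDS + RESPONSE_WINDOW_SECONDS
_NBACK_TRIAL_SECONDS = VOWEL_SECONDS + RETENTION_SECONDS
REST_BLOCK_SECONDS = SENTENCES_PER_BLOCK * _ATT_TRIAL_SECONDS


def _condition_modality(condition: str) -> str:
    if condition == "attend_auditory":
        return "auditory"
    if condition == "attend_visual":
        return "visual"
    if condition in DISTRACTED_CONDITIONS or condition == COND_DIVIDED:
        return "both"
    return "none"


def _finish(rows, acq: AcquisitionSpec, end_time: float) -> pd.DataFrame:
    if end_time > acq.run_seconds + 1e-9:
        raise ValueError(
            f"schedule overflows the run: ends at {end_time:.1f} s but the run "
            f"is only {acq.run_seconds:.1f} s long"
        )
    events = pd.DataFrame(rows)
    validate_events(events, run_seconds=acq.run_seconds)
    return events


def build_attention_schedule(
    run_index: int, acq: AcquisitionSpec = None, rng_seed=0
) -> pd.DataFrame:
    """One attention run: randomized block order, fixed block composition."""
    if run_index not in (1, 2, 3):
        raise ValueError("attention run_index must be 1, 2 or 3")
    if acq is None:
        acq = AcquisitionSpec.attention()
    rng = as_rng(rng_seed)

    blocks = [COND_REST] + list(ATTENTION_TASK_CONDITIONS) + [COND_DIVIDED]
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    rows = []
    t = acq.dummy_seconds
    rows.append(
        dict(
            onset=t,
            duration=RUN_START_INSTRUCTION_SECONDS,
            task="instruction",
            condition=COND_INSTRUCTION,
            modality="none",
            switch="n/a",
            congruent=None,
            block="instr",
            correct=None,
        )
    )
    t += RUN_START_INSTRUCTION_SECONDS

    for b, condition in enumerate(blocks):
        block_id = f"att{run_index}_b{b}_{condition}"
        if condition == COND_REST:
            rows.append(
                dict(
                    onset=t,
                    duration=REST_BLOCK_SECONDS,
                    task="attention",
                    condition=COND_REST,
                    modality="none",
                    switch="n/a",
                    congruent=None,
                    block=block_id,
                    correct=None,
                )
            )
            t += REST_BLOCK_SECONDS
        else:
            for _ in range(SENTENCES_PER_BLOCK):
                rows.append(
                    dict(
                        onset=t,
                        duration=SENTENCE_SECONDS,
                        task="attention",
                        condition=condition,
                        modality=_condition_modality(condition),
                        switch="n/a",
                        congruent=bool(rng.random() < 0.5),
                        block=block_id,
                        correct=None,
                    )
                )
                t += _ATT_TRIAL_SECONDS
        if b < len(blocks) - 1:
            rows.append(
                dict(
                    onset=t,
                    duration=BLOCK_GAP_SECONDS,
                    task="instruction",
                    condition=COND_INSTRUCTION,
                    modality="none",
                    switch="n/a",
                    congruent=None,
                    block="instr",
                    correct=None,
                )
            )
            t += BLOCK_GAP_SECONDS

    return _finish(rows, acq, t)


def _modality_sequence(n_trials: int, rng) -> np.ndarray:
    """Visual/auditory labels with run lengths drawn from {3, 4, 5, 7}."""
    labels = []
    current = "visual" if rng.random() < 0.5 else "auditory"
    while len(labels) < n_trials:
        run_len = int(rng.choice(MODALITY_RUN_LENGTHS))
        labels.extend([current] * run_len)
        current = "auditory" if current == "visual" else "visual"
    return np.array(labels[:n_trials])


def _switch_flags(modalities: np.ndarray) -> np.ndarray:
    """post_switch right after a change, pre_switch right before one."""
    n = len(modalities)
    flags = np.array(["nonswitch"] * n, dtype=object)
    change = modalities[1:] != modalities[:-1]
    flags[1:][change] = "post_switch"
    flags[:-1][change] = "pre_switch"
    return flags


def _vowel_sequence(n: int, level: int, rng) -> np.ndarray:
    """Vowel stream; for 2-back, guarantees at least one n-back match."""
    for _ in range(200):
        vowels = rng.choice(VOWELS, size=n)
        if level < 2 or np.any(vowels[2:] == vowels[:-2]):
            return vowels
    j = int(rng.integers(2, n))
    vowels[j] = vowels[j - 2]
    return vowels


def build_nback_schedule(
    run_index: int, acq: AcquisitionSpec = None, rng_seed=0
) -> pd.DataFrame:
    """One n-back run: three 32-trial blocks (0-, 1-, 2-back), random order."""
    if run_index not in (1, 2):
        raise ValueError("n-back run_index must be 1 or 2")
    if acq is None:
        acq = AcquisitionSpec.nback()
    rng = as_rng(rng_seed)

    levels = [NBACK_LEVELS[i] for i in rng.permutation(3)]
    rows = []
    t = acq.dummy_seconds
    rows.append(
        dict(
            onset=t,
            duration=RUN_START_INSTRUCTION_SECONDS,
            task="instruction",
            condition=COND_INSTRUCTION,
            modality="none",
            switch="n/a",
            congruent=None,
            block="instr",
            correct=None,
        )
    )
    t += RUN_START_INSTRUCTION_SECONDS

    for b, level in enumerate(levels):
        block_id = f"nb{run_index}_b{b}_{level}"
        modalities = _modality_sequence(VOWELS_PER_BLOCK, rng)
        flags = _switch_flags(modalities)
        vowels = _vowel_sequence(VOWELS_PER_BLOCK, int(level[0]), rng)
        for i in range(VOWELS_PER_BLOCK):
            rows.append(
                dict(
                    onset=t,
                    duration=VOWEL_SECONDS,
                    task="nback",
                    condition=level,
                    modality=modalities[i],
                    switch=flags[i],
                    congruent=None,
                    block=block_id,
                    correct=None,
                    stimulus=vowels[i],
                )
            )
            t += _NBACK_TRIAL_SECONDS
        # the retention period of the last trial still belongs to the block
        if b < len(levels) - 1:
            rows.append(
                dict(
                    onset=t,
                    duration=BLOCK_GAP_SECONDS,
                    task="instruction",
                    condition=COND_INSTRUCTION,
                    modality="none",
                    switch="n/a",
                    congruent=None,
                    block="instr",
                    correct=None,
                    stimulus=None,
                )
            )
            t += BLOCK_GAP_SECONDS

    return _finish(rows, acq, t)
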