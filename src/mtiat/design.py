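"""Experimental design of the seven-block race-IAT.

The task presents face stimuli (White / Black young male identities) and
valenced Italian words (positive / negative) over seven experimental blocks.
Blocks 3-4 pair White with positive and Black with negative on a shared
response (stereotype-congruent); blocks 6-7 reverse the pairing
(stereotype-incongruent).  The mouse variant prepends 40 colour-categorisation
practice trials.  Responses are selected in boxes at the top-left / top-right
of a 1024 x 768 screen, starting from a button at the bottom centre, and the
side holding the correct response alternates pseudo-randomly across trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: per-block trial counts of the experimental blocks 1..7
EXPERIMENTAL_BLOCK_TRIALS = (20, 20, 40, 40, 20, 40, 40)

CONGRUENT_BLOCKS = (3, 4)
INCONGRUENT_BLOCKS = (6, 7)
CRITICAL_BLOCKS = (3, 4, 6, 7)

#: block number used for mouse-task practice trials
PRACTICE_BLOCK = 0

# four attribute-by-race cells of the critical blocks
WHITE_POSITIVE = "White-Positive"
WHITE_NEGATIVE = "White-Negative"
BLACK_POSITIVE = "Black-Positive"
BLACK_NEGATIVE = "Black-Negative"
SINGLE_CATEGORY = "single-category"
PRACTICE = "practice"


class ConfigurationError(ValueError):
    """An invalid task design or screen layout."""


@dataclass(frozen=True)
class DesignConfig:
    """Screen geometry, sampling rate and block structure of the task.

    Coordinates are screen pixels with the y axis increasing downward, as
    recorded by the experiment software.  ``sample_interval`` is the cursor
    sampling period in ms (10 ms = 100 Hz).
    """

    screen_w: float = 1024.0
    screen_h: float = 768.0
    start_pos: tuple[float, float] = (512.0, 728.0)
    left_box: tuple[float, float] = (64.0, 40.0)
    right_box: tuple[float, float] = (960.0, 40.0)
    box_radius: float = 30.0
    sample_interval: float = 10.0
    block_trials: tuple[int, ...] = EXPERIMENTAL_BLOCK_TRIALS
    practice_trials: int = 40

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ConfigurationError("sample_interval must be > 0")
        if tuple(self.block_trials) != EXPERIMENTAL_BLOCK_TRIALS:
            raise ConfigurationError(
                f"block trial counts must be {EXPERIMENTAL_BLOCK_TRIALS}, "
                f"got {tuple(self.block_trials)}"
            )
        if self.practice_trials < 0:
            raise ConfigurationError("practice_trials must be >= 0")
        sy = self.start_pos[1]
        if not (sy > self.left_box[1] and sy > self.right_box[1]):
            raise ConfigurationError("start position must lie below both response boxes")
        if self.box_radius <= 0:
            raise ConfigurationError("box_radius must be > 0")

    @property
    def n_experimental_trials(self) -> int:
        return int(sum(self.block_trials))


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Child generator for the stated counter scheme.

    Streams are spawned from ``SeedSequence([seed, *key])`` so that any
    (subject, stream, trial) cell can be regenerated in isolation.  Stream
    codes: 0 = subject parameters, 1 = keyboard session, 2 = mouse trial,
    3 = keyboard schedule, 4 = mouse schedule.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


def _block_stimuli(block: int, n: int) -> list[str]:
    if block in (1, 5):
        per = n // 2
        return ["white_face"] * per + ["black_face"] * (n - per)
    if block == 2:
        per = n // 2
        return ["positive_word"] * per + ["negative_word"] * (n - per)
    # critical blocks mix 10 of each of the four stimulus types per 40 trials
    per = n // 4
    rest = n - 3 * per
    return (
        ["white_face"] * per
        + ["black_face"] * per
        + ["positive_word"] * per
        + ["negative_word"] * rest
    )


def _condition(block: int, stimulus: str) -> str:
    """Attribute-by-race cell of a critical trial.

    In congruent blocks White faces and positive words share a response, so
    both index the White-Positive pairing; Black faces and negative words the
    Black-Negative one.  Incongruent blocks reverse the pairings.
    """
    if block == PRACTICE_BLOCK:
        return PRACTICE
    if block in CONGRUENT_BLOCKS:
        return WHITE_POSITIVE if stimulus in ("white_face", "positive_word") else BLACK_NEGATIVE
    if block in INCONGRUENT_BLOCKS:
        return WHITE_NEGATIVE if stimulus in ("white_face", "negative_word") else BLACK_POSITIVE
    return SINGLE_CATEGORY


def build_schedule(
    design: DesignConfig, seed: int, task: str = "keyboard", subject_index: int = 0
) -> pd.DataFrame:
    """Trial schedule for one session.

    Emits the seven experimental blocks (20/20/40/40/20/40/40 trials); for
    ``task='mouse'`` the colour-categorisation practice trials are prepended
    as block 0.  Within-block stimulus order and the side of the correct
    response are randomised by ``seed``.

    Returns a frame with columns ``block, trial, practice, stimulus,
    condition, congruency, correct_side``.
    """
    if task not in ("keyboard", "mouse"):
        raise ValueError(f"task must be 'keyboard' or 'mouse', got {task!r}")
    stream = 3 if task == "keyboard" else 4
    rng = _rng(seed, subject_index, stream)

    blocks: list[np.ndarray] = []
    trials: list[np.ndarray] = []
    practice: list[np.ndarray] = []
    stimuli: list[np.ndarray] = []
    if task == "mouse":
        npr = design.practice_trials
        blocks.append(np.full(npr, PRACTICE_BLOCK))
        trials.append(np.arange(npr))
        practice.append(np.ones(npr, bool))
        stimuli.append(np.full(npr, "circle", dtype=object))
    for block, n in zip(range(1, 8), design.block_trials):
        stims = np.array(_block_stimuli(block, n), dtype=object)
        blocks.append(np.full(n, block))
        trials.append(np.arange(n))
        practice.append(np.zeros(n, bool))
        stimuli.append(stims[rng.permutation(n)])
    frame = pd.DataFrame(
        {
            "block": np.concatenate(blocks),
            "trial": np.concatenate(trials),
            "practice": np.concatenate(practice),
            "stimulus": np.concatenate(stimuli),
        }
    )
    frame["condition"] = [
        _condition(b, s) for b, s in zip(frame["block"], frame["stimulus"])
    ]
    frame["congruency"] = np.select(
        [frame["block"].isin(CONGRUENT_BLOCKS), frame["block"].isin(INCONGRUENT_BLOCKS)],
        ["congruent", "incongruent"],
        default="none",
    )
    # response-alternative positions vary pseudo-randomly across trials
    frame["correct_side"] = np.where(rng.random(len(frame)) < 0.5, "left", "right")
    return frame
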