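"""Alternating Serial Reaction Time (ASRT) task engine.

In the ASRT task, stimuli appear in one of four positions. Trials strictly
alternate between *pattern* trials, which follow a fixed four-element
sequence cyclically, and *random* trials with uniformly drawn positions.
Because of the alternation, runs of three consecutive trials ("triplets")
differ in frequency: a triplet whose final position is the pattern-successor
of its first position ("high-frequency") occurs about five times as often
as any specific non-conforming ("low-frequency") triplet.

From per-trial triplet labels the engine computes the standard learning
indices, with signs oriented so that larger = more learning:

* **Triplet learning** — advantage for high- over low-frequency triplets
  (a mixed frequency + sequence measure).
* **Higher-order sequence learning** — advantage for pattern-ending over
  random-ending high-frequency triplets (pure sequence knowledge).
* **Statistical learning** — advantage for high- over low-frequency
  random-ending triplets (pure frequency knowledge).
* **General skill learning** — overall improvement from the first to the
  last epoch of the task, independent of triplet type.

plus average RT and accuracy. RT indices use correct trials only by default;
accuracy indices use all classifiable included trials. Trills (X–Y–X) and
repetitions (X–X–X) are excluded from the learning-index cells, as is
standard (they can never be high-frequency, and carry pre-existing response
tendencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatternSequence",
    "LearningIndices",
    "InsufficientTrialsError",
    "generate_stream",
    "classify_triplets",
    "compute_indices",
]

POSITIONS = (1, 2, 3, 4)

#: Default task structure: 85-trial blocks = 5 warmup + 10 cycles of the
#: 8-element alternating sequence; epochs of 5 blocks. Configurable
#: throughout — the exact counts are conventional, not prescriptive.
DEFAULT_BLOCK_LENGTH = 85
DEFAULT_N_WARMUP = 5
DEFAULT_EPOCH_BLOCKS = 5


class InsufficientTrialsError(ValueError):
    """A learning-index cell has no usable trials."""


@dataclass(frozen=True)
class PatternSequence:
    """The fixed four-element pattern, as a permutation of positions 1–4.

    Defines the pattern-successor map ``succ``: the pattern cycles through
    ``order``, so ``succ(order[i]) == order[(i + 1) % 4]``.
    """

    order: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if sorted(self.order) != list(POSITIONS):
            raise ValueError(
                f"pattern must be a permutation of {POSITIONS}, got {self.order}"
            )

    @property
    def succ(self) -> dict[int, int]:
        return {self.order[i]: self.order[(i + 1) % 4] for i in range(4)}

    def succ_array(self) -> np.ndarray:
        """Successor lookup indexed by position (index 0 unused)."""
        out = np.zeros(5, dtype=np.int64)
        for a, b in self.succ.items():
            out[a] = b
        return out


@dataclass
class LearningIndices:
    """The ASRT outcome metrics for one participant.

    RT indices are in milliseconds; ACC indices are proportions. All
    difference scores are signed so that positive values indicate learning.
    """

    rt_triplet: float
    rt_higher_order: float
    rt_statistical: float
    rt_average: float
    rt_general_skill: float
    acc_triplet: float
    acc_higher_order: float
    acc_statistical: float
    acc_average: float
    acc_general_skill: float
    n_trials_used: int = 0
    cell_counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in (
                "rt_triplet",
                "rt_higher_order",
                "rt_statistical",
                "rt_average",
                "rt_general_skill",
                "acc_triplet",
                "acc_higher_order",
                "acc_statistical",
                "acc_average",
                "acc_general_skill",
            )
        }


def generate_stream(
    pattern: PatternSequence,
    n_blocks: int,
    block_length: int = DEFAULT_BLOCK_LENGTH,
    n_warmup: int = DEFAULT_N_WARMUP,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate the position stream of an ASRT session.

    Each block consists of ``n_warmup`` warmup trials with uniformly random
    positions, followed by strictly alternating pattern/random trials
    (pattern first); the pattern restarts at its first element at every
    block. RT and accuracy columns are left unfilled — they are produced by
    the behavioural simulator in :mod:`sleepcog.cohort`.

    Returns a tidy frame with columns ``block`` (1-based), ``trial``
    (1-based within block), ``trial_type`` (pattern/random/warmup) and
    ``position``; plus empty ``rt_ms``/``correct``.
    """
    n_alt = block_length - n_warmup
    if n_alt <= 0 or n_alt % 2 != 0:
        raise ValueError(
            "block_length - n_warmup must be positive and even, got "
            f"{block_length} - {n_warmup} = {n_alt}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    order = np.asarray(pattern.order, dtype=np.int64)
    blocks, trials, types, positions = [], [], [], []
    for b in range(1, n_blocks + 1):
        pos = np.empty(block_length, dtype=np.int64)
        ttype = np.empty(block_length, dtype=object)
        pos[:n_warmup] = rng.integers(1, 5, size=n_warmup)
        ttype[:n_warmup] = "warmup"
        # alternating part: pattern at even offsets from the first alternating trial
        alt_idx = np.arange(n_alt)
        pat_slots = n_warmup + alt_idx[alt_idx % 2 == 0]
        rnd_slots = n_warmup + alt_idx[alt_idx % 2 == 1]
        pos[pat_slots] = order[np.arange(pat_slots.size) % 4]
        pos[rnd_slots] = rng.integers(1, 5, size=rnd_slots.size)
        ttype[pat_slots] = "pattern"
        ttype[rnd_slots] = "random"
        blocks.append(np.full(block_length, b))
        trials.append(np.arange(1, block_length + 1))
        types.append(ttype)
        positions.append(pos)

    return pd.DataFrame(
        {
            "block": np.concatenate(blocks),
            "trial": np.concatenate(trials),
            "trial_type": np.concatenate(types),
            "position": np.concatenate(positions),
            "rt_ms": np.nan,
            "correct": np.nan,
        }
    )


def classify_triplets(stream: pd.DataFrame, pattern: PatternSequence) -> pd.DataFrame:
    """Label each trial's triplet (trials n−2, n−1, n within a block).

    Adds, aligned to ``stream``:

    * ``frequency`` — "high" if ``position[n] == succ(position[n−2])``,
      "low" otherwise, "unclassified" when the trial is a warmup trial or
      lacks two non-warmup within-block predecessors;
    * ``ending_type`` — "pattern"/"random", the type of trial ``n``;
    * ``excluded`` / ``exclusion_reason`` — trills (X–Y–X), repetitions
      (X–X–X), warmup trials and block-start trials are flagged for
      exclusion from the learning-index cells.

    Correctness is not consulted here: error trials are dropped from RT
    cells (not ACC cells) by :func:`compute_indices`.
    """
    succ = pattern.succ_array()
    pos = stream["position"].to_numpy(dtype=np.int64)
    block = stream["block"].to_numpy()
    is_warmup = (stream["trial_type"] == "warmup").to_numpy()
    n = len(stream)

    frequency = np.full(n, "unclassified", dtype=object)
    excluded = np.zeros(n, dtype=bool)
    reason = np.full(n, "", dtype=object)

    same_block2 = np.zeros(n, dtype=bool)
    same_block2[2:] = block[2:] == block[:-2]
    # a trial is classifiable iff it and both predecessors are non-warmup
    # trials of the same block
    pred_ok = np.zeros(n, dtype=bool)
    pred_ok[2:] = same_block2[2:] & ~is_warmup[2:] & ~is_warmup[1:-1] & ~is_warmup[:-2]

    first = np.zeros(n, dtype=np.int64)
    mid = np.zeros(n, dtype=np.int64)
    first[2:] = pos[:-2]
    mid[2:] = pos[1:-1]

    high = pred_ok & (succ[first] == pos)
    frequency[pred_ok & high] = "high"
    frequency[pred_ok & ~high] = "low"

    excluded[is_warmup] = True
    reason[is_warmup] = "warmup"
    start = ~is_warmup & ~pred_ok
    excluded[start] = True
    reason[start] = "stream-start"

    rep = pred_ok & (first == mid) & (mid == pos)
    trill = pred_ok & (first == pos) & (mid != pos)
    excluded[trill] = True
    reason[trill] = "trill"
    excluded[rep] = True
    reason[rep] = "repetition"

    return pd.DataFrame(
        {
            "frequency": frequency,
            "ending_type": stream["trial_type"]
            .where(stream["trial_type"] != "warmup", "random")
            .to_numpy(),
            "excluded": excluded,
            "exclusion_reason": reason,
        },
        index=stream.index,
    )


def _cell_mean(values: np.ndarray, mask: np.ndarray, cell: str) -> float:
    if not mask.any():
        raise InsufficientTrialsError(f"no usable trials in cell '{cell}'")
    return float(values[mask].mean())


def compute_indices(
    stream: pd.DataFrame,
    labels: pd.DataFrame,
    epoch_size_blocks: int = DEFAULT_EPOCH_BLOCKS,
    rt_correct_only: bool = True,
    acc_skill_first_minus_last: bool = False,
    rt_min: float | None = None,
    rt_max: float | None = None,
) -> LearningIndices:
    """Compute the learning indices from a labelled trial stream.

    Parameters
    ----------
    epoch_size_blocks
        Blocks per epoch; general skill compares the first and last epoch.
    rt_correct_only
        Restrict RT cells to correct trials (standard practice; default).
    acc_skill_first_minus_last
        Flip the accuracy general-skill difference to first − last epoch.
        The default (last − first) makes positive = improvement, matching
        the sign convention of every other index.
    rt_min, rt_max
        Optional RT window (ms); trials outside it are dropped from RT
        cells. No trimming is applied by default.

    Raises
    ------
    InsufficientTrialsError
        If any required cell (e.g. random-ending high-frequency triplets)
        contains no usable trials. Empty cells never produce silent NaNs.
    """
    n_blocks = int(stream["block"].max())
    if n_blocks < 2 * epoch_size_blocks:
        raise InsufficientTrialsError(
            f"need at least 2 epochs ({2 * epoch_size_blocks} blocks), "
            f"got {n_blocks}"
        )

    rt = stream["rt_ms"].to_numpy(dtype=float)
    correct = stream["correct"].to_numpy(dtype=float)
    block = stream["block"].to_numpy()
    freq = labels["frequency"].to_numpy()
    ending = labels["ending_type"].to_numpy()
    excluded = labels["excluded"].to_numpy()

    included = ~excluded & ((freq == "high") | (freq == "low"))
    if not included.any():
        raise InsufficientTrialsError("no classifiable included trials")

    rt_ok = included & np.isfinite(rt)
    if rt_correct_only:
        rt_ok &= correct == 1
    if rt_min is not None:
        rt_ok &= rt >= rt_min
    if rt_max is not None:
        rt_ok &= rt <= rt_max

    high = freq == "high"
    low = freq == "low"
    pat = ending == "pattern"
    rnd = ending == "random"

    cells_rt = {
        "high": rt_ok & high,
        "low": rt_ok & low,
        "pattern-high": rt_ok & high & pat,
        "random-high": rt_ok & high & rnd,
        "random-low": rt_ok & low & rnd,
    }
    cells_acc = {
        "high": included & high,
        "low": included & low,
        "pattern-high": included & high & pat,
        "random-high": included & high & rnd,
        "random-low": included & low & rnd,
    }

    m = {k: _cell_mean(rt, v, f"rt:{k}") for k, v in cells_rt.items()}
    a = {k: _cell_mean(correct, v, f"acc:{k}") for k, v in cells_acc.items()}

    first_epoch = block <= epoch_size_blocks
    last_epoch = block > n_blocks - epoch_size_blocks
    rt_first = _cell_mean(rt, rt_ok & first_epoch, "rt:first-epoch")
    rt_last = _cell_mean(rt, rt_ok & last_epoch, "rt:last-epoch")
    acc_first = _cell_mean(correct, included & first_epoch, "acc:first-epoch")
    acc_last = _cell_mean(correct, included & last_epoch, "acc:last-epoch")

    acc_skill = acc_last - acc_first
    if acc_skill_first_minus_last:
        acc_skill = -acc_skill

    return LearningIndices(
        rt_triplet=m["low"] - m["high"],
        rt_higher_order=m["random-high"] - m["pattern-high"],
        rt_statistical=m["random-low"] - m["random-high"],
        rt_average=_cell_mean(rt, rt_ok, "rt:all"),
        rt_general_skill=rt_first - rt_last,
        acc_triplet=a["high"] - a["low"],
        acc_higher_order=a["pattern-high"] - a["random-high"],
        acc_statistical=a["random-high"] - a["random-low"],
        acc_average=_cell_mean(correct, included, "acc:all"),
        acc_general_skill=acc_skill,
        n_trials_used=int(included.sum()),
        cell_counts={k: int(v.sum()) for k, v in cells_acc.items()},
    )


def indices_table(
    streams: dict[object, pd.DataFrame],
    pattern: PatternSequence | dict[object, PatternSequence],
    **kwargs,
) -> pd.DataFrame:
    """Compute indices for many participants; one row per participant."""
    rows = []
    for pid, stream in streams.items():
        pat = pattern[pid] if isinstance(pattern, dict) else pattern
        labels = classify_triplets(stream, pat)
        idx = compute_indices(stream, labels, **kwargs)
        rows.append({"participant_id": pid, **idx.as_dict()})
    return pd.DataFrame(rows)
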