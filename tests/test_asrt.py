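"""ASRT stream generation, triplet classification and learning indices."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepcog.asrt import (
    InsufficientTrialsError,
    PatternSequence,
    classify_triplets,
    compute_indices,
    generate_stream,
)
from sleepcog.cohort import ASRTEffects, generate_asrt_participant

PATTERN = PatternSequence((2, 1, 3, 4))


def brute_force_triplet_table(pattern: PatternSequence) -> dict:
    """Independent oracle: explicit dictionary of all 64 triplets."""
    succ = {pattern.order[i]: pattern.order[(i + 1) % 4] for i in range(4)}
    return {
        (a, b, c): "high" if succ[a] == c else "low"
        for a, b, c in itertools.product((1, 2, 3, 4), repeat=3)
    }


class TestPatternSequence:
    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError):
            PatternSequence((1, 1, 3, 4))

    def test_succ_is_bijection(self):
        succ = PATTERN.succ
        assert sorted(succ) == [1, 2, 3, 4]
        assert sorted(succ.values()) == [1, 2, 3, 4]
        assert succ == {2: 1, 1: 3, 3: 4, 4: 2}


class TestGenerateStream:
    def test_direct_construction_small_block(self):
        """1 block of 13 trials with 5 warmup: 8 alternating trials, pattern
        positions 2,1,3,4 at the pattern slots."""
        s = generate_stream(PATTERN, n_blocks=1, block_length=13, n_warmup=5, seed=0)
        assert len(s) == 13
        assert list(s["trial_type"][:5]) == ["warmup"] * 5
        alt = s.iloc[5:]
        assert list(alt["trial_type"]) == ["pattern", "random"] * 4
        assert list(alt.loc[alt["trial_type"] == "pattern", "position"]) == [2, 1, 3, 4]

    def test_odd_alternating_length_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_stream(PATTERN, n_blocks=1, block_length=12, n_warmup=5)

    def test_seed_changes_random_not_pattern_slots(self):
        a = generate_stream(PATTERN, n_blocks=2, seed=1)
        b = generate_stream(PATTERN, n_blocks=2, seed=2)
        pat = a["trial_type"] == "pattern"
        assert (a.loc[pat, "position"] == b.loc[pat, "position"]).all()
        rnd = a["trial_type"] == "random"
        assert (a.loc[rnd, "position"] != b.loc[rnd, "position"]).any()

    def test_deterministic_for_fixed_seed(self):
        a = generate_stream(PATTERN, n_blocks=3, seed=7)
        b = generate_stream(PATTERN, n_blocks=3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_pattern_cycles_across_alternating_slots(self):
        s = generate_stream(PATTERN, n_blocks=2, seed=0)
        for _, blk in s.groupby("block"):
            pat_pos = blk.loc[blk["trial_type"] == "pattern", "position"].to_numpy()
            expected = np.tile(PATTERN.order, len(pat_pos) // 4 + 1)[: len(pat_pos)]
            assert (pat_pos == expected).all()


class TestClassifyTriplets:
    def test_rule_application_high(self):
        # positions (2, 4, 1) with succ(2)=1 -> high
        s = pd.DataFrame(
            {
                "block": 1,
                "trial": [1, 2, 3],
                "trial_type": ["random", "random", "random"],
                "position": [2, 4, 1],
                "rt_ms": np.nan,
                "correct": np.nan,
            }
        )
        lab = classify_triplets(s, PATTERN)
        assert lab["frequency"].iloc[2] == "high"
        assert not lab["excluded"].iloc[2]

    def test_trill_excluded(self):
        s = pd.DataFrame(
            {
                "block": 1,
                "trial": [1, 2, 3],
                "trial_type": ["random"] * 3,
                "position": [3, 1, 3],
                "rt_ms": np.nan,
                "correct": np.nan,
            }
        )
        lab = classify_triplets(s, PATTERN)
        assert lab["excluded"].iloc[2]
        assert lab["exclusion_reason"].iloc[2] == "trill"

    def test_exhaustive_64_triplets_16_high_48_low(self):
        table = brute_force_triplet_table(PATTERN)
        counts = pd.Series(table).value_counts()
        assert counts["high"] == 16 and counts["low"] == 48
        # and the engine agrees on each of the 64
        for (a, b, c), expected in table.items():
            s = pd.DataFrame(
                {
                    "block": 1,
                    "trial": [1, 2, 3],
                    "trial_type": ["random"] * 3,
                    "position": [a, b, c],
                    "rt_ms": np.nan,
                    "correct": np.nan,
                }
            )
            assert classify_triplets(s, PATTERN)["frequency"].iloc[2] == expected

    def test_first_two_classifiable_trials_unclassified(self):
        s = generate_stream(PATTERN, n_blocks=1, seed=0)
        lab = classify_triplets(s, PATTERN)
        non_warm = lab[s["trial_type"] != "warmup"]
        assert list(non_warm["frequency"].iloc[:2]) == ["unclassified"] * 2
        assert list(non_warm["exclusion_reason"].iloc[:2]) == ["stream-start"] * 2
        assert (non_warm["frequency"].iloc[2:] != "unclassified").all()

    def test_degenerate_short_block_all_unclassified(self):
        s = generate_stream(PATTERN, n_blocks=1, block_length=7, n_warmup=5, seed=0)
        lab = classify_triplets(s, PATTERN)
        assert (lab["frequency"] == "unclassified").all()

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        order=st.permutations([1, 2, 3, 4]),
    )
    def test_agrees_with_brute_force_on_random_streams(self, seed, order):
        pattern = PatternSequence(tuple(order))
        s = generate_stream(pattern, n_blocks=2, block_length=21, n_warmup=3, seed=seed)
        lab = classify_triplets(s, pattern)
        table = brute_force_triplet_table(pattern)
        pos = s["position"].to_numpy()
        for i in range(len(s)):
            if lab["frequency"].iloc[i] == "unclassified":
                continue
            assert lab["frequency"].iloc[i] == table[(pos[i - 2], pos[i - 1], pos[i])]

    def test_pattern_trials_always_high(self):
        s = generate_stream(PATTERN, n_blocks=3, seed=4)
        lab = classify_triplets(s, PATTERN)
        pat_classified = (s["trial_type"] == "pattern") & (
            lab["frequency"] != "unclassified"
        )
        assert (lab.loc[pat_classified, "frequency"] == "high").all()


def _constant_stream(n_blocks=10):
    s = generate_stream(PATTERN, n_blocks=n_blocks, seed=0)
    s["rt_ms"] = 400.0
    s["correct"] = 1
    return s


class TestComputeIndices:
    def test_constant_rts_give_zero_indices(self):
        s = _constant_stream()
        idx = compute_indices(s, classify_triplets(s, PATTERN))
        d = idx.as_dict()
        assert d["acc_average"] == 1.0
        assert d["rt_average"] == 400.0
        for key in (
            "rt_triplet",
            "rt_higher_order",
            "rt_statistical",
            "rt_general_skill",
            "acc_triplet",
            "acc_higher_order",
            "acc_statistical",
            "acc_general_skill",
        ):
            assert d[key] == 0.0, key

    def test_requires_two_epochs(self):
        s = _constant_stream(n_blocks=4)
        with pytest.raises(InsufficientTrialsError, match="epoch"):
            compute_indices(s, classify_triplets(s, PATTERN), epoch_size_blocks=5)

    def test_empty_cell_raises_not_nan(self):
        s = _constant_stream()
        lab = classify_triplets(s, PATTERN)
        # forcing every random-ending high triplet out of the RT pool
        mask = (lab["frequency"] == "high") & (lab["ending_type"] == "random")
        s.loc[mask.to_numpy(), "correct"] = 0
        with pytest.raises(InsufficientTrialsError, match="random-high"):
            compute_indices(s, lab)

    def test_rt_uses_correct_trials_only(self):
        s = _constant_stream()
        lab = classify_triplets(s, PATTERN)
        wrong = (lab["frequency"] == "low") & ~lab["excluded"]
        first_low = int(np.flatnonzero(wrong.to_numpy())[0])
        s.loc[first_low, "rt_ms"] = 4000.0
        s.loc[first_low, "correct"] = 0
        idx = compute_indices(s, classify_triplets(s, PATTERN))
        assert idx.rt_triplet == 0.0  # the error trial's RT is ignored
        # but it still counts against the low cell's accuracy
        assert idx.acc_triplet > 0.0
        assert idx.acc_average < 1.0

    def test_recovers_injected_effects(self):
        """Simulated learners: statistical learning recovers the
        high-frequency RT advantage, higher-order learning recovers the
        pattern advantage, triplet learning is their weighted composite."""
        effects = ASRTEffects(
            triplet_rt=25.0, pattern_rt=12.0, skill_rt=0.0,
            triplet_acc=0.04, pattern_acc=0.0, skill_acc=0.0,
        )
        per = []
        for seed in range(40):
            s = generate_asrt_participant(
                effects=effects, n_blocks=130, pattern=PATTERN, seed=seed
            )
            idx = compute_indices(s, classify_triplets(s, PATTERN))
            per.append(idx.as_dict())
        mean = pd.DataFrame(per).mean()
        assert abs(mean["rt_statistical"] - 25.0) <= 2.5
        assert abs(mean["rt_higher_order"] - 12.0) <= 1.2
        # pattern trials are ~4/5 of the high pool, so triplet learning is
        # statistical + 0.8 * higher-order
        assert abs(mean["rt_triplet"] - (25.0 + 0.8 * 12.0)) <= 3.0
        assert abs(mean["acc_statistical"] - 0.04) <= 0.008

    def test_sign_convention_learner_beats_nonlearner(self):
        learner = generate_asrt_participant(n_blocks=20, pattern=PATTERN, seed=0)
        nonlearner = generate_asrt_participant(
            effects=ASRTEffects.none(), n_blocks=20, pattern=PATTERN, seed=0
        )
        i_l = compute_indices(learner, classify_triplets(learner, PATTERN))
        i_n = compute_indices(nonlearner, classify_triplets(nonlearner, PATTERN))
        for key in ("rt_triplet", "rt_statistical", "rt_higher_order",
                    "rt_general_skill", "acc_triplet", "acc_statistical"):
            assert getattr(i_l, key) > getattr(i_n, key), key

    def test_shuffling_within_blocks_destroys_sequence_learning(self):
        rng = np.random.default_rng(11)
        vals = []
        for seed in range(12):
            s = generate_asrt_participant(n_blocks=25, pattern=PATTERN, seed=seed)
            # permute the observed data within each block; slot labels
            # (trial_type) stay put, as they would for a blinded re-analysis
            parts = []
            for _, blk in s.groupby("block"):
                blk = blk.copy()
                perm = rng.permutation(len(blk))
                blk[["position", "rt_ms", "correct"]] = blk[
                    ["position", "rt_ms", "correct"]
                ].to_numpy()[perm]
                parts.append(blk)
            shuffled = pd.concat(parts, ignore_index=True)
            idx = compute_indices(shuffled, classify_triplets(shuffled, PATTERN))
            vals.append([idx.rt_statistical, idx.rt_higher_order])
        mean = np.mean(vals, axis=0)
        assert abs(mean[0]) < 3.0  # statistical learning gone
        assert abs(mean[1]) < 3.0  # higher-order learning gone

    def test_acc_general_skill_orientation_flag(self):
        s = generate_asrt_participant(n_blocks=20, pattern=PATTERN, seed=3)
        lab = classify_triplets(s, PATTERN)
        default = compute_indices(s, lab)
        flipped = compute_indices(s, lab, acc_skill_first_minus_last=True)
        assert flipped.acc_general_skill == pytest.approx(-default.acc_general_skill)
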