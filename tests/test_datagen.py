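import numpy as np
import pytest
from hypothesis import given, strategies as st

from handoverid.datagen import (
    FACTOR_NAMES,
    ConditionFactors,
    GeneratorConfig,
    ParticipantProfile,
    TrialRecord,
    filter_valid,
    generate_dataset,
    generate_design,
    generate_participants,
    generate_trajectory,
)
from handoverid.dtw import dtw_distance
from handoverid.errors import EmptyDataError, InvalidArgumentError


class TestConditionFactors:
    def test_full_factorial_is_32_distinct_cells(self):
        cells = ConditionFactors.full_factorial()
        assert len(cells) == 32
        assert len({c.index for c in cells}) == 32

    def test_index_roundtrip(self):
        for i in range(32):
            assert ConditionFactors.from_index(i).index == i

    def test_nonbinary_level_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ConditionFactors(2, 0, 0, 0, 0)


class TestDesign:
    @pytest.mark.parametrize("replicates", [1, 3])
    def test_each_condition_appears_replicates_times(self, replicates):
        trials = generate_design(replicates, seed=5)
        assert len(trials) == 32 * replicates
        counts = {}
        for t in trials:
            counts[t.condition.index] = counts.get(t.condition.index, 0) + 1
        assert counts == {i: replicates for i in range(32)}

    def test_zero_replicates_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_design(0, seed=1)

    def test_seeded_order_is_deterministic_and_randomized(self):
        a = generate_design(3, seed=9)
        b = generate_design(3, seed=9)
        assert [t.condition.index for t in a] == [t.condition.index for t in b]
        # not in enumeration order
        assert [t.condition.index for t in a] != sorted(
            t.condition.index for t in a
        )

    def test_factor_balance(self):
        trials = generate_design(3, seed=2)
        for name in FACTOR_NAMES:
            levels = [getattr(t.condition, name) for t in trials]
            assert sum(levels) == len(trials) // 2

    def test_giver_assignment_follows_side_factor(self):
        for t in generate_design(1, seed=3, participants=("A", "B")):
            expected = "A" if t.condition.giver_side == 0 else "B"
            assert t.giver_id == expected
            assert t.receiver_id != t.giver_id


class TestParticipants:
    def test_profiles_satisfy_invariants(self):
        for p in generate_participants(8, seed=1):
            assert 0 <= p.openness <= 100 and 0 <= p.neuroticism <= 100
            assert p.familiarity in range(1, 6)
            assert p.age >= 0 and p.body_size > 0 and p.weight > 0

    def test_same_seed_reproduces(self):
        assert generate_participants(8, seed=4) == generate_participants(8, seed=4)

    @pytest.mark.parametrize("n", [0, 1, 3])
    def test_odd_or_small_counts_rejected(self, n):
        with pytest.raises(InvalidArgumentError):
            generate_participants(n, seed=0)

    def test_pair_members_share_familiarity(self):
        ps = generate_participants(10, seed=7)
        for i in range(0, 10, 2):
            assert ps[i].familiarity == ps[i + 1].familiarity

    def test_big_five_bounds_enforced_on_construction(self):
        good = generate_participants(2, seed=0)[0]
        with pytest.raises(InvalidArgumentError):
            ParticipantProfile(**{**good.as_dict(), "openness": 101.0})


def _trial(cond_index=0, idx=0):
    cond = ConditionFactors.from_index(cond_index)
    giver, receiver = ("P1", "P2") if cond.giver_side == 0 else ("P2", "P1")
    return TrialRecord(
        trial_index=idx, pair_id="pair1", condition=cond,
        giver_id=giver, receiver_id=receiver, replicate=1,
    )


class TestTrajectoryGenerator:
    zero_cfg = GeneratorConfig(
        sigma_identity=0, sigma_condition=0, sigma_trait=0, sigma_noise=0,
        warp_jitter=0, t_range=(50, 50), seed=0,
    )

    def test_zero_effect_limit_gives_identical_trajectories(self):
        prof = generate_participants(2, seed=1)
        # same role, same giver side, all effect scales zero
        t1, t2 = _trial(0, 0), _trial(1, 1)  # differ in platform only
        a = generate_trajectory(t1, prof[0], "giver", self.zero_cfg)
        b = generate_trajectory(t2, prof[1], "giver", self.zero_cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_identity_signature_fixed_across_trials(self):
        cfg = GeneratorConfig(
            sigma_identity=0.5, sigma_condition=0, sigma_trait=0,
            sigma_noise=0, warp_jitter=0, t_range=(60, 60), seed=2,
        )
        prof = generate_participants(2, seed=1)[0]
        a = generate_trajectory(_trial(0, 0), prof, "giver", cfg)
        b = generate_trajectory(_trial(0, 5), prof, "giver", cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_giver_side_inverts_the_time_course(self):
        prof = generate_participants(2, seed=1)
        left = generate_trajectory(_trial(0, 0), prof[0], "giver", self.zero_cfg)
        right = generate_trajectory(_trial(16, 1), prof[1], "giver", self.zero_cfg)
        np.testing.assert_allclose(left.values, right.values[::-1])

    def test_channel_count_and_finiteness(self):
        cfg = GeneratorConfig(seed=3)
        prof = generate_participants(2, seed=1)[0]
        traj = generate_trajectory(_trial(3, 0), prof, "receiver", cfg)
        assert traj.values.shape[1] == 20
        assert np.all(np.isfinite(traj.values))

    def test_within_participant_distances_smaller_than_between(self):
        cfg = GeneratorConfig(
            n_pairs=2, replicates=1, sigma_identity=0.8, sigma_condition=0.0,
            sigma_trait=0.0, sigma_noise=0.05, warp_jitter=0.05,
            t_range=(30, 40), seed=6,
        )
        ds = generate_dataset(cfg)
        trajs = ds.trajectories[:40]
        within, between = [], []
        for i in range(len(trajs)):
            for j in range(i + 1, len(trajs)):
                d = dtw_distance(trajs[i], trajs[j])
                (within if trajs[i].owner_id == trajs[j].owner_id else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_effect_scale_ordering_is_realized(self):
        """Switching each effect on alone, at the default scale ordering
        sigma_identity > sigma_condition > sigma_trait, induces DTW
        displacements with the same ordering."""
        base = dict(sigma_identity=0, sigma_condition=0, sigma_trait=0,
                    sigma_noise=0, warp_jitter=0, t_range=(40, 40))
        d_id, d_cond, d_trait = [], [], []
        for seed in range(3):
            profs = generate_participants(2, seed=seed)
            c_id = GeneratorConfig(**{**base, "sigma_identity": 0.6}, seed=seed)
            d_id.append(dtw_distance(
                generate_trajectory(_trial(0, 0), profs[0], "giver", c_id),
                generate_trajectory(_trial(0, 0), profs[1], "giver", c_id),
            ))
            c_cond = GeneratorConfig(**{**base, "sigma_condition": 0.25}, seed=seed)
            d_cond.append(dtw_distance(
                generate_trajectory(_trial(0, 0), profs[0], "giver", c_cond),
                generate_trajectory(_trial(1, 1), profs[0], "giver", c_cond),
            ))
            c_tr = GeneratorConfig(**{**base, "sigma_trait": 0.05}, seed=seed)
            d_trait.append(dtw_distance(
                generate_trajectory(_trial(0, 0), profs[0], "giver", c_tr),
                generate_trajectory(_trial(0, 0), profs[1], "giver", c_tr),
            ))
        assert np.mean(d_id) > np.mean(d_cond) > np.mean(d_trait) > 0

    def test_determinism_under_repeated_seed(self):
        cfg = GeneratorConfig(n_pairs=1, replicates=1, t_range=(20, 30), seed=12)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        for x, y in zip(a.trajectories, b.trajectories):
            np.testing.assert_array_equal(x.values, y.values)


class TestFilterValid:
    def _trials_for(self, n_participants, failing):
        trials = []
        idx = 0
        for p in range(0, n_participants, 2):
            a, b = f"P{p + 1}", f"P{p + 2}"
            fail = a in failing or b in failing
            for cond_index in range(4):
                cond = ConditionFactors.from_index(cond_index)
                giver, receiver = (a, b) if cond.giver_side == 0 else (b, a)
                trials.append(TrialRecord(
                    trial_index=idx, pair_id=f"pair{p // 2 + 1}", condition=cond,
                    giver_id=giver, receiver_id=receiver, replicate=1,
                    valid=not fail,
                ))
                idx += 1
        return trials

    def test_two_fully_failing_participants_are_excluded(self):
        trials = self._trials_for(10, failing={"P9", "P10"})
        kept, _, log = filter_valid(trials, threshold=0.5)
        retained = {p for t in kept for p in t.participants()}
        assert len(retained) == 8
        assert log["excluded_participants"] == ["P10", "P9"]

    def test_no_failures_is_identity(self):
        trials = self._trials_for(4, failing=set())
        kept, _, _ = filter_valid(trials)
        assert kept == trials

    def test_everything_failing_raises(self):
        trials = self._trials_for(4, failing={"P1", "P2", "P3", "P4"})
        with pytest.raises(EmptyDataError):
            filter_valid(trials)


class TestDatasetAssembly:
    def test_study_scale_layout_retains_8_of_10(self):
        cfg = GeneratorConfig(
            n_pairs=4, replicates=1, t_range=(20, 25), seed=5
        ).study_scale()
        ds = generate_dataset(cfg)
        assert len(ds.profiles) == 8
        assert {p.identity for p in ds.profiles} == {f"P{i}" for i in range(1, 9)}
        assert ds.exclusion_log["excluded_participants"] == ["P10", "P9"]
        assert len(ds.trajectories) == 2 * len(ds.trials)

    def test_frame_aligns_with_trajectories(self, tiny_dataset, tiny_frame):
        assert len(tiny_frame) == len(tiny_dataset.trajectories)
        assert set(tiny_frame["role"]) == {"giver", "receiver"}
        for name in FACTOR_NAMES:
            assert set(tiny_frame[name]) <= {0, 1}

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_design_balance_under_any_seed(self, seed):
        trials = generate_design(1, seed=seed)
        assert len({t.condition.index for t in trials}) == 32
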