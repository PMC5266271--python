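"""Standardization, the matching metric, greedy quartets, arm allocation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import quartetri as q
from quartetri.design import covariate_frame


def units_from_matrix(x):
    cols = [f"c{j}" for j in range(x.shape[1])]
    return [
        q.UnitRecord(unit_id=i, covariates={c: float(v) for c, v in zip(cols, row)})
        for i, row in enumerate(x)
    ]


class TestStandardize:
    def test_constant_column_maps_to_zeros(self):
        df = pd.DataFrame({"a": [3.0, 3.0, 3.0], "b": [0.0, 1.0, 2.0]})
        std = q.standardize(df)
        assert np.all(std.values[:, 0] == 0.0)
        assert std.scales[0] == 0.0

    def test_two_point_column_sample_sd(self):
        # mean 1, sd sqrt(2) under the n-1 denominator
        std = q.standardize(pd.DataFrame({"a": [0.0, 2.0]}))
        np.testing.assert_allclose(std.values[:, 0], [-0.70710678, 0.70710678], atol=1e-8)

    def test_nonconstant_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        std = q.standardize(df)
        np.testing.assert_allclose(std.values.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(std.values.std(axis=0, ddof=1), 1, atol=1e-10)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=20),
        st.floats(0.1, 10),
        st.floats(-100, 100),
    )
    def test_location_scale_invariance(self, xs, a, c):
        # near-constant columns are legitimately mapped to zero; skip the
        # region where round-off decides constancy
        assume(np.std(xs) > 1e-6 * (1 + max(abs(v) for v in xs)))
        df1 = pd.DataFrame({"x": xs})
        df2 = pd.DataFrame({"x": [a * v + c for v in xs]})
        s1, s2 = q.standardize(df1), q.standardize(df2)
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-8)

    def test_missing_value_names_unit_and_covariate(self):
        df = pd.DataFrame({"age": [30.0, np.nan]}, index=["u1", "u2"])
        with pytest.raises(ValueError, match="age.*u2"):
            q.standardize(df)


class TestPairDistance:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(1)
        u, v = rng.normal(size=10), rng.normal(size=10)
        assert q.pair_distance(u, u) == 0.0
        assert q.pair_distance(u, v) == q.pair_distance(v, u)

    def test_single_coordinate_difference(self):
        u = np.zeros(10)
        v = np.zeros(10)
        v[3] = 1.0
        assert q.pair_distance(u, v) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_elementwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=10), rng.normal(size=10)
        brute = sum((a - b) ** 2 for a, b in zip(u, v)) ** 0.5
        assert q.pair_distance(u, v) == pytest.approx(brute, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            q.pair_distance(np.zeros(3), np.zeros(4))


class TestFormBlocks:
    def test_248_units_give_62_blocks(self):
        units = q.generate_baseline(q.BaselineConfig(n_units=248, seed=5))
        blocks = q.form_blocks(units, seed=6)
        assert len(blocks) == 62
        covered = [m for b in blocks for m in b.member_ids]
        assert sorted(covered) == list(range(248))  # a partition into quartets

    def test_four_units_one_block(self):
        units = units_from_matrix(np.random.default_rng(2).normal(size=(4, 3)))
        blocks = q.form_blocks(units, seed=0)
        assert len(blocks) == 1
        assert sorted(blocks[0].member_ids) == [0, 1, 2, 3]

    @pytest.mark.parametrize("neighbor", ["seed-unit", "centroid"])
    @pytest.mark.parametrize("seed", range(8))
    def test_two_well_separated_clusters_recovered(self, seed, neighbor):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(8, 3)) * 0.1
        x[4:] += 100.0  # two clusters, separation >> spread
        units = units_from_matrix(x)
        blocks = q.form_blocks(units, seed=seed, neighbor=neighbor)
        groups = {frozenset(b.member_ids) for b in blocks}
        assert groups == {frozenset({0, 1, 2, 3}), frozenset({4, 5, 6, 7})}

    def test_fewer_than_four_is_domain_error(self):
        units = units_from_matrix(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            q.form_blocks(units, seed=0)

    def test_leftover_units_excluded_with_warning(self, caplog):
        units = units_from_matrix(np.random.default_rng(3).normal(size=(10, 2)))
        with caplog.at_level("WARNING", logger="quartetri.design"):
            blocks = q.form_blocks(units, seed=0)
        assert len(blocks) == 2
        assert sum(len(b.member_ids) for b in blocks) == 8
        assert any("leftover" in r.message for r in caplog.records)

    def test_deterministic_given_seed(self):
        units = q.generate_baseline(q.BaselineConfig(n_units=48, seed=8))
        b1 = q.form_blocks(units, seed=99)
        b2 = q.form_blocks(units, seed=99)
        assert b1 == b2

    def test_matching_beats_random_partition(self):
        """Mean within-block distance under matching < under random quartets."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            units = q.generate_baseline(
                q.BaselineConfig(n_units=48, n_clusters=6, cluster_sep=3.0, seed=seed)
            )
            units = [
                q.UnitRecord(u.unit_id, {k: v for k, v in u.covariates.items() if not k.startswith("_")})
                for u in units
            ]
            std = q.standardize(covariate_frame(units))

            def mean_within(blocks):
                ds = []
                idx = {u.unit_id: i for i, u in enumerate(units)}
                for blk in blocks:
                    rows = [idx[m] for m in blk.member_ids]
                    for a in range(4):
                        for b in range(a + 1, 4):
                            ds.append(q.pair_distance(std.values[rows[a]], std.values[rows[b]]))
                return np.mean(ds)

            matched = q.form_blocks(units, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            perm = rng.permutation(48)
            random_blocks = [
                q.Block(b, tuple(int(i) for i in perm[4 * b : 4 * b + 4])) for b in range(12)
            ]
            if mean_within(matched) < mean_within(random_blocks):
                wins += 1
        assert wins >= int(0.95 * n_seeds)


class TestAssignArms:
    def test_each_arm_once_per_block(self):
        units = q.generate_baseline(q.BaselineConfig(n_units=16, seed=9))
        blocks = q.form_blocks(units, seed=1)
        arms = q.assign_arms(blocks, seed=2)
        for blk in blocks:
            assert sorted(arms[m].label for m in blk.member_ids) == sorted(
                a.label for a in q.ARMS
            )

    def test_full_design_counts(self):
        units = q.generate_baseline(q.BaselineConfig(n_units=248, seed=10))
        study = q.design_experiment(units, seed=11)
        arms = [u.arm for u in study.units]
        assert all(arms.count(a) == 62 for a in q.ARMS)
        for effect in q.MainEffect:
            ind = study.indicator_vector(effect)
            assert ind.sum() == 124
            for rows in study.member_rows():
                assert ind[rows].sum() == 2

    def test_allocation_is_uniform_over_members(self):
        """Over 10,000 reseeded assignments of one block, each arm lands on
        each member ~2,500 times (4-sigma binomial bounds)."""
        blk = [q.Block(1, (0, 1, 2, 3))]
        counts = np.zeros((4, 4), dtype=int)  # member x arm
        for seed in range(10_000):
            arms = q.assign_arms(blk, seed=seed)
            for m in range(4):
                counts[m, q.ARMS.index(arms[m])] += 1
        sd = np.sqrt(10_000 * 0.25 * 0.75)
        assert np.all(np.abs(counts - 2500) < 4 * sd)

    def test_design_deterministic_and_seed_sensitive(self):
        units = q.generate_baseline(q.BaselineConfig(n_units=24, seed=12))
        s1 = q.design_experiment(units, seed=5)
        s2 = q.design_experiment(units, seed=5)
        s3 = q.design_experiment(units, seed=6)
        assert [(u.unit_id, u.block_id, u.arm) for u in s1.units] == [
            (u.unit_id, u.block_id, u.arm) for u in s2.units
        ]
        assert [(u.unit_id, u.block_id, u.arm) for u in s1.units] != [
            (u.unit_id, u.block_id, u.arm) for u in s3.units
        ]
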