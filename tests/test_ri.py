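"""The within-block permutation null and randomization p-values."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import quartetri as q
from quartetri.estimators import block_fe_beta
from quartetri.ri import PATTERN_MATRIX, _pvalue


def beta_statistic(study, ind):
    """Full block-FE refit per permutation (the slow, general route)."""
    rows = study.member_rows()
    codes = np.empty(study.n, dtype=int)
    for b, r in enumerate(rows):
        codes[r] = b
    return block_fe_beta(study.outcome_vector("store1"), ind, codes, len(rows))


def dim_statistic(outcome):
    def stat(study, ind):
        return q.diff_in_means(study.outcome_vector(outcome), ind)

    return stat


class TestPatterns:
    def test_the_six_patterns(self):
        pats = q.block_patterns()
        assert len(pats) == 6
        assert all(p.count("T") == 2 and p.count("C") == 2 for p in pats)
        # matches brute-force enumeration of 4-choose-2 labelings
        brute = set()
        for treated in itertools.combinations(range(4), 2):
            brute.add(tuple("T" if i in treated else "C" for i in range(4)))
        assert set(pats) == brute

    def test_permute_assignment_treats_half(self, study_b5):
        rows = study_b5.member_rows()
        rng = np.random.default_rng(0)
        ind = q.permute_assignment(rows, rng, study_b5.n)
        assert ind.sum() == 2 * len(rows)
        for r in rows:
            assert ind[r].sum() == 2

    def test_seeded_draws_reproducible(self, study_b5):
        rows = study_b5.member_rows()
        a = q.permute_assignment(rows, np.random.default_rng(7), study_b5.n)
        b = q.permute_assignment(rows, np.random.default_rng(7), study_b5.n)
        np.testing.assert_array_equal(a, b)

    def test_patterns_drawn_uniformly(self):
        """One block, 60,000 draws: each pattern ~1/6 (chi-square)."""
        rows = np.array([[0, 1, 2, 3]])
        rng = np.random.default_rng(1)
        counts = np.zeros(6, dtype=int)
        lookup = {tuple(row): k for k, row in enumerate(PATTERN_MATRIX.astype(int).tolist())}
        for _ in range(60_000):
            ind = q.permute_assignment(rows, rng, 4)
            counts[lookup[tuple(ind.astype(int))]] += 1
        assert sps.chisquare(counts).pvalue > 1e-3


class TestPvalues:
    def test_raw_proportion_and_plus_one_conventions(self, study_b5):
        exact = q.ri_pvalue(
            study_b5, dim_statistic("sel1"), q.MainEffect.PSS, mode="exact"
        )
        plus = q.ri_pvalue(
            study_b5, dim_statistic("sel1"), q.MainEffect.PSS, mode="exact", plus_one=True
        )
        assert exact.n_permutations == 6**5
        assert exact.p_value == exact.n_extreme / 6**5
        assert plus.p_value == (exact.n_extreme + 1) / (6**5 + 1)

    def test_observed_above_all_permuted_gives_zero(self, study_b5):
        """No plus-one correction: a statistic larger than every sampled
        value reports p = 0."""

        observed = study_b5.indicator_vector(q.MainEffect.PSS)

        def is_observed(study, ind):
            return float(np.array_equal(ind, observed))

        res = q.ri_pvalue(
            study_b5, is_observed, q.MainEffect.PSS, M=200, seed=0, mode="sampled"
        )
        # chance of re-drawing the observed assignment is 6^-5 per draw
        assert res.observed_stat == 1.0
        assert res.p_value == 0.0

    def test_fast_path_matches_generic_refit_exactly(self, study_b5):
        generic = q.ri_pvalue(study_b5, beta_statistic, q.MainEffect.PSSH, mode="exact")
        fast = q.ri_pvalue_block_fe(study_b5, "store1", q.MainEffect.PSSH, mode="exact")
        assert fast.n_permutations == generic.n_permutations == 6**5
        assert fast.observed_stat == pytest.approx(generic.observed_stat, abs=1e-12)
        assert fast.p_value == generic.p_value

    def test_exact_invariant_to_block_and_member_relabeling(self, study_b5):
        base = q.ri_pvalue_block_fe(study_b5, "sel2", q.MainEffect.PSS, mode="exact")
        # reverse block order and rotate members within each block,
        # carrying outcomes along (pure relabeling)
        units = {u.unit_id: u for u in study_b5.units}
        new_blocks = [
            q.Block(b.block_id, b.member_ids[1:] + b.member_ids[:1])
            for b in reversed(study_b5.blocks)
        ]
        reordered = q.Study(
            units=[units[m] for b in new_blocks for m in b.member_ids],
            blocks=new_blocks,
        )
        reordered.validate()
        perm = q.ri_pvalue_block_fe(reordered, "sel2", q.MainEffect.PSS, mode="exact")
        assert perm.p_value == base.p_value
        assert perm.observed_stat == pytest.approx(base.observed_stat, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_one_sided_pvalues_cover(self, seed):
        """p(greater) + p(less) >= 1, with equality broken only by ties."""
        study = q.simulate_study(n_units=16, seed=300 + seed)
        g = q.ri_pvalue_block_fe(study, "gen1", q.MainEffect.PSS, mode="exact", sidedness="greater")
        l = q.ri_pvalue_block_fe(study, "gen1", q.MainEffect.PSS, mode="exact", sidedness="less")
        assert g.p_value + l.p_value >= 1.0
        assert g.p_value + l.p_value == pytest.approx(1 + g.n_ties / g.n_permutations, abs=1e-12)

    def test_monotone_in_treated_outcomes(self, study_b5):
        """Raising treated outcomes cannot lower the observed difference in
        means or raise the one-sided (greater) p-value."""
        ind = study_b5.indicator_vector(q.MainEffect.PSS)
        base = q.ri_pvalue(study_b5, dim_statistic("gen2"), q.MainEffect.PSS, mode="exact")
        boosted_units = []
        for u, i in zip(study_b5.units, ind):
            out = dict(u.outcomes)
            if i == 1:
                out["gen2"] = 1
            boosted_units.append(
                q.UnitRecord(u.unit_id, dict(u.covariates), u.block_id, u.arm, out,
                             u.know_pss, u.know_pssh)
            )
        boosted = q.Study(units=boosted_units, blocks=study_b5.blocks)
        res = q.ri_pvalue(boosted, dim_statistic("gen2"), q.MainEffect.PSS, mode="exact")
        assert res.observed_stat >= base.observed_stat
        assert res.p_value <= base.p_value

    def test_sampled_converges_to_exact(self, study_b5):
        exact = q.ri_pvalue_block_fe(study_b5, "store1", q.MainEffect.PSSH, mode="exact")
        p = exact.p_value
        for M in (100, 1_000, 10_000):
            samp = q.ri_pvalue_block_fe(
                study_b5, "store1", q.MainEffect.PSSH, M=M, seed=50, mode="sampled"
            )
            bound = 4 * np.sqrt(max(p * (1 - p), 1e-4) / M)
            assert abs(samp.p_value - p) <= bound

    def test_exact_mode_capacity_error(self, study_full):
        with pytest.raises(q.CapacityError, match="sampled"):
            q.ri_pvalue_block_fe(study_full, "sel1", q.MainEffect.PSS, mode="exact")

    def test_pvalue_helper_tie_handling(self):
        perm = np.array([0.1, 0.2, 0.2, 0.3])
        p, extreme, ties = _pvalue(perm, 0.2, "greater", plus_one=False)
        assert extreme == 3 and ties == 2 and p == 0.75
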