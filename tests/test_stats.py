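"""Exact Wilcoxon, two-stage FDR, Spearman and ddCt utilities."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import cytogravity as cg
from cytogravity.stats import UndefinedTestError


def wilcoxon_bruteforce(diffs):
    """Oracle: literal enumeration of all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product([0, 1], repeat=d.size):
        ws.append(ranks[np.array(signs, dtype=bool)].sum())
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    @pytest.mark.parametrize(
        "diffs,expected_p",
        [
            ([1, 2, 3], 0.25),  # 2/8: all-positive is one of two extreme tails
            (list(range(1, 9)), 2 / 256),  # exact floor for 8 distinct pairs
            ([1, -1], 1.0),  # perfectly symmetric
        ],
    )
    def test_enumerated_examples(self, diffs, expected_p):
        res = cg.wilcoxon_signed_rank_exact(diffs)
        assert res.p_two_sided == pytest.approx(expected_p, abs=1e-12)

    def test_all_zero_differences_undefined(self):
        with pytest.raises(UndefinedTestError):
            cg.wilcoxon_signed_rank_exact([0.0, 0.0])

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(7)
        for n in range(2, 11):
            for _ in range(5):
                d = np.round(rng.normal(0.3, 1.0, size=n), 1)  # rounding makes ties
                d = d[d != 0]
                if d.size == 0:
                    continue
                res = cg.wilcoxon_signed_rank_exact(d)
                w_oracle, p_oracle = wilcoxon_bruteforce(d)
                assert res.statistic == pytest.approx(w_oracle)
                assert res.p_two_sided == pytest.approx(p_oracle, abs=1e-12)
                assert res.method == "exact"

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.integers(-50, 50).filter(lambda v: v != 0),
                    min_size=3, max_size=12, unique_by=abs))
    def test_matches_scipy_exact_without_ties(self, diffs):
        res = cg.wilcoxon_signed_rank_exact(diffs)
        ref = sps.wilcoxon(diffs, alternative="two-sided", method="exact")
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.5, 1.0, size=60)
        res = cg.wilcoxon_signed_rank_exact(d)
        ref = sps.wilcoxon(d, alternative="two-sided", method="approx", correction=True)
        assert res.method == "normal"
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=0.05)


def bh_reference(p, q):
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, alpha=q, method="fdr_bh")[0]


class TestBKY:
    def test_all_ones_no_discoveries(self):
        res = cg.bky_two_stage_fdr([1.0, 1.0, 1.0], q=0.01)
        assert res.n_discoveries == 0

    def test_hand_executed_two_stage_example(self):
        # stage 1 at 0.05/1.05 rejects 2 of 3; m0 = 1; stage 2 at 0.15 keeps 2
        res = cg.bky_two_stage_fdr([0.001, 0.02, 0.8], q=0.05)
        assert res.discoveries.tolist() == [True, True, False]
        assert res.m0 == 1
        assert res.stage1_rejections == 2

    def test_stage1_all_rejected_short_circuits(self):
        res = cg.bky_two_stage_fdr([1e-5, 1e-6, 1e-4], q=0.05)
        assert res.n_discoveries == 3

    def test_dominates_plain_bh(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            m = rng.integers(5, 120)
            p = np.concatenate([
                rng.uniform(size=m // 2),
                rng.beta(0.2, 6.0, size=m - m // 2),  # enriched small p
            ])
            for q in (0.01, 0.05, 0.1):
                ours = cg.bky_two_stage_fdr(p, q).discoveries
                bh = bh_reference(p, q)
                assert (ours | ~bh).all(), "BKY must contain every BH discovery"

    def test_empirical_fdr_controlled(self):
        rng = np.random.default_rng(5)
        q = 0.05
        fdps = []
        for _ in range(400):
            null_p = rng.uniform(size=80)
            alt_p = 2 * sps.norm.sf(np.abs(rng.normal(3.0, 1.0, size=20)))
            p = np.concatenate([null_p, alt_p])
            res = cg.bky_two_stage_fdr(p, q)
            n_false = int(res.discoveries[:80].sum())
            n_total = res.n_discoveries
            fdps.append(n_false / n_total if n_total else 0.0)
        fdr = float(np.mean(fdps))
        se = float(np.std(fdps) / np.sqrt(len(fdps)))
        assert fdr <= q + 3 * se + 0.01

    @pytest.mark.parametrize("bad", [[-0.1], [1.2], [float("nan")]])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValueError):
            cg.bky_two_stage_fdr(bad, q=0.05)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.5, 3.0, 7.0, 11.0]
        rho, _ = cg.spearman_rho_p(x, x)
        assert rho == pytest.approx(1.0)
        rho_rev, _ = cg.spearman_rho_p(x, list(reversed(x)))
        assert rho_rev == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_oracle_n5(self):
        from itertools import permutations

        x = np.array([0.3, 1.2, -0.5, 2.2, 0.9])
        y = np.array([1.0, 0.2, 0.1, 1.9, 2.5])
        rho, p = cg.spearman_rho_p(x, y)
        rho_ref = sps.spearmanr(x, y).statistic
        assert rho == pytest.approx(rho_ref)
        count = 0
        total = 0
        for perm in permutations(y):
            r = sps.spearmanr(x, perm).statistic
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho1, p1 = cg.spearman_rho_p(x, y)
        rho2, p2 = cg.spearman_rho_p(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_constant_vector_flagged_undefined(self):
        rho, p = cg.spearman_rho_p([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert np.isnan(rho) and np.isnan(p)


class TestDdct:
    def test_equal_cts_give_unit_fold_change(self):
        rec = cg.QPCRRecord(20, 20, 20, 20)
        assert cg.ddct_fold_change(rec) == 1.0

    def test_one_cycle_up_halves(self):
        rec = cg.QPCRRecord(20, 18, 21, 18)
        assert cg.ddct_fold_change(rec) == 0.5

    def test_two_cycles_down_quadruples(self):
        rec = cg.QPCRRecord(20, 18, 18, 18)
        assert cg.ddct_fold_change(rec) == 4.0

    def test_missing_ct_rejected(self):
        with pytest.raises(ValueError):
            cg.QPCRRecord(20, 18, float("nan"), 18)
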