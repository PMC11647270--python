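import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

import spotsim as s
from spotsim.deg import bh_adjust, deg_lm_covariate, majority_vote


class TestFilter:
    def test_low_count_gene_removed(self, toy_spots):
        # g1 totals 3 counts, g2 totals 2 -> g2 removed
        out = s.filter_dataset(toy_spots)
        assert "g2" not in set(out.genes)
        assert "g1" in set(out.genes)

    def test_background_spot_with_leaked_counts_removed(self, toy_spots):
        ds = toy_spots
        counts = ds.counts.copy()
        counts[3] = [4, 4, 4]  # background spot received leaked transcripts
        leaked = ds.replace_counts(counts, "ST-L")
        out = s.filter_dataset(leaked)
        assert "spot_2_0" not in set(out.barcodes)

    def test_cell_free_and_zero_count_spots_removed(self, toy_spots):
        out = s.filter_dataset(toy_spots)
        # spot_0_2 is occupied but has zero counts -> dropped
        assert "spot_0_2" not in set(out.barcodes)

    def test_idempotent_on_clean_data(self, toy_spots):
        once = s.filter_dataset(toy_spots)
        twice = s.filter_dataset(once)
        np.testing.assert_array_equal(once.counts, twice.counts)


class TestLoglib:
    def test_zero_count_maps_to_zero(self):
        counts = np.array([[0, 10]])
        out = s.normalize_loglib(counts)
        assert out[0, 0] == 0.0

    def test_depth_invariance(self):
        counts = np.array([[5, 10, 25]])
        np.testing.assert_allclose(
            s.normalize_loglib(counts), s.normalize_loglib(counts * 2)
        )

    def test_direct_formula(self):
        counts = np.zeros((1, 2))
        counts[0] = [100, 9900]
        out = s.normalize_loglib(counts, scale=1e4, pseudocount=1.0)
        assert np.isclose(out[0, 0], np.log(101))

    def test_zero_total_spot_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            s.normalize_loglib(np.zeros((1, 3)))


class TestTestUnits:
    def test_containing_includes_single_cell_spots(self, toy_spots):
        ia, ib = s.select_test_units(toy_spots, "ct0", "containing")
        barcodes = toy_spots.barcodes
        assert set(barcodes[ia]) == {"spot_0_0", "spot_0_2"}
        assert len(ib) == 0

    def test_single_mode_majority_rule(self):
        comp = np.array([[3, 2], [2, 3], [2, 2], [0, 0]])
        ds = s.SpotDataset(
            np.ones((4, 2), dtype=int),
            np.array(["g0", "g1"], dtype=object),
            np.array(["c", "d"], dtype=object),
            np.array([[0, 0], [0, 2], [1, 1], [2, 2]]),
            np.array([True, True, True, False]),
            np.array(["A", "A", "A", ""], dtype=object),
            comp,
        )
        ia, _ = s.select_test_units(ds, "c", "single")
        assert list(ia) == [0]  # {c:3, d:2} majority; the 2-2 tie excluded
        ia_d, _ = s.select_test_units(ds, "d", "single")
        assert list(ia_d) == [1]

    def test_regional_groups_independent_of_cell_type(self, tissue_run):
        ds = tissue_run["st_m"]
        groups = {
            ct: s.select_test_units(ds, ct, "regional") for ct in ds.cell_types
        }
        first = next(iter(groups.values()))
        for ia, ib in groups.values():
            np.testing.assert_array_equal(ia, first[0])
            np.testing.assert_array_equal(ib, first[1])
        assert len(first[0]) + len(first[1]) == int(ds.is_tissue.sum())


class TestTTest:
    def test_welch_p_against_closed_form(self):
        a = np.array([[1.0], [2.0], [3.0], [4.0]])
        b = np.array([[5.0], [6.0], [7.0], [8.0]])
        # closed-form Welch oracle
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t = (a.mean() - b.mean()) / np.sqrt(va / 4 + vb / 4)
        df = (va / 4 + vb / 4) ** 2 / (
            (va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3
        )
        expected = 2 * special.stdtr(df, -abs(t))
        p = s.deg_ttest(a, b)
        assert np.isclose(p[0], expected)
        assert np.isclose(p[0], 0.004659, atol=2e-5)

    def test_constant_groups_fall_back_to_one(self):
        a = np.full((5, 2), 3.0)
        b = np.full((6, 2), 3.0)
        np.testing.assert_array_equal(s.deg_ttest(a, b), [1.0, 1.0])

    def test_tiny_groups_fall_back_to_one(self):
        assert s.deg_ttest(np.array([[1.0]]), np.array([[2.0], [3.0]]))[0] == 1.0


class TestWilcoxon:
    @staticmethod
    def exhaustive_rank_p(a, b):
        """Two-sided p from the full permutation distribution of U."""
        pooled = np.concatenate([a, b])
        n1 = len(a)
        ranks = np.argsort(np.argsort(pooled)) + 1
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        n2 = len(b)
        us = []
        for comb in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
            us.append(u)
        us = np.array(us)
        lo = (us <= min(u_obs, n1 * n2 - u_obs)).mean()
        hi = (us >= max(u_obs, n1 * n2 - u_obs)).mean()
        return min(1.0, lo + hi)

    def test_fully_separated_groups_exact(self):
        a = np.array([[1.0], [2.0], [3.0], [4.0]])
        b = np.array([[5.0], [6.0], [7.0], [8.0]])
        p = s.deg_wilcoxon(a, b)
        oracle = self.exhaustive_rank_p(a[:, 0], b[:, 0])
        assert np.isclose(oracle, 2 / 70)
        assert np.isclose(p[0], oracle)

    def test_agrees_with_permutation_oracle_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.normal(size=(5, 1))
            b = rng.normal(size=(4, 1))
            p = s.deg_wilcoxon(a, b)
            assert np.isclose(p[0], self.exhaustive_rank_p(a[:, 0], b[:, 0]))

    def test_constant_groups_fall_back_to_one(self):
        a = np.full((5, 1), 2.0)
        b = np.full((5, 1), 2.0)
        assert s.deg_wilcoxon(a, b)[0] == 1.0


class TestInteractionModel:
    def test_constant_ratio_flagged(self):
        rng = np.random.default_rng(1)
        expr = rng.normal(size=(50, 3))
        cond = np.array(["A", "B"] * 25, dtype=object)
        p, flagged = deg_lm_covariate(expr, cond, np.full(50, 0.5))
        assert flagged
        np.testing.assert_array_equal(p, 1.0)

    def test_detects_interaction_effect(self):
        rng = np.random.default_rng(2)
        n = 400
        cond = np.array(["A"] * 200 + ["B"] * 200, dtype=object)
        ratio = rng.uniform(0, 1, n)
        is_b = (cond == "B").astype(float)
        expr = (1 + 0.5 * ratio + 2.0 * is_b * ratio + rng.normal(0, 1, n))[:, None]
        p, flagged = deg_lm_covariate(expr, cond, ratio)
        assert not flagged
        assert p[0] < 0.01

    def test_null_interaction_p_uniform(self):
        """Under no interaction the p-value is U(0,1)-distributed."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(500):
            n = 60
            cond = np.array(["A", "B"] * 30, dtype=object)
            ratio = rng.uniform(0, 1, n)
            expr = rng.normal(size=(n, 1))
            p, _ = deg_lm_covariate(expr, cond, ratio)
            pvals.append(p[0])
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 80
        cond = np.array(["A"] * 40 + ["B"] * 40, dtype=object)
        ratio = rng.uniform(0, 1, n)
        expr = rng.normal(size=(n, 2))
        p, _ = deg_lm_covariate(expr, cond, ratio)
        is_b = (cond == "B").astype(float)
        X = sm.add_constant(np.column_stack([is_b, ratio, is_b * ratio]))
        for g in range(2):
            fit = sm.OLS(expr[:, g], X).fit()
            assert np.isclose(p[g], fit.pvalues[3])


class TestMajority:
    @pytest.mark.parametrize(
        "n_calling, n_methods, expected",
        [(4, 6, True), (3, 6, False), (2, 2, True), (1, 2, False)],
    )
    def test_half_plus_one_rule(self, n_calling, n_methods, expected):
        calls = np.zeros((n_methods, 1), dtype=bool)
        calls[:n_calling, 0] = True
        assert majority_vote(calls)[0] == expected

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(np.array([[True]]))


class TestBH:
    @staticmethod
    def naive_bh(p):
        """Independent step-up oracle."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            running = min(running, p[idx] * m / rank)
            adj[idx] = running
        return adj

    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
        ],
    )
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_independent_step_up_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), self.naive_bh(p), atol=1e-12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=50, deadline=None)
    def test_adjusted_never_below_raw(self, p):
        assert (bh_adjust(p) >= np.asarray(p) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestRunDeg:
    def test_spot_order_invariance(self, tissue_run):
        ds = s.filter_dataset(tissue_run["st_m"])
        res = s.run_deg(ds, "ttest", "containing", 0.01)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_spots)
        res_p = s.run_deg(ds.subset_spots(perm), "ttest", "containing", 0.01)
        for r, rp in zip(res, res_p):
            np.testing.assert_allclose(r.p, rp.p)

    def test_empty_group_flags_and_returns_ones(self, toy_spots):
        # ct0 only appears in condition A spots
        res = [
            r for r in s.run_deg(toy_spots, "ttest", "containing", 0.01)
            if r.cell_type == "ct0"
        ][0]
        assert res.flagged
        np.testing.assert_array_equal(res.p, 1.0)

    def test_unknown_method_rejected(self, toy_spots):
        with pytest.raises(ValueError, match="method"):
            s.run_deg(toy_spots, "limma", "containing", 0.01)
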