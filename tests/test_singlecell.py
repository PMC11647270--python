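import numpy as np
import pytest

import spotsim as s
from spotsim.singlecell import MAX_DISPERSION


def make_labeled_counts(rng, n_per_group, mean=5.0):
    """Poisson toy with two donors and controllable type sizes."""
    blocks, types, donors = [], [], []
    for (ct, donor), n in n_per_group.items():
        blocks.append(rng.poisson(mean, size=(n, 30)))
        types += [ct] * n
        donors += [donor] * n
    return (
        np.vstack(blocks),
        np.array(types, dtype=object),
        np.array(donors, dtype=object),
    )


class TestEstimatePrior:
    def test_type_below_50_cells_in_one_donor_dropped(self):
        rng = np.random.default_rng(0)
        counts, types, donors = make_labeled_counts(
            rng,
            {
                ("keep1", "d1"): 60, ("keep1", "d2"): 60,
                ("keep2", "d1"): 55, ("keep2", "d2"): 70,
                ("rare", "d1"): 49, ("rare", "d2"): 200,
            },
            mean=30.0,
        )
        prior = s.estimate_prior(counts, types, donors)
        assert set(prior.cell_types) == {"keep1", "keep2"}

    def test_cells_with_499_counts_dropped(self):
        rng = np.random.default_rng(1)
        counts, types, _ = make_labeled_counts(
            rng, {("a", "d"): 60, ("b", "d"): 60}, mean=30.0
        )
        # every type-b cell gets exactly 499 total counts -> all dropped,
        # so only one type survives and estimation must refuse
        b_rows = np.flatnonzero(types == "b")
        counts[b_rows] = 0
        counts[b_rows, 0] = 499
        with pytest.raises(ValueError, match="fewer than 2"):
            s.estimate_prior(counts, types, None)
        # at exactly 500 the same cells clear the depth rule
        counts[b_rows, 0] = 500
        prior = s.estimate_prior(counts, types, None, min_cells_expressing=1)
        assert set(prior.cell_types) == {"a", "b"}

    def test_high_mito_cells_dropped(self):
        rng = np.random.default_rng(2)
        counts, types, _ = make_labeled_counts(
            rng, {("a", "d"): 60, ("b", "d"): 60}, mean=30.0
        )
        mito = np.zeros(30, dtype=bool)
        mito[0] = True
        counts[:5, 0] = counts[:5].sum(axis=1)  # ~50% mitochondrial
        prior_all = s.estimate_prior(counts, types, None)
        prior_filtered = s.estimate_prior(counts, types, None, mito_gene_mask=mito)
        a = int(np.flatnonzero(prior_filtered.cell_types == "a")[0])
        assert prior_filtered.mean[0, a] < prior_all.mean[0, a]

    def test_poisson_data_estimates_near_poisson_dispersion(self):
        rng = np.random.default_rng(3)
        counts, types, _ = make_labeled_counts(
            rng, {("a", "d"): 5000, ("b", "d"): 5000}, mean=20.0
        )
        prior = s.estimate_prior(counts, types, None)
        # Poisson = NB dispersion -> infinity; moment estimates must be large
        assert np.median(prior.dispersion) > 20

    def test_fewer_than_two_surviving_types_is_an_error(self):
        rng = np.random.default_rng(4)
        counts, types, donors = make_labeled_counts(
            rng, {("a", "d1"): 60, ("b", "d1"): 30}, mean=30.0
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            s.estimate_prior(counts, types, donors)


class TestSimulate:
    def test_no_de_case(self, small_prior, small_cfg):
        import dataclasses

        cfg = dataclasses.replace(small_cfg, p_de=0.0)
        _, gt = s.simulate_sc(small_prior, cfg, seed=0)
        assert not gt.is_de.any()
        assert (gt.logfc == 0).all()
        np.testing.assert_array_equal(gt.mean_A, gt.mean_B)

    def test_ground_truth_consistency_invariant(self, small_prior, small_cfg):
        _, gt = s.simulate_sc(small_prior, small_cfg, seed=1)
        np.testing.assert_allclose(gt.mean_B, gt.mean_A * np.exp2(gt.logfc))

    def test_fold_change_realized_in_empirical_means(self):
        """A gene with logfc=1 shows an empirical B/A mean ratio near 2."""
        prior = s.make_sc_prior(100, 2, seed=5)
        cfg = s.SimConfig(
            n_genes=100, n_cell_types=2, n_cells_per_type=2000, p_de=0.2
        )
        ds, gt = s.simulate_sc(prior, cfg, seed=5)
        c = 0
        ct = gt.cell_types[c]
        a = ds.counts[(ds.cell_type == ct) & (ds.condition == "A")]
        b = ds.counts[(ds.cell_type == ct) & (ds.condition == "B")]
        candidates = np.flatnonzero((gt.logfc[:, c] == 1.0) & (gt.mean_A[:, c] > 1))
        g = candidates[0]
        n = len(a)
        # delta-method oracle for the SE of the mean ratio
        d = prior.dispersion[g]
        mu_a, mu_b = gt.mean_A[g, c], gt.mean_B[g, c]
        var_a = (mu_a + mu_a**2 / d) / n
        var_b = (mu_b + mu_b**2 / d) / n
        ratio = b[:, g].mean() / a[:, g].mean()
        se = 2 * np.sqrt(var_a / mu_a**2 + var_b / mu_b**2)
        assert abs(ratio - 2.0) < 3 * se

    def test_nb_moment_structure(self):
        """Sample variance tracks mu + mu^2/dispersion at large n."""
        genes = np.array([f"g{i}" for i in range(4)], dtype=object)
        mean = np.tile(np.array([[1.0], [3.0], [8.0], [20.0]]), (1, 2))
        disp = np.array([0.5, 1.0, 2.0, 5.0])
        prior = s.SCReference(genes, np.array(["x", "y"], dtype=object), mean, disp)
        cfg = s.SimConfig(n_genes=4, n_cell_types=2, n_cells_per_type=5000, p_de=0.0)
        ds, _ = s.simulate_sc(prior, cfg, seed=6)
        block = ds.counts[(ds.cell_type == "x") & (ds.condition == "A")]
        s2 = block.var(axis=0, ddof=1)
        theory = mean[:, 0] + mean[:, 0] ** 2 / disp
        np.testing.assert_allclose(s2, theory, rtol=0.25)

    def test_round_trip_prior_recovery(self):
        """simulate -> re-estimate recovers type means within 10%."""
        prior = s.make_sc_prior(200, 3, seed=8)
        cfg = s.SimConfig(
            n_genes=200, n_cell_types=3, n_cells_per_type=2000, p_de=0.0
        )
        ds, _ = s.simulate_sc(prior, cfg, seed=8)
        # the depth filter targets full droplet transcriptomes; a 200-gene
        # synthetic cell never reaches 500 counts, so disable it here
        est = s.estimate_prior(
            ds.counts, ds.cell_type, None, genes=ds.genes, min_counts_per_cell=0
        )
        gi = {g: i for i, g in enumerate(prior.genes)}
        for c, ct in enumerate(est.cell_types):
            pc = int(np.flatnonzero(prior.cell_types == ct)[0])
            for i, g in enumerate(est.genes):
                true = prior.mean[gi[g], pc]
                if true > 0.5:
                    assert abs(est.mean[i, c] - true) / true < 0.1

    def test_determinism(self, small_prior, small_cfg):
        a, _ = s.simulate_sc(small_prior, small_cfg, seed=3)
        b, _ = s.simulate_sc(small_prior, small_cfg, seed=3)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestGroundTruthType:
    def test_nonzero_logfc_without_flag_rejected(self):
        genes = np.array(["g0"], dtype=object)
        cts = np.array(["c0"], dtype=object)
        with pytest.raises(ValueError, match="logfc"):
            s.GroundTruth(
                genes, cts,
                is_de=np.array([[False]]),
                logfc=np.array([[1.0]]),
                mean_A=np.array([[1.0]]),
                mean_B=np.array([[2.0]]),
            )


class TestInflate:
    def test_full_pool_is_a_permutation(self, tissue_run):
        sc = tissue_run["sc"]
        out = s.inflate_sc_baseline(sc, sc.n_cells, seed=0)
        assert out.counts.sum() == sc.counts.sum()
        assert sorted(map(str, out.cell_type)) == sorted(map(str, sc.cell_type))

    def test_seed_reproducibility(self, tissue_run):
        sc = tissue_run["sc"]
        a = s.inflate_sc_baseline(sc, 100, seed=4)
        b = s.inflate_sc_baseline(sc, 100, seed=4)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_invalid_sizes_rejected(self, tissue_run):
        sc = tissue_run["sc"]
        with pytest.raises(ValueError):
            s.inflate_sc_baseline(sc, 0)
        with pytest.raises(ValueError):
            s.inflate_sc_baseline(sc, sc.n_cells + 1)


def test_screference_tsv_round_trip(tmp_path, small_prior):
    path = tmp_path / "prior.tsv"
    small_prior.to_tsv(path)
    back = s.SCReference.from_tsv(path)
    np.testing.assert_allclose(back.mean, small_prior.mean)
    np.testing.assert_allclose(back.dispersion, small_prior.dispersion)
    assert list(back.cell_types) == list(small_prior.cell_types)
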