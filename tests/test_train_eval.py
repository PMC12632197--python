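"""Evaluation statistics, protocol helpers, training behaviour, noise."""

import itertools

import numpy as np
import pytest
import scipy.stats

from scist.datasets import SpotDataset
from scist.model import make_variant, small_config
from scist.train_eval import (TrainConfig, loso_folds, train, per_sample_pcc,
                              compare_models_wilcoxon,
                              gene_positive_correlation_test,
                              dispersion_score, geneset_spatial_map,
                              pseudo_bulk, inject_noise)


class TestLosoFolds:
    def test_three_sections_cover_the_set(self):
        folds = loso_folds(["a", "b", "c"])
        assert len(folds) == 3
        for tr, te in folds:
            assert sorted(tr + [te]) == ["a", "b", "c"]

    def test_each_section_in_exactly_n_minus_1_training_sets(self):
        folds = loso_folds(list("abcde"))
        for s in "abcde":
            assert sum(s in tr for tr, _ in folds) == 4

    def test_n5_matches_enumeration_oracle(self):
        secs = list("vwxyz")
        folds = loso_folds(secs)
        expected = [([t for t in secs if t != h], h) for h in secs]
        assert folds == expected

    def test_single_section_errors(self):
        with pytest.raises(ValueError, match="2 sections"):
            loso_folds(["only"])


class TestPerSamplePCC:
    def test_identical_matrices_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, (30, 5))
        res = per_sample_pcc(m, m)
        assert np.allclose(res.pcc, 1.0)
        assert res.mean == pytest.approx(1.0)

    def test_negated_prediction_gives_minus_one(self):
        rng = np.random.default_rng(1)
        m = rng.normal(0, 1, (30, 5))
        res = per_sample_pcc(-m, m)
        assert np.allclose(res.pcc, -1.0)

    def test_random_matrices_match_covariance_formula(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (50, 20))
        b = rng.normal(0, 1, (50, 20))
        res = per_sample_pcc(a, b)
        for g in range(20):
            x, y = a[:, g], b[:, g]
            r = ((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std())
            assert res.pcc[g] == pytest.approx(r, abs=1e-12)

    def test_affine_invariance_per_gene(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (40, 6))
        b = rng.normal(0, 1, (40, 6))
        res = per_sample_pcc(a, b)
        res2 = per_sample_pcc(3.5 * a + 2.0, 0.1 * b - 7.0)
        assert np.allclose(res.pcc, res2.pcc, atol=1e-10)

    def test_zero_variance_genes_flagged_undefined(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (20, 3))
        b = rng.normal(0, 1, (20, 3))
        a[:, 1] = 5.0
        res = per_sample_pcc(a, b)
        assert np.isnan(res.pcc[1]) and res.n_undefined == 1
        defined = [res.pcc[0], res.pcc[2]]
        assert res.mean == pytest.approx(np.mean(defined))

    def test_too_few_spots_errors(self):
        with pytest.raises(ValueError, match="3 spots"):
            per_sample_pcc(np.ones((2, 3)), np.ones((2, 3)))


class TestWilcoxon:
    def test_identical_metrics_flagged(self):
        p, defined = compare_models_wilcoxon(np.ones(6), np.ones(6))
        assert p == 1.0 and not defined

    def test_constant_positive_shift_attains_minimal_p(self):
        a = np.arange(10, dtype=float) + 1.0
        p, defined = compare_models_wilcoxon(a + 0.5, a)
        # all signs positive: two-sided exact p = 2 / 2^10
        assert defined
        assert p == pytest.approx(2 / 1024)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_pairs_match_scipy_exact_null(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 9)
        b = rng.normal(0, 1, 9)
        p, _ = compare_models_wilcoxon(a, b)
        ref = scipy.stats.wilcoxon(a - b, zero_method="wilcox",
                                   method="exact").pvalue
        assert p == pytest.approx(float(ref), abs=1e-12)

    def test_one_sided_option(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 0.2, 8)
        b = rng.normal(0.0, 0.2, 8)
        p_g, _ = compare_models_wilcoxon(a, b, alternative="greater")
        p_l, _ = compare_models_wilcoxon(a, b, alternative="less")
        assert p_g < 0.05 < p_l

    def test_exact_null_matches_full_sign_enumeration(self):
        """Cross-check against an independent 2^n enumeration with midranks."""
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 8)
        b = a + rng.normal(0, 1, 8)
        d = a - b
        ranks = scipy.stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [sum(r for r, s in zip(ranks, signs) if s > 0)
              for signs in itertools.product([1, -1], repeat=8)]
        ws = np.array(ws)
        p_two = min(1.0, 2 * min((ws <= w_obs + 1e-9).mean(),
                                 (ws >= w_obs - 1e-9).mean()))
        p, _ = compare_models_wilcoxon(a, b)
        assert p == pytest.approx(p_two, abs=1e-12)


class TestPositiveCorrelationTest:
    def test_zero_correlation_gives_half(self):
        raw, _ = gene_positive_correlation_test(np.array([0.0]), n_spots=30)
        assert raw[0] == pytest.approx(0.5)

    def test_perfect_correlation_hits_floor(self):
        raw, _ = gene_positive_correlation_test(np.array([1.0]), n_spots=30)
        assert raw[0] == 0.0

    def test_r_half_n27_matches_quadrature_oracle(self):
        raw, _ = gene_positive_correlation_test(np.array([0.5]), n_spots=27)
        t = 0.5 * np.sqrt(25 / (1 - 0.25))
        # numerically integrate the t density tail (independent of scipy.sf)
        df = 25
        x = np.linspace(t, 200, 2_000_001)
        from scipy.special import gammaln
        logc = gammaln((df + 1) / 2) - gammaln(df / 2) \
            - 0.5 * np.log(df * np.pi)
        pdf = np.exp(logc - (df + 1) / 2 * np.log1p(x * x / df))
        tail = np.trapezoid(pdf, x)
        assert raw[0] == pytest.approx(tail, abs=1e-6)

    def test_bh_adjustment_preserves_raw_ordering(self):
        rng = np.random.default_rng(7)
        pcc = rng.uniform(-0.5, 0.9, 40)
        raw, adj = gene_positive_correlation_test(pcc, n_spots=50)
        order_raw = np.argsort(raw)
        assert np.all(np.diff(adj[order_raw]) >= -1e-12)
        assert np.all((adj >= raw - 1e-12) & (adj <= 1.0))

    def test_nan_correlations_are_passed_through(self):
        raw, adj = gene_positive_correlation_test(
            np.array([0.3, np.nan, -0.2]), n_spots=20)
        assert np.isnan(raw[1]) and np.isnan(adj[1])
        assert np.isfinite(adj[0]) and np.isfinite(adj[2])


class TestDispersionScore:
    def test_all_equal_gives_zero(self):
        assert dispersion_score(np.full(50, 0.3)) == 0.0

    def test_single_outlier_matches_enumeration(self):
        pcc = np.zeros(100)
        pcc[42] = 1.0
        # top decile = 10 genes: one at 1, nine at 0; median 0
        assert dispersion_score(pcc) == pytest.approx(0.1)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(8)
        pcc = rng.uniform(-1, 1, 73)
        assert dispersion_score(pcc) == pytest.approx(
            dispersion_score(rng.permutation(pcc)))

    def test_too_few_genes_undefined(self):
        assert np.isnan(dispersion_score(np.arange(9) / 10))

    def test_nonnegative_on_random_input(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            assert dispersion_score(rng.uniform(-1, 1, 31)) >= 0


class TestAggregations:
    def test_singleton_gene_set_is_that_column(self):
        rng = np.random.default_rng(10)
        pred = rng.normal(0, 1, (15, 4))
        genes = list("abcd")
        out = geneset_spatial_map(pred, genes, ["c"])
        assert np.array_equal(out, pred[:, 2])

    def test_full_panel_is_row_mean_and_random_set_matches_mask(self):
        rng = np.random.default_rng(11)
        pred = rng.normal(0, 1, (15, 6))
        genes = [f"g{i}" for i in range(6)]
        assert np.allclose(geneset_spatial_map(pred, genes, genes),
                           pred.mean(axis=1))
        subset = ["g1", "g4", "g5"]
        assert np.allclose(geneset_spatial_map(pred, genes, subset),
                           pred[:, [1, 4, 5]].mean(axis=1))

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError, match="intersect"):
            geneset_spatial_map(np.ones((5, 2)), ["a", "b"], ["zz"])

    def test_pseudo_bulk_column_mean_and_duplication_invariance(self):
        rng = np.random.default_rng(12)
        pred = rng.normal(0, 1, (9, 5))
        assert np.allclose(pseudo_bulk(pred), pred.mean(axis=0))
        assert np.allclose(pseudo_bulk(np.vstack([pred, pred])),
                           pseudo_bulk(pred))
        one = pred[:1]
        assert np.allclose(pseudo_bulk(one), one[0])


def make_dataset(n=24, n_genes=6, seed=0, size=32):
    rng = np.random.default_rng(seed)
    return SpotDataset(
        patches=rng.integers(0, 255, (n, size, size, 3)).astype(np.uint8),
        ie=rng.normal(0, 1, (n, n_genes)),
        labels=rng.normal(0, 1, (n, n_genes)),
        spot_ids=[f"s{i}" for i in range(n)],
        section_ids=["sec0"] * (n // 2) + ["sec1"] * (n - n // 2),
        patient_ids=["p0"] * n,
        genes=[f"g{i}" for i in range(n_genes)],
        centers=np.full((n, 2), 16.0),
    )


class TestInjectNoise:
    def test_level_zero_is_bit_exact_noop(self):
        ds = make_dataset()
        for kind in ("spot", "stain"):
            out = inject_noise(ds, kind, 0.0, seed=1)
            assert np.array_equal(out.patches, ds.patches)
            assert np.array_equal(out.ie, ds.ie)
            assert np.array_equal(out.labels, ds.labels)

    def test_level_one_spot_noise_moves_every_center_within_radius(self):
        ds = make_dataset(n=30)
        out = inject_noise(ds, "spot", 1.0, seed=2)
        delta = out.centers - ds.centers
        assert np.all(np.any(delta != 0, axis=1))
        radius = ds.patches.shape[1] // 2
        assert np.all(np.abs(delta) <= radius)
        assert np.array_equal(out.labels, ds.labels)  # labels untouched

    def test_fractional_level_perturbs_exact_count(self):
        ds = make_dataset(n=200, size=16)
        out = inject_noise(ds, "spot", 0.04, seed=3)
        changed = [i for i in range(200)
                   if not np.array_equal(out.patches[i], ds.patches[i])]
        assert len(changed) == round(0.04 * 200) == 8

    def test_stain_noise_changes_selected_patches_only(self):
        ds = make_dataset(n=50, size=16)
        out = inject_noise(ds, "stain", 0.2, seed=4, magnitude=0.3)
        changed = sum(not np.array_equal(out.patches[i], ds.patches[i])
                      for i in range(50))
        assert changed == 10
        assert np.array_equal(out.labels, ds.labels)

    def test_invalid_level_and_kind(self):
        ds = make_dataset(n=6)
        with pytest.raises(ValueError, match="outside"):
            inject_noise(ds, "spot", 1.2)
        with pytest.raises(ValueError, match="kind"):
            inject_noise(ds, "blur", 0.5)

    def test_seeded_injection_is_reproducible(self):
        ds = make_dataset(n=40, size=16)
        a = inject_noise(ds, "spot", 0.5, seed=5)
        b = inject_noise(ds, "spot", 0.5, seed=5)
        assert np.array_equal(a.patches, b.patches)


class TestTraining:
    def test_one_epoch_decreases_loss_and_same_seed_repeats(self):
        ds = make_dataset(n=32, n_genes=6, seed=13)
        cfg = TrainConfig(batch_size=8, epochs=4, learning_rate=1e-3, seed=3)
        curves = []
        for _ in range(2):
            model = make_variant(small_config(6, seed=2, image_size=32))
            model, curve = train(model, ds, cfg)
            curves.append(curve)
        assert curves[0] == curves[1]  # determinism
        assert curves[0][-1] < curves[0][0]  # descent

    def test_training_fits_ie_linked_labels_below_noise_floor(self):
        """Labels = linear(IE) + noise(sigma): a small model overfits a small
        training set below sigma^2 mean-squared error."""
        rng = np.random.default_rng(14)
        n, n_genes, sigma = 64, 6, 0.3
        ie = rng.normal(0, 1, (n, n_genes))
        A = rng.normal(0, 1, (n_genes, n_genes)) / np.sqrt(n_genes)
        labels = ie @ A + rng.normal(0, sigma, (n, n_genes))
        ds = make_dataset(n=n, n_genes=n_genes, seed=15)
        ds.ie = ie
        ds.labels = labels
        model = make_variant(small_config(n_genes, seed=4, image_size=32))
        model.cast(np.float32)
        cfg = TrainConfig(batch_size=16, epochs=40, learning_rate=3e-3, seed=6)
        model, curve = train(model, ds, cfg)
        assert curve[-1] < sigma ** 2

    def test_empty_dataset_errors(self):
        ds = make_dataset(n=4).subset(np.array([], dtype=int))
        model = make_variant(small_config(6, seed=0, image_size=32))
        with pytest.raises(ValueError, match="empty"):
            train(model, ds, TrainConfig(epochs=1))
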