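"""Decoding-relevance framework: balanced subsampling, kernels, nested
CV, model variants and sparse multiple kernel learning."""

import numpy as np
import pytest

import ecogface as ef
from ecogface import decoding as dec
from ecogface.containers import NONFACE_CATEGORIES


class TestSubsampleNonfaces:
    def test_target_50_draws_seven_or_eight_per_subcategory(self):
        cats = np.repeat(list(NONFACE_CATEGORIES) + ["human_face"], 50)
        idx = dec.subsample_nonfaces(cats, 50, seed=0)
        assert len(idx) == 50
        sizes = [np.sum(np.isin(idx, np.flatnonzero(cats == c))) for c in NONFACE_CATEGORIES]
        assert set(sizes) <= {7, 8} and sum(sizes) == 50

    def test_target_seven_gives_one_each(self):
        cats = np.repeat(list(NONFACE_CATEGORIES), 10)
        idx = dec.subsample_nonfaces(cats, 7, seed=1)
        sizes = [np.sum(cats[idx] == c) for c in NONFACE_CATEGORIES]
        assert sizes == [1] * 7

    def test_two_seeds_same_size_profile_different_draws(self):
        cats = np.repeat(list(NONFACE_CATEGORIES), 30)
        a = dec.subsample_nonfaces(cats, 70, seed=0)
        b = dec.subsample_nonfaces(cats, 70, seed=1)
        assert len(a) == len(b) == 70
        assert not np.array_equal(a, b)
        assert np.array_equal(a, dec.subsample_nonfaces(cats, 70, seed=0))

    def test_excess_target_rejected(self):
        cats = np.repeat(list(NONFACE_CATEGORIES), 2)
        with pytest.raises(ValueError):
            dec.subsample_nonfaces(cats, 100, seed=0)


class TestLinearKernel:
    def test_orthonormal_rows_give_identity(self):
        k = dec.linear_kernel(np.eye(4))
        np.testing.assert_allclose(k, np.eye(4))

    def test_matches_double_loop(self, rng):
        x = rng.standard_normal((5, 7))
        k = dec.linear_kernel(x)
        brute = np.array([[xi @ xj for xj in x] for xi in x])
        np.testing.assert_allclose(k, brute)

    def test_kernel_of_concatenated_blocks_is_sum_of_block_kernels(self, rng):
        """Dot-product additivity: the full-feature kernel equals the
        sum of per-site kernels — the identity behind the sparse model."""
        blocks = [rng.standard_normal((6, 4)) for _ in range(3)]
        full = dec.linear_kernel(np.hstack(blocks))
        summed = sum(dec.linear_kernel(b) for b in blocks)
        np.testing.assert_allclose(full, summed, atol=1e-10)


class TestCrossvalSVM:
    def test_balanced_accuracy_definition(self):
        y_true = np.array(["a"] * 10 + ["b"] * 10)
        y_pred = np.array(["a"] * 8 + ["b"] * 2 + ["b"] * 6 + ["a"] * 4)
        bacc, s0, s1 = dec.balanced_accuracy(y_true, y_pred)
        assert (s0, s1) == (0.8, 0.6)
        assert bacc == pytest.approx(0.7)

    def test_noise_features_decode_at_chance(self, rng):
        x = rng.standard_normal((100, 30))
        labels = np.array(["a", "b"] * 50)
        res = dec.crossval_svm(dec.linear_kernel(x), labels, seed=0)
        assert 35.0 <= res.balanced_accuracy <= 65.0

    def test_separable_pattern_decodes_above_95(self, rng):
        x = rng.standard_normal((80, 10))
        labels = np.array(["a"] * 40 + ["b"] * 40)
        x[:40, 0] += 8.0
        res = dec.crossval_svm(dec.linear_kernel(x), labels, seed=1)
        assert res.balanced_accuracy >= 95.0

    def test_fold_structure_disjoint_stratified(self, rng):
        labels = np.array(["a"] * 30 + ["b"] * 30)
        folds = dec._stratified_folds(labels, 5, rng)
        seen = np.concatenate([test for _, test in folds])
        assert sorted(seen) == list(range(60))
        for train, test in folds:
            assert set(train) & set(test) == set()
            assert set(labels[test]) == {"a", "b"}

    def test_fold_metrics_balanced_accuracy_consistent(self, rng):
        x = rng.standard_normal((60, 10))
        x[:30, 0] += 2.0
        labels = np.array(["a"] * 30 + ["b"] * 30)
        res = dec.crossval_svm(dec.linear_kernel(x), labels, seed=2)
        for f in res.fold_metrics:
            assert f["balanced_accuracy"] == pytest.approx(
                (f["sens_class0"] + f["sens_class1"]) / 2
            )


class TestPermutationSignificance:
    def test_null_distribution_centred_on_chance(self, rng):
        x = rng.standard_normal((60, 10))
        labels = np.array(["a", "b"] * 30)
        K = dec.linear_kernel(x)
        cv = dec.CVConfig(inner_folds=0)
        null = [
            dec.crossval_svm(K, rng.permutation(labels), cv, rng).balanced_accuracy
            for _ in range(60)
        ]
        assert abs(float(np.mean(null)) - 50.0) < 4.0

    def test_separable_data_reaches_minimal_p(self, rng):
        x = rng.standard_normal((40, 5))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        x[:20, 0] += 10.0
        K = dec.linear_kernel(x)
        cv = dec.CVConfig(inner_folds=0)
        res = dec.crossval_svm(K, labels, cv, seed=0)
        p = dec.permutation_significance(K, labels, res.balanced_accuracy, 99, cv, seed=0)
        assert p == pytest.approx(1 / 100)


class TestSiteSetModels:
    def test_ablating_planted_face_sites_lowers_accuracy(self, planted_bp):
        """Model II (face sites removed) underperforms model I when all
        planted signal lives on face sites: paired across seeds."""
        bp, face_sites = planted_bp
        others = [s for s in bp.channel_names if s not in face_sites]
        cv = dec.CVConfig(inner_folds=0)
        diffs = []
        for seed in range(8):
            m1 = dec.run_site_set_model(bp, bp.channel_names, seed, cv=cv)
            m2 = dec.run_site_set_model(bp, others, seed, cv=cv)
            diffs.append(m1.balanced_accuracy - m2.balanced_accuracy)
        assert np.mean(diffs) > 0
        assert sum(d > 0 for d in diffs) >= 7

    def test_signal_free_data_not_significant(self):
        layout = ef.make_layout(6, seed=0)
        bp = ef.simulate_band_power(layout, [], trials_per_category=10, seed=1)
        cv = dec.CVConfig(inner_folds=0)
        res = dec.run_site_set_model(bp, bp.channel_names, seed=2, cv=cv, n_perm=49)
        assert res.p_permutation > 0.05

    def test_full_site_set_equals_model_one(self, planted_bp):
        bp, _ = planted_bp
        cv = dec.CVConfig(inner_folds=0)
        a = dec.run_site_set_model(bp, bp.channel_names, seed=3, cv=cv)
        b = dec.run_site_set_model(bp, list(bp.channel_names), seed=3, cv=cv)
        assert a.balanced_accuracy == b.balanced_accuracy


class TestRandomSetModels:
    def test_requested_model_count_produced(self, planted_bp):
        bp, face_sites = planted_bp
        task = [s for s in bp.channel_names if s not in face_sites]
        r = dec.random_set_models(bp, face_sites, task, n_models=25, size=6, seed=0)
        assert len(r.accuracies) == 25
        assert len(r.site_sets) == 25
        assert all(any(s in face_sites for s in ss) for ss in r.site_sets)

    def test_accuracy_increases_with_face_site_proportion(self, weak_planted_bp):
        bp, face_sites = weak_planted_bp
        task = [s for s in bp.channel_names if s not in face_sites]
        r = dec.random_set_models(
            bp, face_sites, task, n_models=99, size=5, seed=1,
            cv=dec.CVConfig(outer_folds=3, inner_folds=0),
        )
        assert r.rho > 0
        assert r.p < 0.05

    def test_all_face_pool_degenerate_proportions(self, planted_bp):
        bp, face_sites = planted_bp
        r = dec.random_set_models(bp, face_sites, [], n_models=10, size=3, seed=2)
        assert np.all(r.face_proportions == 1.0)
        assert np.isnan(r.rho)


class TestSparseMKL:
    def test_single_kernel_degenerates_to_plain_svm(self, rng):
        x = rng.standard_normal((60, 8))
        x[:30, 0] += 3.0
        labels = np.array(["a"] * 30 + ["b"] * 30)
        K = dec.linear_kernel(x)
        cv = dec.CVConfig(inner_folds=0)
        res, cmap = dec.sparse_mkl([K], labels, cv=cv, seed=0)
        assert cmap.contributions[0] == pytest.approx(1.0)
        plain = dec.crossval_svm(K, labels, cv, seed=0)
        assert abs(res.balanced_accuracy - plain.balanced_accuracy) <= 10.0

    def test_contribution_concentrates_on_planted_site(self, rng):
        """Signal on one site among 10 noise sites: its contribution
        exceeds 0.5 and the solution is sparse."""
        labels = np.array(["a"] * 30 + ["b"] * 30)
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            kernels = []
            for site in range(11):
                x = r.standard_normal((60, 20))
                if site == 4:
                    x[:30] += 1.5
                kernels.append(dec.linear_kernel(x))
            res, cmap = dec.sparse_mkl(
                kernels, labels, cv=dec.CVConfig(inner_folds=0), seed=seed
            )
            if cmap.contributions[4] > 0.5 and cmap.sparsity <= 0.5:
                hits += 1
        assert hits >= 4

    def test_sparsity_definition(self):
        cmap = dec.ContributionMap(
            names=[f"s{i}" for i in range(20)],
            contributions=np.r_[np.full(7, 1 / 7), np.zeros(13)],
            sparsity=7 / 20,
        )
        assert cmap.sparsity == pytest.approx(0.35)

    def test_contributions_nonnegative_sum_to_one(self, planted_bp):
        bp, _ = planted_bp
        rng = np.random.default_rng(3)
        idx, labels = dec._face_nonface_epochs(bp, rng)
        kernels = {
            s: dec.linear_kernel(dec.build_features(bp, [s], idx))
            for s in bp.channel_names
        }
        _, cmap = dec.sparse_mkl(kernels, labels, cv=dec.CVConfig(inner_folds=0), seed=4)
        assert np.all(cmap.contributions >= 0)
        assert cmap.contributions.sum() == pytest.approx(1.0)


class TestContributionCorrelation:
    def test_proportional_contributions_give_r_one(self):
        sel = np.array([0.5, 1.0, 2.0, 3.0])
        r, _ = dec.contribution_selectivity_correlation(0.1 * sel, sel)
        assert r == pytest.approx(1.0)

    def test_permuted_contributions_centred_on_zero(self, rng):
        sel = rng.standard_normal(30)
        rs = []
        for _ in range(200):
            r, _ = dec.contribution_selectivity_correlation(rng.permutation(sel), sel)
            rs.append(r)
        assert abs(float(np.mean(rs))) < 0.05

    def test_misaligned_lists_rejected(self):
        with pytest.raises(ValueError):
            dec.contribution_selectivity_correlation(np.ones(3), np.ones(4))
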