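import numpy as np
import pytest
from scipy.stats import multivariate_normal

from morphoerr.discriminant import (fit_lda, loocv_classify, predict,
                                    resubstitution_classify, stepwise_select)


def two_clouds(rng, n=30, sep=10.0, sd=0.1, p=4):
    x = np.concatenate([rng.normal(-sep / 2, sd, size=(n, p)),
                        rng.normal(sep / 2, sd, size=(n, p))])
    labels = np.array(["a"] * n + ["b"] * n)
    return x, labels


class TestFitAndPredict:
    def test_separated_clouds_confident(self, rng):
        x, labels = two_clouds(rng)
        res = resubstitution_classify(x, labels)
        assert res.pgm_error_percent == 0.0
        assert np.all(res.posteriors.max(axis=1) > 0.999)

    def test_posteriors_normalized(self, rng):
        x = rng.normal(size=(40, 6))
        labels = np.array(["a", "b", "c", "d"] * 10)
        model = fit_lda(x, labels)
        _, post = predict(model, rng.normal(size=(15, 6)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_1d_two_group_boundary_at_midpoint(self, rng):
        """Equal priors and covariance put the decision boundary midway."""
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(4, 1, 50)])[:, None]
        labels = np.array(["a"] * 50 + ["b"] * 50)
        model = fit_lda(x, labels, priors=[0.5, 0.5])
        mid = 0.5 * (x[:50].mean() + x[50:].mean())
        eps = 1e-6 * np.ptp(x)
        below, _ = predict(model, np.array([[mid - 0.2]]))
        above, _ = predict(model, np.array([[mid + 0.2]]))
        assert below[0] == "a" and above[0] == "b"
        _, post_mid = predict(model, np.array([[mid]]))
        np.testing.assert_allclose(post_mid[0], [0.5, 0.5], atol=1e-6)

    def test_posteriors_match_gaussian_density_oracle(self, rng):
        """Posteriors equal brute-force pooled-covariance Gaussian densities."""
        means = {"a": np.zeros(5), "b": np.full(5, 1.5), "c": np.full(5, -1.0)}
        cov_l = rng.normal(size=(5, 5)) * 0.3 + np.eye(5)
        cov = cov_l @ cov_l.T
        xs, labels = [], []
        for g, mu in means.items():
            xs.append(rng.multivariate_normal(mu, cov, size=25))
            labels += [g] * 25
        x = np.concatenate(xs)
        labels = np.array(labels)
        model = fit_lda(x, labels)
        unknowns = rng.normal(size=(10, 5))
        _, post = predict(model, unknowns)
        # independent route: explicit group means + pooled covariance + pdf
        pooled = sum((x[labels == g] - x[labels == g].mean(0)).T
                     @ (x[labels == g] - x[labels == g].mean(0))
                     for g in means) / (len(x) - 3)
        dens = np.column_stack([
            (labels == g).mean() * multivariate_normal.pdf(
                unknowns, x[labels == g].mean(0), pooled)
            for g in sorted(means)])
        np.testing.assert_allclose(post, dens / dens.sum(1, keepdims=True), atol=1e-8)

    def test_matches_sklearn_reference(self, rng):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        x = rng.normal(size=(90, 7))
        labels = np.repeat(["a", "b", "c"], 30)
        x[labels == "b"] += 0.8
        model = fit_lda(x, labels)
        _, post = predict(model, x)
        ref = sklearn.LinearDiscriminantAnalysis().fit(x, labels)
        np.testing.assert_allclose(post, ref.predict_proba(x), atol=1e-6)

    def test_rank_deficient_input_handled(self, rng):
        """Duplicated columns (rank-deficient) fit via PC-space reduction."""
        x, labels = two_clouds(rng, sd=0.5, sep=4.0, p=3)
        x = np.hstack([x, x[:, :1]])  # exact collinearity
        res = resubstitution_classify(x, labels)
        assert res.pgm_error_percent == 0.0

    def test_rotation_invariance_of_predictions(self, rng):
        x = rng.normal(size=(60, 6))
        labels = np.repeat(["a", "b", "c"], 20)
        x[labels == "b", 0] += 1.0
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        p1 = resubstitution_classify(x, labels).predicted
        p2 = resubstitution_classify(x @ q, labels).predicted
        assert np.array_equal(p1, p2)

    def test_proportional_equals_uniform_priors_when_balanced(self, rng):
        x, labels = two_clouds(rng, sd=2.0, sep=2.0)
        r1 = resubstitution_classify(x, labels, priors="proportional")
        r2 = resubstitution_classify(x, labels, priors=[0.5, 0.5])
        assert np.array_equal(r1.predicted, r2.predicted)

    def test_singleton_group_rejected(self, rng):
        x = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_lda(x, ["a", "a", "a", "a", "b"])


class TestLoocv:
    def test_perfect_separation_zero_error(self, rng):
        x, labels = two_clouds(rng)
        assert loocv_classify(x, labels).pgm_error_percent == 0.0

    def test_error_percentage_contract(self, rng):
        """pgm_error_percent is exactly 100 * misclassified / n."""
        x, labels = two_clouds(rng, n=20, sep=1.0, sd=2.0)
        res = loocv_classify(x, labels)
        assert res.pgm_error_percent == pytest.approx(
            100.0 * res.n_misclassified / 40)

    def test_permuted_labels_give_chance_error(self, rng):
        """Five equal groups with shuffled labels misclassify ~80%."""
        errs = []
        for seed in range(8):
            r = np.random.default_rng(seed)
            x = np.concatenate([r.normal(5 * i, 0.2, size=(30, 3)) for i in range(5)])
            labels = np.repeat([f"g{i}" for i in range(5)], 30)
            errs.append(loocv_classify(x, r.permutation(labels)).pgm_error_percent)
        assert abs(np.mean(errs) - 80.0) < 5.0

    def test_loocv_at_least_resubstitution_error_on_average(self):
        """Cross-validation removes the optimism of resubstitution error."""
        diffs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = np.concatenate([r.normal(0, 1.5, size=(15, 8)),
                                r.normal(0.8, 1.5, size=(15, 8)),
                                r.normal(-0.8, 1.5, size=(15, 8))])
            labels = np.repeat(["a", "b", "c"], 15)
            diffs.append(loocv_classify(x, labels).pgm_error_percent
                         - resubstitution_classify(x, labels).pgm_error_percent)
        assert np.mean(diffs) >= 0.0

    def test_small_group_rejected(self, rng):
        x = rng.normal(size=(6, 3))
        with pytest.raises(ValueError, match="b"):
            loocv_classify(x, ["a", "a", "a", "a", "b", "b"])


class TestStepwise:
    def test_planted_signal_selected_first(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(size=(60, 10))
            labels = np.repeat(["a", "b"], 30)
            x[labels == "b", 3] += 5.0  # 5-sd mean shift on variable 4
            sel = stepwise_select(x, labels, alpha_enter=0.05)
            hits += bool(sel) and sel[0] == "v4"
        assert hits >= 19

    def test_identical_groups_select_nothing_much(self, rng):
        x = rng.normal(size=(40, 8))
        labels = np.repeat(["a", "b"], 20)
        sel = stepwise_select(x, labels, alpha_enter=0.05)
        assert len(sel) <= 2  # null case: empty or chance-level pickup

    def test_column_order_invariance(self, rng):
        x = rng.normal(size=(80, 6))
        labels = np.repeat(["a", "b"], 40)
        x[labels == "b", 1] += 2.0
        x[labels == "b", 4] += 1.0
        names = [f"v{i + 1}" for i in range(6)]
        sel1 = stepwise_select(x, labels, feature_names=names)
        perm = [3, 0, 5, 1, 4, 2]
        sel2 = stepwise_select(x[:, perm], labels,
                               feature_names=[names[i] for i in perm])
        assert sel1 == sel2

    def test_landmark_coordinate_naming(self, rng):
        x = rng.normal(size=(30, 4, 2))
        labels = np.repeat(["a", "b"], 15)
        x[labels == "b", 2, 1] += 4.0
        sel = stepwise_select(x, labels)
        assert sel and sel[0] == "lm3_y"
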