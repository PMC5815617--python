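"""Pooled-covariance LDA against independent oracles."""

import numpy as np
import pytest

from crossslope.gait_data import DataError
from crossslope.lda import (
    ConditioningError,
    decision_scores,
    fit_lda_arrays,
    load_model,
    majority_vote,
    predict,
    save_model,
)


def oracle_predict(Xtr, ytr, Xte, priors="empirical"):
    """Independent brute-force pooled-covariance discriminant: explicit
    matrix inverse, per-row per-class loop, no shared code with the
    implementation."""
    classes = sorted(set(ytr))
    n, p = Xtr.shape
    mus, scatter = {}, np.zeros((p, p))
    for c in classes:
        Xc = Xtr[ytr == c]
        mus[c] = Xc.mean(axis=0)
        scatter += (Xc - mus[c]).T @ (Xc - mus[c])
    sigma_inv = np.linalg.inv(scatter / (n - len(classes)))
    logpri = {
        c: np.log((ytr == c).mean() if priors == "empirical" else 1 / len(classes))
        for c in classes
    }
    out = []
    for x in Xte:
        best, best_d = None, -np.inf
        for c in classes:
            d = x @ sigma_inv @ mus[c] - 0.5 * mus[c] @ sigma_inv @ mus[c] + logpri[c]
            if d > best_d:
                best, best_d = c, d
        out.append(best)
    return np.array(out)


def random_instance(rng, n_classes=3, p=None, n=None):
    p = p or rng.integers(2, 6)
    n = n or rng.integers(30, 200)
    means = rng.normal(0, 2, size=(n_classes, p))
    A = rng.normal(size=(p, p))
    cov = A @ A.T + 0.5 * np.eye(p)
    y = rng.integers(0, n_classes, size=n)
    # guarantee ≥2 rows per class
    y[: 2 * n_classes] = np.repeat(np.arange(n_classes), 2)
    X = means[y] + rng.multivariate_normal(np.zeros(p), cov, size=n)
    return X, np.array([f"c{c}" for c in y])


class TestOracleAgreement:
    def test_matches_brute_force_on_many_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            X, y = random_instance(rng)
            Xte = X + rng.normal(0, 0.5, size=X.shape)
            model = fit_lda_arrays(X, y, shrinkage=0.0)
            np.testing.assert_array_equal(
                predict(model, Xte), oracle_predict(X, y, Xte)
            )

    def test_matches_scikit_learn_with_balanced_classes(self):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        rng = np.random.default_rng(12)
        for _ in range(20):
            p, per = 4, 40
            means = rng.normal(0, 2, size=(3, p))
            y = np.repeat(np.array(["a", "b", "c"]), per)
            X = means[np.repeat(np.arange(3), per)] + rng.normal(size=(3 * per, p))
            Xte = rng.permutation(X)
            ours = predict(fit_lda_arrays(X, y, shrinkage=0.0), Xte)
            ref = sklearn_lda().fit(X, y).predict(Xte)
            np.testing.assert_array_equal(ours, ref)

    def test_boundary_close_to_bayes_for_known_gaussians(self):
        # two equal-covariance 2-D Gaussians: the Bayes boundary is the
        # perpendicular bisector of the means; compare normal directions.
        rng = np.random.default_rng(13)
        mu = np.array([[-1.5, 0.0], [1.5, 0.0]])
        y = np.repeat(np.array(["a", "b"]), 200)
        X = mu[np.repeat([0, 1], 200)] + rng.normal(size=(400, 2))
        model = fit_lda_arrays(X, y, shrinkage=0.0)
        model._ensure_coefficients()
        w = model._coef[1] - model._coef[0]  # fitted boundary normal
        w_bayes = mu[1] - mu[0]
        cos = w @ w_bayes / (np.linalg.norm(w) * np.linalg.norm(w_bayes))
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0


class TestAlgebraicLimits:
    def test_point_at_class_mean_predicts_that_class(self):
        rng = np.random.default_rng(14)
        X, y = random_instance(rng, p=3, n=90)
        model = fit_lda_arrays(X, y, shrinkage=1e-3, priors="uniform")
        for i, c in enumerate(model.class_order):
            assert predict(model, model.means[i])[0] == c

    def test_identical_means_scores_differ_only_by_log_priors(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(90, 3))
        y = np.repeat(np.array(["a", "b", "c"]), 30)  # same mean-ish classes
        X -= X.mean(axis=0)
        for c in "abc":  # force exactly identical class means
            X[y == c] -= X[y == c].mean(axis=0)
        model = fit_lda_arrays(X, y, shrinkage=0.0, priors="uniform")
        scores = decision_scores(model, rng.normal(size=(5, 3)))
        np.testing.assert_allclose(scores - scores[:, :1], 0.0, atol=1e-9)

    def test_full_shrinkage_is_nearest_mean_rule(self):
        rng = np.random.default_rng(16)
        X, y = random_instance(rng, p=4, n=120)
        model = fit_lda_arrays(X, y, shrinkage=1.0, priors="uniform")
        Xte = rng.normal(0, 2, size=(50, 4))
        dists = np.stack(
            [np.linalg.norm(Xte - m, axis=1) for m in model.means], axis=1
        )
        nearest = np.asarray(model.class_order, dtype=object)[dists.argmin(axis=1)]
        np.testing.assert_array_equal(predict(model, Xte), nearest)

    def test_scale_invariance_at_zero_shrinkage(self):
        rng = np.random.default_rng(17)
        X, y = random_instance(rng, p=4, n=150)
        Xte = rng.normal(size=(40, 4))
        base = predict(fit_lda_arrays(X, y, shrinkage=0.0), Xte)
        scale = np.array([100.0, 0.01, 1.0, 5.0])
        rescaled = predict(fit_lda_arrays(X * scale, y, shrinkage=0.0), Xte * scale)
        np.testing.assert_array_equal(base, rescaled)

    def test_shrinkage_improves_conditioning_monotonically(self):
        rng = np.random.default_rng(18)
        X, y = random_instance(rng, p=5, n=60)
        conds = []
        for lam in [0.0, 1e-3, 1e-2, 0.1, 0.5, 1.0]:
            model = fit_lda_arrays(X, y, shrinkage=lam)
            conds.append(np.linalg.cond(model.shrunk_covariance()))
        assert all(a >= b - 1e-6 for a, b in zip(conds, conds[1:]))


class TestDegenerateInputs:
    def test_singular_covariance_advises_shrinkage(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(10, 20))  # p > n
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ConditioningError, match="shrinkage"):
            fit_lda_arrays(X, y, shrinkage=0.0)

    def test_collinear_feature_with_shrinkage_changes_little(self, preset_matrix):
        from crossslope.features import restrict_to_signals

        sub = restrict_to_signals(
            preset_matrix, ["ankle_inversion_angvel", "foot_vert_velocity"]
        )
        X, y = sub.X, sub.y
        Xdup = np.hstack([X, X[:, :1]])  # perfectly collinear extra column
        acc = (predict(fit_lda_arrays(X, y, shrinkage=1e-4), X) == y).mean()
        acc_dup = (predict(fit_lda_arrays(Xdup, y, shrinkage=1e-4), Xdup) == y).mean()
        assert abs(acc - acc_dup) < 0.01

    def test_class_with_one_row_rejected(self):
        X = np.zeros((5, 2))
        y = np.array(["a", "a", "b", "b", "c"])
        with pytest.raises(DataError, match="<2 rows"):
            fit_lda_arrays(X, y)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "labels,k,expected",
        [
            (["flush", "inversion", "inversion"], 3, "inversion"),
            (["eversion", "flush", "inversion"], 1, "inversion"),
            (["eversion", "inversion"], 2, "inversion"),  # tie → most recent
            (["inversion", "eversion"], 2, "eversion"),
            (["flush"] * 5 + ["eversion"], 4, "flush"),
        ],
    )
    def test_vote(self, labels, k, expected):
        assert majority_vote(labels, k) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([], 1)


class TestSerialization:
    def test_round_trip_predictions_identical(self, tmp_path):
        rng = np.random.default_rng(20)
        X, y = random_instance(rng, p=3, n=80)
        model = fit_lda_arrays(X, y, shrinkage=1e-3)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        Xte = rng.normal(size=(30, 3))
        np.testing.assert_array_equal(predict(model, Xte), predict(back, Xte))
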