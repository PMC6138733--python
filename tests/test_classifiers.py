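import numpy as np
import pytest
from scipy import stats

from aapfuse.classifiers import (
    FusionModel,
    GaussianNB,
    LogisticRegressionIRLS,
    NearestNeighbor,
    select_base_pair,
)


class TestGaussianNB:
    def test_symmetric_classes_give_half(self, rng):
        X = np.vstack([rng.normal(size=(50, 3))] * 2)
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        p = GaussianNB().fit(X, y).predict_proba_pos(X)
        assert np.allclose(p, 0.5)

    def test_separated_1d_posterior(self):
        X = np.array([[0.0], [0.2], [1.0], [1.2]])
        y = np.array([1, 1, 0, 0])
        clf = GaussianNB().fit(X, y)
        assert clf.predict_proba_pos([[0.1]])[0] > 0.99
        assert clf.predict_proba_pos([[1.1]])[0] < 0.01

    def test_constant_feature_defers_to_priors(self):
        X = np.column_stack([np.full(6, 3.0), np.zeros(6)])
        y = np.array([1, 1, 1, 1, 0, 0])
        clf = GaussianNB().fit(X, y)
        assert np.all(clf.vars_ >= clf.variance_floor_)
        p = clf.predict_proba_pos([[3.0, 0.0]])[0]
        assert p == pytest.approx(4 / 6)

    def test_monotone_in_1d(self):
        X = np.array([[0.0], [0.5], [2.0], [2.5]])
        y = np.array([1, 1, 0, 0])
        clf = GaussianNB().fit(X, y)
        grid = np.linspace(0, 2.5, 50)[:, None]
        p = clf.predict_proba_pos(grid)
        assert np.all(np.diff(p) <= 1e-12)

    def test_direct_density_oracle(self, rng):
        """Posterior equals prior-weighted product of per-feature normal
        densities computed independently with scipy.stats.norm."""
        X = rng.normal(size=(30, 2)) + np.where(
            rng.integers(0, 2, size=(30, 1)), 2.0, 0.0
        )
        y = rng.integers(0, 2, size=30)
        while min(np.bincount(y)) < 2:
            y = rng.integers(0, 2, size=30)
        clf = GaussianNB().fit(X, y)
        x = rng.normal(size=2)
        like = [
            np.prod(stats.norm.pdf(x, clf.means_[c], np.sqrt(clf.vars_[c])))
            for c in (0, 1)
        ]
        expected = (clf.priors_[1] * like[1]) / (
            clf.priors_[0] * like[0] + clf.priors_[1] * like[1]
        )
        assert clf.predict_proba_pos(x[None, :])[0] == pytest.approx(
            expected, abs=1e-10
        )

    def test_sklearn_cross_check(self, rng):
        from sklearn.naive_bayes import GaussianNB as SkNB

        X = rng.normal(size=(60, 4)) + np.r_[
            np.zeros((30, 4)), np.full((30, 4), 1.5)
        ]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        ours = GaussianNB().fit(X, y).predict_proba_pos(X)
        theirs = SkNB().fit(X, y).predict_proba(X)[:, 1]
        assert np.allclose(ours, theirs, atol=1e-6)

    def test_determinism_and_errors(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        a, b = GaussianNB().fit(X, y), GaussianNB().fit(X, y)
        assert np.array_equal(a.means_, b.means_)
        assert np.array_equal(a.vars_, b.vars_)
        with pytest.raises(ValueError):
            GaussianNB().fit(X, np.ones(20, int))
        with pytest.raises(ValueError):
            a.predict_proba_pos(np.zeros((2, 5)))


class TestLogisticRegressionIRLS:
    def test_statsmodels_oracle(self, rng):
        """Near-unpenalised IRLS matches an independent ML fit to 1e-6."""
        import statsmodels.api as sm

        X = rng.normal(size=(40, 3))
        logits = 0.5 + X @ np.array([1.0, -2.0, 0.3])
        y = (rng.random(40) < 1 / (1 + np.exp(-logits))).astype(int)
        clf = LogisticRegressionIRLS(ridge=1e-8).fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="newton", tol=1e-12)
        assert np.allclose(clf.weights_, ref.params, atol=1e-6)
        assert clf.converged_

    def test_separable_data_stays_finite(self):
        X = np.array([[0.0], [0.1], [1.0], [1.1]])
        y = np.array([0, 0, 1, 1])
        clf = LogisticRegressionIRLS().fit(X, y)
        assert np.isfinite(clf.weights_).all()
        pred = (clf.predict_proba_pos(X) >= 0.5).astype(int)
        assert np.array_equal(pred, y)

    def test_mirror_symmetric_intercept_is_zero(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        clf = LogisticRegressionIRLS().fit(X, y)
        assert abs(clf.weights_[0]) < 1e-6

    def test_determinism_and_errors(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.r_[np.ones(15, int), np.zeros(15, int)]
        a, b = LogisticRegressionIRLS().fit(X, y), LogisticRegressionIRLS().fit(X, y)
        assert np.array_equal(a.weights_, b.weights_)
        with pytest.raises(ValueError):
            LogisticRegressionIRLS().fit(np.array([[np.nan], [1.0]]), np.array([0, 1]))


class TestNearestNeighbor:
    def test_exact_match_and_tie(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([1, 0])
        clf = NearestNeighbor().fit(X, y)
        assert clf.predict_proba_pos([[0.0]])[0] == 1.0
        # midpoint tie: lowest training index (the positive) wins
        assert clf.predict_proba_pos([[0.5]])[0] == 1.0

    def test_hard_probabilities(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.integers(0, 2, size=10)
        p = NearestNeighbor().fit(X, y).predict_proba_pos(rng.normal(size=(5, 2)))
        assert set(p).issubset({0.0, 1.0})

    def test_exhaustive_scan_oracle(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, size=20)
        clf = NearestNeighbor().fit(X, y)
        for _ in range(25):
            q = rng.normal(size=3)
            dists = [np.linalg.norm(q - x) for x in X]
            assert clf.predict_proba_pos(q[None])[0] == y[int(np.argmin(dists))]

    def test_errors(self):
        with pytest.raises(ValueError):
            NearestNeighbor().fit(np.zeros((0, 2)), np.zeros(0, int))
        clf = NearestNeighbor().fit(np.zeros((2, 2)), np.array([0, 1]))
        with pytest.raises(ValueError):
            clf.predict_proba_pos(np.zeros((1, 3)))


def _toy_fusion(p_a, p_b, threshold=0.5):
    class Fixed:
        def __init__(self, p):
            self.p = p

        def fit(self, X, y):
            return self

        def predict_proba_pos(self, X):
            return np.full(len(np.atleast_2d(X)), self.p)

    return FusionModel(
        base_a=Fixed(p_a), base_b=Fixed(p_b), base_a_name="a", base_b_name="b",
        feature_indices=np.array([0]), feature_names=["f0"], threshold=threshold,
    )


class TestFusion:
    @pytest.mark.parametrize(
        "p_a, p_b, fused, label",
        [(0.8, 0.6, 0.7, 1), (0.3, 0.3, 0.3, 0), (0.5, 0.5, 0.5, 1)],
    )
    def test_average_and_boundary(self, p_a, p_b, fused, label):
        model = _toy_fusion(p_a, p_b)
        p, lab = model.fuse_predict(np.zeros((1, 1)))
        assert p[0] == pytest.approx(fused)
        assert lab[0] == label

    def test_untrained_base_raises(self):
        model = FusionModel(
            base_a=GaussianNB(), base_b=GaussianNB(), base_a_name="nb",
            base_b_name="nb", feature_indices=np.array([0]), feature_names=["f0"],
        )
        with pytest.raises(ValueError):
            model.fuse_predict(np.zeros((1, 1)))

    def test_fusion_dominance_simulation(self):
        """A sensitive base and a specific base fused by averaging score at
        least as well as the weaker of the two on fresh data."""
        rng = np.random.default_rng(7)
        n = 1000
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 1)) + 2.0 * y[:, None]
        train = LogisticRegressionIRLS().fit(X[:500], y[:500])
        sens = LogisticRegressionIRLS()
        spec = LogisticRegressionIRLS()
        sens.weights_ = train.weights_ + np.array([1.5, 0.0])   # liberal: high Sn
        spec.weights_ = train.weights_ - np.array([1.5, 0.0])   # strict: high Sp
        Xt, yt = X[500:], y[500:]

        def acc(clf):
            return np.mean((clf.predict_proba_pos(Xt) >= 0.5).astype(int) == yt)

        sn_a = np.mean(sens.predict_proba_pos(Xt[yt == 1]) >= 0.5)
        sp_b = np.mean(spec.predict_proba_pos(Xt[yt == 0]) < 0.5)
        assert sn_a > 0.9 and sp_b > 0.9  # the intended asymmetry is present
        model = FusionModel(
            base_a=sens, base_b=spec, base_a_name="lr", base_b_name="lr",
            feature_indices=np.array([0]), feature_names=["f0"],
        )
        _, fused_lab = model.fuse_predict(Xt)
        assert np.mean(fused_lab == yt) >= min(acc(sens), acc(spec))

    def test_serialization_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(20, 3))
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        model = FusionModel(
            base_a=LogisticRegressionIRLS().fit(X, y),
            base_b=GaussianNB().fit(X, y),
            base_a_name="lr", base_b_name="nb",
            feature_indices=np.array([0, 1, 2]),
            feature_names=["f0", "f1", "f2"],
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FusionModel.from_json(path)
        p0, _ = model.fuse_predict(X)
        p1, _ = back.fuse_predict(X)
        assert np.allclose(p0, p1, atol=0)


class TestSelectBasePair:
    def test_benchmark_style_candidates(self):
        # best sensitivity -> LR, best specificity -> NB
        pair = select_base_pair([("nb", 0.682, 0.925), ("lr", 0.785, 0.748)])
        assert pair == ("lr", "nb")

    def test_dominant_candidate_pairs_with_runner_up(self):
        pair = select_base_pair(
            [("a", 0.9, 0.9), ("b", 0.5, 0.8), ("c", 0.6, 0.4)]
        )
        assert pair == ("a", "b")

    def test_tie_goes_to_first_listed(self):
        pair = select_base_pair([("a", 0.7, 0.5), ("b", 0.7, 0.9)])
        assert pair == ("a", "b")

    def test_needs_two_candidates(self):
        with pytest.raises(ValueError):
            select_base_pair([("a", 0.5, 0.5)])
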