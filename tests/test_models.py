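import numpy as np
import pytest

from promoterbench.features import FeatureMatrix, encode
from promoterbench.models import (
    MetaModel,
    ScoreVector,
    meta_predict,
    save_model,
    load_model,
    train_naive_bayes,
    train_predictor,
    train_profile_hmm,
    train_random_forest,
    train_svm,
)
from promoterbench.negatives import generate_random_negatives
from promoterbench.synthetic import make_synthetic_promoters

from conftest import make_set, random_window


def _nominal_toy(n_pos=10, n_neg=10):
    """One nominal attribute: positives all 'A', negatives all 'C'."""
    values = np.array([["A"]] * n_pos + [["C"]] * n_neg, dtype="<U1")
    return FeatureMatrix(
        values=values,
        feature_names=["x1"],
        encoding_tag="toy",
        labels=np.array([1] * n_pos + [0] * n_neg),
        categories=[tuple("ACGT")],
    )


def _query(symbols):
    return FeatureMatrix(
        values=np.array([[s] for s in symbols], dtype="<U1"),
        feature_names=["x1"],
        encoding_tag="toy",
        categories=[tuple("ACGT")],
    )


class TestNaiveBayes:
    def test_separable_toy_classified_correctly(self):
        model = train_naive_bayes(_nominal_toy())
        p = model.predict_proba(_query(["A", "C"]))
        assert p[0] > 0.5 > p[1]

    def test_laplace_smoothed_posterior_hand_value(self):
        # n+ = n- = 10, alpha = 1, 4 categories:
        # P(A|1) = 11/14, P(A|0) = 1/14, posterior for 'A' = 11/12
        model = train_naive_bayes(_nominal_toy(10, 10), alpha=1.0)
        table = model.nominal_tables[0]
        cats = model.categories[0]
        assert table[1, cats.index("A")] == pytest.approx(11 / 14)
        assert table[0, cats.index("A")] == pytest.approx(1 / 14)
        p = model.predict_proba(_query(["A"]))
        assert p[0] == pytest.approx(11 / 12)

    def test_attribute_order_irrelevant(self, rng):
        seqs = [random_window(rng, 12) for _ in range(40)]
        labels = np.array([1] * 20 + [0] * 20)
        m = encode(make_set(seqs), "DNID")
        m.labels = labels
        perm = rng.permutation(m.d)
        m_perm = FeatureMatrix(
            values=m.values[:, perm],
            feature_names=[m.feature_names[j] for j in perm],
            encoding_tag="DNID",
            labels=labels,
            categories=[m.categories[j] for j in perm],
        )
        a = train_naive_bayes(m).predict_proba(m)
        b = train_naive_bayes(m_perm).predict_proba(m_perm)
        assert np.allclose(a, b)

    def test_duplicating_training_set_invariant_as_alpha_vanishes(self):
        base = _nominal_toy(8, 8)
        doubled = FeatureMatrix(
            values=np.vstack([base.values, base.values]),
            feature_names=base.feature_names,
            encoding_tag="toy",
            labels=np.concatenate([base.labels, base.labels]),
            categories=base.categories,
        )
        q = _query(["A", "C"])
        tiny = 1e-9
        a = train_naive_bayes(base, alpha=tiny).predict_proba(q)
        b = train_naive_bayes(doubled, alpha=tiny).predict_proba(q)
        assert np.allclose(a, b, atol=1e-6)

    def test_gaussian_branch_on_numeric_features(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(3, 1, (30, 3))])
        m = FeatureMatrix(
            values=X, feature_names=list("abc"), encoding_tag="num",
            labels=np.array([0] * 30 + [1] * 30),
        )
        model = train_naive_bayes(m)
        p = model.predict_proba(m)
        assert (p[:30] < 0.5).mean() > 0.9 and (p[30:] > 0.5).mean() > 0.9

    def test_single_class_training_rejected(self):
        m = _nominal_toy(10, 10)
        with pytest.raises(ValueError, match="both classes"):
            train_naive_bayes(m, y=np.ones(20, dtype=int))


class TestRandomForest:
    def _numeric_toy(self):
        values = np.array([[0.0, 0.0], [1.0, 1.0]])
        return FeatureMatrix(
            values=values, feature_names=["a", "b"], encoding_tag="num",
            labels=np.array([0, 1]),
        )

    def test_single_tree_memorizes_separable_points(self):
        m = self._numeric_toy()
        model = train_random_forest(m, n_trees=1, seed=0)
        p = model.predict_proba(m)
        assert p[0] < 0.5 < p[1]

    def test_probabilities_on_vote_grid(self, rng):
        k = 7
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] > 0).astype(int)
        m = FeatureMatrix(values=X, feature_names=[f"f{i}" for i in range(5)],
                          encoding_tag="num", labels=y)
        model = train_random_forest(m, n_trees=k, seed=1)
        p = model.predict_proba(m)
        grid = np.arange(k + 1) / k
        assert np.all(np.isclose(p[:, None], grid[None, :], atol=1e-12).any(axis=1))

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(40, 6))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        m = FeatureMatrix(values=X, feature_names=[f"f{i}" for i in range(6)],
                          encoding_tag="num", labels=y)
        a = train_random_forest(m, seed=5).predict_proba(m)
        b = train_random_forest(m, seed=5).predict_proba(m)
        assert np.array_equal(a, b)

    def test_nominal_input_directed_to_codification(self):
        with pytest.raises(ValueError, match="orthogonal_codify"):
            train_random_forest(_nominal_toy())

    def test_invalid_tree_count(self):
        with pytest.raises(ValueError):
            train_random_forest(self._numeric_toy(), n_trees=0)


class TestSVM:
    def test_linear_kernel_separates_separable_toy(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, (20, 2)), rng.normal(2, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        m = FeatureMatrix(values=X, feature_names=["a", "b"],
                          encoding_tag="num", labels=y)
        model = train_svm(m, kernel="linear")
        p = model.predict_proba(m)
        assert np.all((p >= 0.5) == (y == 1))

    def test_rbf_solves_xor_linear_cannot(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]] * 10, dtype=float)
        y = np.array([0, 0, 1, 1] * 10)
        m = FeatureMatrix(values=X, feature_names=["a", "b"],
                          encoding_tag="num", labels=y)
        rbf = train_svm(m, kernel="rbf", gamma=2.0)
        p_rbf = (rbf.predict_proba(m) >= 0.5).astype(int)
        assert np.array_equal(p_rbf, y)
        lin = train_svm(m, kernel="linear")
        p_lin = (lin.predict_proba(m) >= 0.5).astype(int)
        assert np.mean(p_lin == y) < 1.0

    def test_scores_invariant_to_row_order(self, rng):
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(int)
        m = FeatureMatrix(values=X, feature_names=list("abcd"),
                          encoding_tag="num", labels=y)
        model = train_svm(m, kernel="rbf")
        perm = rng.permutation(30)
        m_perm = m.select_rows(perm)
        assert np.allclose(model.predict_proba(m_perm),
                           model.predict_proba(m)[perm])

    def test_invalid_cost(self, rng):
        with pytest.raises(ValueError):
            train_svm(_nominal_toy(), cost=-1)


class TestProfileHMM:
    def test_emission_rows_sum_to_one(self, rng):
        pos = make_set([random_window(rng, 30) for _ in range(20)], label=1)
        model = train_profile_hmm(pos)
        assert np.allclose(model.emissions.sum(axis=1), 1.0)

    def test_consensus_maximizes_score(self, rng):
        w = random_window(rng, 25)
        pos = make_set([w] * 15, label=1)
        model = train_profile_hmm(pos)
        consensus_score = model.log_odds(w)
        for _ in range(50):
            assert model.log_odds(random_window(rng, 25)) <= consensus_score

    def test_separates_motif_from_background(self):
        pos = make_synthetic_promoters(200, seed=1)
        neg = generate_random_negatives(200, seed=2)
        model = train_profile_hmm(pos.relabel(1))
        s_pos = model.score_set(make_synthetic_promoters(100, seed=3)).scores
        s_neg = model.score_set(generate_random_negatives(100, seed=4)).scores
        assert np.median(s_pos) > np.median(s_neg)

    def test_empty_training_set_rejected(self):
        from promoterbench.seqio import SequenceSet

        with pytest.raises(ValueError, match="empty"):
            train_profile_hmm(SequenceSet(name="none", records=[]))

    def test_scores_in_unit_interval(self, rng):
        pos = make_set([random_window(rng, 20) for _ in range(10)], label=1)
        model = train_profile_hmm(pos)
        s = model.score_set(make_set([random_window(rng, 20) for _ in range(5)]))
        assert np.all((s.scores >= 0) & (s.scores <= 1))


class TestMetaPredictor:
    class _Const:
        def __init__(self, value, model_id="const"):
            self.value = value
            from promoterbench.models import ModelSpec

            self.spec = ModelSpec("nb", "DNID")
            self._id = model_id

        def score_set(self, sset):
            return ScoreVector(np.full(len(sset), self.value), self._id, sset.name)

    def test_identical_components_idempotent(self, small_set):
        meta = meta_predict(self._Const(0.7), self._Const(0.7), small_set)
        assert np.allclose(meta.scores, 0.7)

    def test_midpoint_of_extremes(self, small_set):
        meta = meta_predict(self._Const(1.0), self._Const(0.0), small_set)
        assert np.allclose(meta.scores, 0.5)

    def test_bounded_by_components(self, rng, small_set):
        class Jitter:
            def __init__(self, base, seed):
                from promoterbench.models import ModelSpec

                self.spec = ModelSpec("nb", "DNID")
                self.base, self.seed = base, seed

            def score_set(self, sset):
                r = np.random.default_rng(self.seed)
                return ScoreVector(
                    np.clip(self.base + r.normal(0, 0.1, len(sset)), 0, 1),
                    "j", sset.name,
                )

        a, b = Jitter(0.4, 1), Jitter(0.6, 2)
        sa, sb = a.score_set(small_set).scores, b.score_set(small_set).scores
        meta = meta_predict(a, b, small_set).scores
        assert np.all(meta >= np.minimum(sa, sb) - 1e-12)
        assert np.all(meta <= np.maximum(sa, sb) + 1e-12)

    def test_end_to_end_meta_model(self):
        pos = make_synthetic_promoters(150, seed=1)
        neg = generate_random_negatives(150, seed=2)
        nb = train_predictor(pos, neg, "nb", "DNID")
        rf = train_predictor(pos, neg, "rf", "struct:M7", seed=0)
        meta = MetaModel(nb, rf)
        test = make_synthetic_promoters(50, seed=9)
        s = meta.score_set(test)
        assert len(s) == 50 and np.all((s.scores >= 0) & (s.scores <= 1))


class TestPersistence:
    def test_nb_round_trip(self, tmp_path):
        model = train_naive_bayes(_nominal_toy())
        save_model(model, tmp_path / "nb.json")
        back = load_model(tmp_path / "nb.json")
        q = _query(["A", "C", "G"])
        assert np.allclose(model.predict_proba(q), back.predict_proba(q))

    def test_hmm_round_trip(self, tmp_path, rng):
        pos = make_set([random_window(rng, 15) for _ in range(10)], label=1)
        model = train_profile_hmm(pos)
        save_model(model, tmp_path / "hmm.json")
        back = load_model(tmp_path / "hmm.json")
        probe = make_set([random_window(rng, 15) for _ in range(4)])
        assert np.allclose(model.score_set(probe).scores,
                           back.score_set(probe).scores)

    def test_sklearn_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(int)
        m = FeatureMatrix(values=X, feature_names=list("abcd"),
                          encoding_tag="num", labels=y)
        model = train_random_forest(m, n_trees=10, seed=3)
        save_model(model, tmp_path / "rf.json")
        back = load_model(tmp_path / "rf.json")
        assert np.allclose(model.predict_proba(m), back.predict_proba(m))
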