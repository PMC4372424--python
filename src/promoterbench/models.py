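"""Classifiers over promoter feature matrices.

The Naive Bayes decision rule classifies a window as promoter when the
posterior ratio P(C=1|X)/P(C=0|X) >= 1 under the attribute-independence
factorization: nominal attributes use Laplace-smoothed (alpha=1) category
frequencies, numeric attributes use Gaussian class-conditional densities.
Random forest (100 trees, per-split subspace of ceil(sqrt(M)) features) and
SVM (linear / RBF) are delegated to scikit-learn behind the same scoring
interface.  A fixed-length profile HMM scores raw windows by log-odds
against an i.i.d. background, and the meta-predictor averages the promoter
probabilities of two base models (the paper's NB_DNID + RF100_M7 combiner).
"""

from __future__ import annotations

import base64
import json
import math
import pickle
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import features as F
from .features import FeatureMatrix
from .seqio import SequenceSet, concat_sets

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm id + encoding tag + hyperparameters + seed."""

    algorithm: str  # nb | rf | svm_linear | svm_rbf | hmm | meta
    encoding_tag: str  # e.g. "DNID", "kmer:4", "struct:M7:w3"; "seq" for hmm
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def id(self) -> str:
        alg = {
            "nb": "NB",
            "rf": f"RF{self.hyperparams.get('n_trees', 100)}",
            "svm_linear": "SVMLnr",
            "svm_rbf": "SVMRBF",
            "hmm": "HMM",
            "meta": "meta",
        }.get(self.algorithm, self.algorithm)
        enc = self.encoding_tag.replace("struct:", "").split(":w")[0]
        if self.algorithm == "hmm":
            return "HMM"
        kmap = {"kmer:1": "1-mer", "kmer:2": "2-mer", "kmer:3": "3-mer",
                "kmer:4": "4-mer", "kmer:5": "5-mer"}
        enc = kmap.get(self.encoding_tag, enc)
        return f"{alg}_{enc}"


@dataclass
class ScoreVector:
    """Per-sequence promoter scores in [0, 1] for one model on one set."""

    scores: np.ndarray
    model_id: str
    set_name: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be a 1-D vector")

    def __len__(self) -> int:
        return len(self.scores)


class TrainedModel:
    """Base: a fitted model that scores feature matrices and sequence sets."""

    spec: ModelSpec

    def predict_proba(self, X: FeatureMatrix) -> np.ndarray:
        raise NotImplementedError

    def score_set(self, sset: SequenceSet) -> ScoreVector:
        X = F.encode(sset, self.spec.encoding_tag)
        return ScoreVector(self.predict_proba(X), self.spec.id, sset.name)


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            f"training labels must contain both classes 0 and 1, got {classes}"
        )
    return y


class NaiveBayesModel(TrainedModel):
    """Naive Bayes with Laplace-smoothed nominal or Gaussian numeric terms."""

    def __init__(self, spec, priors, nominal_tables, gaussian_params, categories):
        self.spec = spec
        self.log_priors = np.log(priors)
        self.nominal_tables = nominal_tables  # list of (2, c) prob arrays, or None
        self.gaussian_params = gaussian_params  # (2, d) means, (2, d) vars, or None
        self.categories = categories

    def predict_proba(self, X: FeatureMatrix) -> np.ndarray:
        n = X.n
        log_post = np.tile(self.log_priors, (n, 1))  # (n, 2)
        if self.nominal_tables is not None:
            for j, table in enumerate(self.nominal_tables):
                cat_index = {c: t for t, c in enumerate(self.categories[j])}
                idx = np.array([cat_index[v] for v in X.values[:, j]])
                log_post += np.log(table[:, idx]).T
        else:
            means, variances = self.gaussian_params
            for c in (0, 1):
                z = (X.values.astype(float) - means[c]) ** 2 / variances[c]
                log_post[:, c] += -0.5 * np.sum(
                    z + np.log(2 * np.pi * variances[c]), axis=1
                )
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        post /= post.sum(axis=1, keepdims=True)
        return post[:, 1]


def train_naive_bayes(
    X: FeatureMatrix,
    y: Optional[np.ndarray] = None,
    alpha: float = 1.0,
) -> NaiveBayesModel:
    """Fit the NB decision rule.  ``alpha`` is the Laplace pseudo-count for
    nominal attributes; numeric attributes get Gaussian class densities."""
    y = _check_two_classes(X.labels if y is None else y)
    priors = np.array([(y == 0).mean(), (y == 1).mean()])
    spec = ModelSpec("nb", X.encoding_tag, {"alpha": alpha})
    if X.is_nominal:
        tables = []
        for j, cats in enumerate(X.categories):
            table = np.empty((2, len(cats)))
            for c in (0, 1):
                col = X.values[y == c, j]
                counts = np.array([(col == cat).sum() for cat in cats], dtype=float)
                table[c] = (counts + alpha) / (counts.sum() + alpha * len(cats))
            tables.append(table)
        return NaiveBayesModel(spec, priors, tables, None, X.categories)
    Xv = X.values.astype(float)
    means = np.stack([Xv[y == c].mean(axis=0) for c in (0, 1)])
    variances = np.stack([Xv[y == c].var(axis=0) for c in (0, 1)])
    # variance floor keeps constant features from producing degenerate densities
    floor = 1e-9 * max(Xv.var(axis=0).max(), 1e-12)
    variances = np.maximum(variances, floor)
    return NaiveBayesModel(spec, priors, None, (means, variances), None)


class SklearnModel(TrainedModel):
    """Adapter giving sklearn estimators the TrainedModel scoring contract."""

    def __init__(self, spec: ModelSpec, estimator, use_decision: bool = False):
        self.spec = spec
        self.estimator = estimator
        self.use_decision = use_decision

    def predict_proba(self, X: FeatureMatrix) -> np.ndarray:
        if X.is_nominal:
            raise ValueError(
                "numeric features required; apply orthogonal_codify first"
            )
        Xv = X.values.astype(float)
        if self.use_decision:
            # monotone logistic map of the signed decision value; rank-based
            # metrics (AUC) are unaffected by the choice of map
            return 1.0 / (1.0 + np.exp(-self.estimator.decision_function(Xv)))
        return self.estimator.predict_proba(Xv)[:, 1]


def train_random_forest(
    X: FeatureMatrix,
    y: Optional[np.ndarray] = None,
    n_trees: int = 100,
    seed: int = 0,
) -> SklearnModel:
    """Random forest of ``n_trees`` fully grown trees, bootstrap samples,
    per-split random subspace of m = ceil(sqrt(M)) features."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if X.is_nominal:
        raise ValueError("numeric features required; apply orthogonal_codify first")
    y = _check_two_classes(X.labels if y is None else y)
    m = math.ceil(math.sqrt(X.d))
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=m,
        bootstrap=True,
        random_state=seed,
    )
    est.fit(X.values.astype(float), y)
    spec = ModelSpec("rf", X.encoding_tag, {"n_trees": n_trees, "m": m}, seed)
    return SklearnModel(spec, est)


def train_svm(
    X: FeatureMatrix,
    y: Optional[np.ndarray] = None,
    kernel: str = "linear",
    cost: float = 1.0,
    gamma: float | str = "auto",
) -> SklearnModel:
    """Maximum-margin classifier with linear or RBF kernel; the ranking
    score is the signed decision value mapped monotonically to [0, 1]."""
    if kernel not in ("linear", "rbf"):
        raise ValueError("kernel must be 'linear' or 'rbf'")
    if cost <= 0:
        raise ValueError("cost must be positive")
    if X.is_nominal:
        raise ValueError("numeric features required; apply orthogonal_codify first")
    y = _check_two_classes(X.labels if y is None else y)
    est = SVC(kernel=kernel, C=cost, gamma=gamma)
    est.fit(X.values.astype(float), y)
    spec = ModelSpec(
        f"svm_{kernel}", X.encoding_tag, {"cost": cost, "gamma": gamma}
    )
    return SklearnModel(spec, est, use_decision=True)


class ProfileHMMModel(TrainedModel):
    """Fixed-length profile HMM with match/insert/delete architecture.

    Training windows are fixed-length and ungapped, so after iterative
    re-estimation virtually all probability mass sits on the all-match path;
    insert/delete transitions are retained structurally with small
    probabilities.  The score of a query is the log-odds of the match-path
    likelihood against an i.i.d. background estimated from the pooled base
    frequencies of the training positives, squashed through a logistic to
    [0, 1] (monotone, so threshold-free metrics are unaffected).
    """

    def __init__(self, spec, emissions, background, gap_prob):
        self.spec = spec
        self.emissions = emissions  # (L, 4) row-stochastic
        self.background = background  # (4,)
        self.gap_prob = gap_prob  # residual insert/delete transition mass
        self._base_index = {b: i for i, b in enumerate("ACGT")}

    def log_odds(self, sequence: str) -> float:
        idx = [self._base_index[b] for b in sequence]
        score = sum(
            math.log(self.emissions[i, j] / self.background[j])
            for i, j in enumerate(idx)
        )
        # all-match transition mass; constant per model, kept for completeness
        score += len(idx) * math.log(1.0 - 2.0 * self.gap_prob)
        return score

    def score_set(self, sset: SequenceSet) -> ScoreVector:
        raw = np.array([self.log_odds(r.residues) for r in sset])
        return ScoreVector(1.0 / (1.0 + np.exp(-raw)), self.spec.id, sset.name)

    def predict_proba(self, X: FeatureMatrix) -> np.ndarray:
        raise ValueError("the profile HMM scores sequence sets, not matrices")


def train_profile_hmm(
    positives: SequenceSet,
    pseudocount: float = 1.0,
    gap_prob: float = 0.01,
    tol: float = 1e-9,
    max_iter: int = 20,
) -> ProfileHMMModel:
    """Fit a length-L profile to the positive windows.

    Match emissions are position-specific smoothed base frequencies; the
    re-estimation loop (expected counts under the current model, ungapped
    alignment) is run to log-likelihood convergence — with fixed-length
    training data it converges immediately, which the loop verifies.
    """
    if len(positives) == 0:
        raise ValueError("cannot train a profile on an empty set")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    L = positives.window_length
    base_index = {b: i for i, b in enumerate("ACGT")}
    obs = np.array(
        [[base_index[b] for b in rec.residues] for rec in positives], dtype=int
    )
    counts = np.zeros((L, 4))
    for j in range(L):
        counts[j] = np.bincount(obs[:, j], minlength=4)
    emissions = (counts + pseudocount) / (len(positives) + 4 * pseudocount)
    pooled = counts.sum(axis=0) + pseudocount
    background = pooled / pooled.sum()

    prev_ll = -np.inf
    for _ in range(max_iter):
        log_e = np.log(emissions)
        ll = sum(log_e[np.arange(L), row].sum() for row in obs)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
        # expected emission counts under the (single) ungapped path
        counts = np.zeros((L, 4))
        for j in range(L):
            counts[j] = np.bincount(obs[:, j], minlength=4)
        emissions = (counts + pseudocount) / (len(positives) + 4 * pseudocount)

    spec = ModelSpec("hmm", "seq", {"pseudocount": pseudocount, "gap_prob": gap_prob})
    return ProfileHMMModel(spec, emissions, background, gap_prob)


class MetaModel(TrainedModel):
    """Average-of-probabilities combiner of two base models."""

    def __init__(self, model_a: TrainedModel, model_b: TrainedModel):
        self.model_a = model_a
        self.model_b = model_b
        self.spec = ModelSpec(
            "meta",
            f"{model_a.spec.encoding_tag}+{model_b.spec.encoding_tag}",
            {"components": [model_a.spec.id, model_b.spec.id]},
        )

    def score_set(self, sset: SequenceSet) -> ScoreVector:
        return meta_predict(self.model_a, self.model_b, sset)

    def predict_proba(self, X: FeatureMatrix) -> np.ndarray:
        raise ValueError("the meta-predictor scores sequence sets, not matrices")


def meta_predict(
    model_a: TrainedModel, model_b: TrainedModel, sset: SequenceSet
) -> ScoreVector:
    """score_i = (p_a,i + p_b,i) / 2, each model using its own encoding."""
    sa = model_a.score_set(sset)
    sb = model_b.score_set(sset)
    if len(sa) != len(sb):
        raise ValueError("component models scored different set sizes")
    return ScoreVector(
        (sa.scores + sb.scores) / 2.0,
        f"meta({sa.model_id},{sb.model_id})",
        sset.name,
    )


def train_predictor(
    pos: SequenceSet,
    neg: SequenceSet,
    algorithm: str,
    encoding_tag: str = "DNID",
    seed: int = 0,
    **hyper,
) -> TrainedModel:
    """Convenience front end: label, pool, encode and dispatch to a trainer.

    ``algorithm``: nb | rf | svm_linear | svm_rbf | hmm.  For nominal
    encodings the RF/SVM trainers receive the orthogonal codification
    automatically (tag ``<enc>:onehot``).
    """
    pos = pos.relabel(1)
    neg = neg.relabel(0)
    if algorithm == "hmm":
        return train_profile_hmm(pos, **hyper)
    combined = concat_sets(f"{pos.name}+{neg.name}", [pos, neg])
    needs_numeric = algorithm in ("rf", "svm_linear", "svm_rbf")
    tag = encoding_tag
    if needs_numeric and tag in ("NID", "DNID"):
        tag = f"{tag}:onehot"
    X = F.encode(combined, tag)
    if algorithm == "nb":
        return train_naive_bayes(X, **hyper)
    if algorithm == "rf":
        return train_random_forest(X, seed=seed, **hyper)
    if algorithm == "svm_linear":
        return train_svm(X, kernel="linear", **hyper)
    if algorithm == "svm_rbf":
        return train_svm(X, kernel="rbf", **hyper)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def save_model(model: TrainedModel, path) -> None:
    """Persist a model as versioned JSON (spec + fitted parameters)."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "spec": {
            "algorithm": model.spec.algorithm,
            "encoding_tag": model.spec.encoding_tag,
            "hyperparams": model.spec.hyperparams,
            "seed": model.spec.seed,
        },
    }
    if isinstance(model, NaiveBayesModel):
        payload["parameters"] = {
            "log_priors": model.log_priors.tolist(),
            "nominal_tables": None
            if model.nominal_tables is None
            else [t.tolist() for t in model.nominal_tables],
            "gaussian_params": None
            if model.gaussian_params is None
            else [a.tolist() for a in model.gaussian_params],
            "categories": model.categories,
        }
    elif isinstance(model, ProfileHMMModel):
        payload["parameters"] = {
            "emissions": model.emissions.tolist(),
            "background": model.background.tolist(),
            "gap_prob": model.gap_prob,
        }
    elif isinstance(model, SklearnModel):
        blob = base64.b64encode(pickle.dumps(model.estimator)).decode("ascii")
        payload["parameters"] = {
            "sklearn_pickle_b64": blob,
            "use_decision": model.use_decision,
        }
    else:
        raise ValueError(f"cannot serialize model of type {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    spec = ModelSpec(**payload["spec"])
    params = payload["parameters"]
    if spec.algorithm == "nb":
        return NaiveBayesModel(
            spec,
            np.exp(np.array(params["log_priors"])),
            None
            if params["nominal_tables"] is None
            else [np.array(t) for t in params["nominal_tables"]],
            None
            if params["gaussian_params"] is None
            else tuple(np.array(a) for a in params["gaussian_params"]),
            None
            if params["categories"] is None
            else [tuple(c) for c in params["categories"]],
        )
    if spec.algorithm == "hmm":
        return ProfileHMMModel(
            spec,
            np.array(params["emissions"]),
            np.array(params["background"]),
            params["gap_prob"],
        )
    est = pickle.loads(base64.b64decode(params["sklearn_pickle_b64"]))
    return SklearnModel(spec, est, use_decision=params["use_decision"])
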