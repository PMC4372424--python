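"""Threshold metrics, ROC/AUC, AUC grading, repeated CV and train/test grids.

AUC is computed by midrank (Mann-Whitney) counting — the probability that a
random positive outranks a random negative, ties counting one half — and is
therefore invariant under any strictly monotone rescaling of scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .models import ScoreVector, TrainedModel, train_predictor
from .seqio import SequenceSet


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class ROCResult:
    points: list[tuple[float, float]]  # (FPR, TPR), (0,0) .. (1,1)
    auc: float


@dataclass
class EvalRecord:
    model_id: str
    train_set: str
    test_set: str  # or "CV"
    metrics: dict[str, float]
    cv_config: Optional[dict] = None
    per_run: list[float] = field(default_factory=list)


def _scores_labels(
    scores: ScoreVector | np.ndarray, labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    s = scores.scores if isinstance(scores, ScoreVector) else np.asarray(scores, float)
    y = np.asarray(labels, dtype=int)
    if len(s) != len(y):
        raise ValueError(f"scores ({len(s)}) and labels ({len(y)}) differ in length")
    return s, y


def confusion(
    scores: ScoreVector | np.ndarray, labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Counts at a threshold; score >= threshold predicts promoter."""
    s, y = _scores_labels(scores, labels)
    pred = s >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        FP=int(np.sum(pred & (y == 0))),
        TN=int(np.sum(~pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def metrics(c: ConfusionCounts) -> dict[str, Optional[float]]:
    """ACC, Sn, Sp and MCC from a confusion table.

    A metric whose denominator vanishes is reported as None (and MCC as 0.0
    with the ``MCC_degenerate`` flag set) rather than raising.
    """
    out: dict[str, Optional[float]] = {}
    out["ACC"] = (c.TP + c.TN) / c.total if c.total else None
    out["Sn"] = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else None
    out["Sp"] = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else None
    denom = (
        (c.TN + c.FN) * (c.TN + c.FP) * (c.TP + c.FN) * (c.TP + c.FP)
    )
    if denom == 0:
        out["MCC"] = 0.0
        out["MCC_degenerate"] = True
    else:
        out["MCC"] = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom)
        out["MCC_degenerate"] = False
    return out


def auc_score(scores: ScoreVector | np.ndarray, labels: Sequence[int]) -> float:
    """Mann-Whitney AUC via midranks; ties contribute 1/2."""
    s, y = _scores_labels(scores, labels)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties at exactly 1/2 credit
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores: ScoreVector | np.ndarray, labels: Sequence[int]) -> ROCResult:
    """ROC curve over all distinct thresholds plus the midrank AUC."""
    s, y = _scores_labels(scores, labels)
    auc = auc_score(s, y)  # midrank counting, not trapezoid-of-curve
    fpr, tpr, _ = roc_curve(y, s)
    return ROCResult(points=list(zip(fpr.tolist(), tpr.tolist())), auc=auc)


#: AUC grading bands; the sub-0.5 "Fail" band extends the published table
GRADE_BANDS = (
    (0.90, "Excellent"),
    (0.80, "Good"),
    (0.70, "Fair"),
    (0.50, "Poor"),
)


def grade_auc(auc: float) -> str:
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must be in [0, 1], got {auc}")
    for lo, grade in GRADE_BANDS:
        if auc >= lo:
            return grade
    return "Fail"


TrainerFn = Callable[[SequenceSet, SequenceSet], TrainedModel]


def make_trainer(
    algorithm: str, encoding_tag: str = "DNID", seed: int = 0, **hyper
) -> TrainerFn:
    """Bind a (pos, neg) -> TrainedModel factory for CV and grid runs."""

    def fit(pos: SequenceSet, neg: SequenceSet) -> TrainedModel:
        return train_predictor(pos, neg, algorithm, encoding_tag, seed=seed, **hyper)

    fit.algorithm = algorithm  # type: ignore[attr-defined]
    fit.encoding_tag = encoding_tag  # type: ignore[attr-defined]
    return fit


def _subset(sset: SequenceSet, idx: np.ndarray, name: str) -> SequenceSet:
    return SequenceSet(
        name=name,
        records=[sset[int(i)] for i in idx],
        window_length=sset.window_length,
    )


def repeated_cv(
    trainer: TrainerFn,
    pos: SequenceSet,
    neg: SequenceSet,
    k: int = 10,
    runs: int = 10,
    seed: int = 0,
    pool_scores: bool = True,
    stratified: bool = True,
    model_id: Optional[str] = None,
) -> EvalRecord:
    """Average AUC over ``runs`` repetitions of stratified k-fold CV.

    Per run, either all held-out scores are pooled into a single AUC
    (default) or per-fold AUCs are averaged (``pool_scores=False``); the
    reported AUC is the mean over runs, with per-run values retained.
    With ``stratified=False`` and k equal to the total instance count the
    procedure is leave-one-out (pooled scoring only, since a singleton
    fold carries one class).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if stratified and (len(pos) < k or len(neg) < k):
        raise ValueError(f"need >= {k} records per class for stratified {k}-fold CV")
    labels = np.array([1] * len(pos) + [0] * len(neg))
    run_aucs = []
    fitted_id = model_id
    for run in range(runs):
        if stratified:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + run)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed + run)
        pooled_scores, pooled_labels, fold_aucs = [], [], []
        for train_idx, test_idx in splitter.split(np.zeros(len(labels)), labels):
            tr_pos = train_idx[train_idx < len(pos)]
            tr_neg = train_idx[train_idx >= len(pos)] - len(pos)
            te_pos = test_idx[test_idx < len(pos)]
            te_neg = test_idx[test_idx >= len(pos)] - len(pos)
            model = trainer(
                _subset(pos, tr_pos, pos.name), _subset(neg, tr_neg, neg.name)
            )
            if fitted_id is None:
                fitted_id = model.spec.id
            held = SequenceSet(
                name="heldout",
                records=[pos[int(i)] for i in te_pos] + [neg[int(i)] for i in te_neg],
                window_length=pos.window_length,
            )
            sv = model.score_set(held)
            fold_labels = [1] * len(te_pos) + [0] * len(te_neg)
            if pool_scores:
                pooled_scores.extend(sv.scores.tolist())
                pooled_labels.extend(fold_labels)
            else:
                fold_aucs.append(auc_score(sv.scores, fold_labels))
        run_aucs.append(
            auc_score(np.array(pooled_scores), pooled_labels)
            if pool_scores
            else float(np.mean(fold_aucs))
        )
    return EvalRecord(
        model_id=fitted_id or "model",
        train_set=f"{pos.name}+{neg.name}",
        test_set="CV",
        metrics={"AUC": float(np.mean(run_aucs))},
        cv_config={"k": k, "runs": runs, "seed": seed, "pooled": pool_scores},
        per_run=run_aucs,
    )


def evaluate_on(
    model: TrainedModel, pos: SequenceSet, neg: SequenceSet, threshold: float = 0.5
) -> EvalRecord:
    """Score a trained model on a labeled test pair; AUC plus threshold metrics."""
    test = SequenceSet(
        name=f"{pos.name}+{neg.name}",
        records=list(pos) + list(neg),
        window_length=pos.window_length,
    )
    labels = [1] * len(pos) + [0] * len(neg)
    sv = model.score_set(test)
    m = metrics(confusion(sv, labels, threshold))
    m["AUC"] = auc_score(sv, labels)
    return EvalRecord(
        model_id=model.spec.id,
        train_set="(pretrained)",
        test_set=test.name,
        metrics=m,
    )


def train_test_grid(
    trainers: dict[str, TrainerFn],
    train_sets: dict[str, tuple[SequenceSet, SequenceSet]],
    test_sets: dict[str, tuple[SequenceSet, SequenceSet]],
) -> pd.DataFrame:
    """AUC for every (model, train pair, test pair) triple.

    Returns a tidy frame (model, train, test, auc).  Use
    :func:`grid_table` to pivot one model into the printed layout with
    Average/STD margin rows.
    """
    if not trainers or not train_sets or not test_sets:
        raise ValueError("trainers, train_sets and test_sets must be non-empty")
    rows = []
    for model_name, trainer in trainers.items():
        for train_name, (tr_pos, tr_neg) in train_sets.items():
            model = trainer(tr_pos, tr_neg)
            for test_name, (te_pos, te_neg) in test_sets.items():
                rec = evaluate_on(model, te_pos, te_neg)
                rows.append(
                    {
                        "model": model_name,
                        "train": train_name,
                        "test": test_name,
                        "auc": rec.metrics["AUC"],
                    }
                )
    return pd.DataFrame(rows)


def grid_table(tidy: pd.DataFrame, model: str) -> pd.DataFrame:
    """Pivot one model's grid to train x test AUCs with Average/STD rows.

    STD is the population standard deviation down each test column,
    matching the printed convention of summarizing per-column spread.
    """
    sub = tidy[tidy["model"] == model]
    table = sub.pivot(index="train", columns="test", values="auc")
    table.loc["Average"] = table.mean(axis=0)
    table.loc["STD"] = table.drop(index="Average").std(axis=0, ddof=0)
    return table


def write_tidy_tsv(tidy: pd.DataFrame, path) -> None:
    tidy.to_csv(path, sep="\t", index=False)
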