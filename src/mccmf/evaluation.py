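"""Pairs-mode cross-validation and ranking metrics.

Pairs-mode CV masks known association *pairs* (never whole rows or columns):
each repeat partitions the positive entries of MD into folds of near-equal
size, zeros one fold out, re-runs the entire pipeline — GIP kernels,
similarity integration, WKNKN and CMF — on the masked matrix only, and ranks
the held-out pairs against every pair that is 0 in the full matrix. The AUC
uses the rank-based (Mann-Whitney) formulation with ties counted 1/2, which
equals the trapezoidal area under the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from ._types import AssociationMatrix, DiseaseDAGCollection, SimilarityMatrix

__all__ = [
    "CvPlan",
    "MetricsReport",
    "make_cv_plan",
    "rank_auc",
    "threshold_metrics",
    "run_cv",
]


@dataclass
class CvPlan:
    """Hold-out schedule: per repeat, per fold, the masked positive pairs."""

    folds: int
    repeats: int
    seed: int
    masks: list[list[np.ndarray]]  # masks[r][f]: array of (i, j) rows

    def __post_init__(self) -> None:
        for repeat in self.masks:
            sizes = [len(m) for m in repeat]
            if max(sizes) - min(sizes) > 1:
                raise ValueError("fold sizes differ by more than 1")


@dataclass
class MetricsReport:
    auc_mean: float
    auc_std: float
    per_repeat_auc: list[float]
    per_fold_auc: list[list[float]]
    threshold: float = float("nan")
    accuracy: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")
    f_measure: float = float("nan")
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0
    undefined: list[str] = field(default_factory=list)


def make_cv_plan(
    md: AssociationMatrix, folds: int = 5, repeats: int = 10, seed: int = 0
) -> CvPlan:
    """Randomly partition the positive pairs into folds, per repeat.

    Deterministic given the seed; within a repeat the folds are disjoint,
    cover every positive pair, and differ in size by at most one.
    """
    positives = np.argwhere(md.values == 1)
    if len(positives) < folds:
        raise ValueError(
            f"only {len(positives)} positive pairs for {folds} folds"
        )
    rng = np.random.default_rng(seed)
    masks: list[list[np.ndarray]] = []
    for _ in range(repeats):
        perm = rng.permutation(len(positives))
        masks.append([positives[chunk] for chunk in np.array_split(perm, folds)])
    return CvPlan(folds=folds, repeats=repeats, seed=seed, masks=masks)


def rank_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 1/2 P(tie).

    Exact (no threshold grid); equals the trapezoidal area under the ROC
    curve built from the same scores.
    """
    pos = np.asarray(pos_scores, dtype=float).ravel()
    neg = np.asarray(neg_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float(
        (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0)
        / (pos.size * neg.size)
    )


def threshold_metrics(
    pos_scores: np.ndarray, neg_scores: np.ndarray, threshold: float
) -> dict:
    """Confusion counts and derived rates at ``score >= threshold``.

    Ratios with a zero denominator are reported as 0 and named in the
    ``undefined`` list.
    """
    pos = np.asarray(pos_scores, dtype=float).ravel()
    neg = np.asarray(neg_scores, dtype=float).ravel()
    TP = int((pos >= threshold).sum())
    FN = int(pos.size - TP)
    FP = int((neg >= threshold).sum())
    TN = int(neg.size - FP)
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = ratio(TP + TN, TP + TN + FP + FN, "accuracy")
    precision = ratio(TP, TP + FP, "precision")
    recall = ratio(TP, TP + FN, "recall")
    f_measure = ratio(2 * precision * recall, precision + recall, "f_measure")
    return {
        "TP": TP,
        "FP": FP,
        "TN": TN,
        "FN": FN,
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f_measure": f_measure,
        "threshold": float(threshold),
        "undefined": undefined,
    }


def _best_f_threshold(pos: np.ndarray, neg: np.ndarray) -> float:
    """Threshold (drawn from the positive scores) maximizing the f-measure."""
    candidates = np.unique(pos)
    best_t, best_f = float(candidates[0]), -1.0
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    for t in candidates:
        TP = pos.size - np.searchsorted(pos_sorted, t, side="left")
        FP = neg.size - np.searchsorted(neg_sorted, t, side="left")
        FN = pos.size - TP
        if TP == 0:
            continue
        prec = TP / (TP + FP)
        rec = TP / (TP + FN)
        f = 2 * prec * rec / (prec + rec)
        if f > best_f:
            best_f, best_t = f, float(t)
    return best_t


def run_cv(
    md: AssociationMatrix,
    mf: SimilarityMatrix,
    ds: SimilarityMatrix | DiseaseDAGCollection,
    config=None,
    plan: CvPlan | None = None,
) -> MetricsReport:
    """Cross-validate the full pipeline on masked copies of MD.

    Every stage that depends on the association matrix (GIP kernels, WKNKN,
    CMF) is recomputed from the masked training matrix alone; the completed
    similarity matrices depend only on MF/DS and are computed once. Held-out
    fold pairs are ranked against all pairs that are 0 in the *full* matrix.
    AUC is averaged within each repeat, then summarized across repeats.
    """
    from .pipeline import RunConfig, prepare_static, score_associations
    from .similarity import disease_semantic_similarity

    config = config or RunConfig()
    if isinstance(ds, DiseaseDAGCollection):
        ds = disease_semantic_similarity(ds, config.semantic)
    plan = plan or make_cv_plan(md, seed=config.seed)
    static = prepare_static(mf, ds, config)
    neg_idx = np.argwhere(md.values == 0)
    all_pos = np.argwhere(md.values == 1)
    pos_set = {tuple(p) for p in all_pos}

    per_fold: list[list[float]] = []
    train_pos_scores: list[np.ndarray] = []
    test_pos_scores: list[np.ndarray] = []
    neg_scores_all: list[np.ndarray] = []
    for r, repeat in enumerate(plan.masks):
        fold_aucs: list[float] = []
        for f, mask in enumerate(repeat):
            try:
                train = md.values.copy()
                train[mask[:, 0], mask[:, 1]] = 0
                md_train = AssociationMatrix(
                    train, list(md.mirna_ids), list(md.disease_ids)
                )
                pred = score_associations(md_train, mf, ds, config, static=static)
                scores = pred.scores
            except Exception as exc:  # annotate with CV context
                raise RuntimeError(f"CV repeat {r}, fold {f}: {exc}") from exc
            pos = scores[mask[:, 0], mask[:, 1]]
            neg = scores[neg_idx[:, 0], neg_idx[:, 1]]
            fold_aucs.append(rank_auc(pos, neg))
            mask_set = {tuple(p) for p in mask}
            train_pos = np.array(sorted(pos_set - mask_set))
            train_pos_scores.append(scores[train_pos[:, 0], train_pos[:, 1]])
            test_pos_scores.append(pos)
            neg_scores_all.append(neg)
        per_fold.append(fold_aucs)
    per_repeat = [float(np.mean(f)) for f in per_fold]
    report = MetricsReport(
        auc_mean=float(np.mean(per_repeat)),
        auc_std=float(np.std(per_repeat)),
        per_repeat_auc=per_repeat,
        per_fold_auc=per_fold,
    )
    test_pos = np.concatenate(test_pos_scores)
    negs = np.concatenate(neg_scores_all)
    if config.threshold is not None:
        thr = config.threshold
    else:
        thr = _best_f_threshold(np.concatenate(train_pos_scores), negs)
    frag = threshold_metrics(test_pos, negs, thr)
    report.threshold = frag["threshold"]
    report.accuracy = frag["accuracy"]
    report.precision = frag["precision"]
    report.recall = frag["recall"]
    report.f_measure = frag["f_measure"]
    report.TP, report.FP = frag["TP"], frag["FP"]
    report.TN, report.FN = frag["TN"], frag["FN"]
    report.undefined = frag["undefined"]
    return report
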