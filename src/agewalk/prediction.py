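"""Supervised prediction of aging-related genes from node features.

The modelling surface follows the statsmodels convention: a
:class:`GenePredictionModel` is built from a feature matrix and a label
set and configured with a dimensionality-reduction choice and a
classifier; :meth:`GenePredictionModel.fit` runs repeated stratified
cross-validation and returns a :class:`GenePredictionResults` object
carrying out-of-fold scores, per-repeat accuracy measures (AUPR,
precision, recall, F-score), the aggregated prediction sets, and a
``summary()`` table.  :func:`fit_model_grid` fits the full
feature x {none, PCA} x {LR, NB, SVM-rbf} grid and selects the best model
by mean AUPR.

Evaluation statistics (permutation baseline, empirical p-values with
Benjamini--Hochberg adjustment, Jaccard/hypergeometric overlap analysis,
and cancer-list validation of novel predictions) live alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .features import FeatureMatrix
from .network import DataError, LabelSet

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "GenePredictionModel",
    "GenePredictionResults",
    "GridResults",
    "fit_model_grid",
    "select_best_model",
    "aupr",
    "precision_recall_f",
    "random_baseline",
    "compare_to_baseline",
    "adjust_pvalues",
    "jaccard",
    "hypergeometric_overlap_test",
    "OverlapReport",
    "overlap_report",
    "novel_predictions",
    "cancer_validation",
    "assemble_labels",
]

CLASSIFIERS = ("LR", "NB", "SVM_rbf")
DIM_REDUCTIONS = ("none", "PCA")

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified cross-validation settings."""

    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0
    positive_decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def _make_estimator(classifier: str, dim_reduction: str) -> Pipeline:
    steps = []
    if classifier in ("LR", "SVM_rbf") or dim_reduction == "PCA":
        steps.append(("scale", StandardScaler()))
    if dim_reduction == "PCA":
        # smallest number of components explaining >= 90% of training variance
        steps.append(("pca", PCA(n_components=0.90, svd_solver="full")))
    elif dim_reduction != "none":
        raise ValueError(f"unknown dimensionality reduction {dim_reduction!r}")
    if classifier == "LR":
        steps.append(
            ("clf", LogisticRegression(class_weight="balanced", max_iter=2000))
        )
    elif classifier == "NB":
        steps.append(("clf", GaussianNB()))
    elif classifier == "SVM_rbf":
        steps.append(("clf", SVC(kernel="rbf", class_weight="balanced")))
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    return Pipeline(steps)


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise, no interpolation)."""
    return float(average_precision_score(np.asarray(labels), np.asarray(scores)))


def precision_recall_f(tp: int, fp: int, fn: int) -> tuple:
    """Precision, recall and F-score from aggregated hard predictions.

    With no predicted positives, all three are reported as 0 (warned).
    """
    if tp + fp == 0:
        logger.warning("no predicted positives; precision/recall/F reported as 0")
        return 0.0, 0.0, 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f


class GenePredictionModel:
    """A (feature, dimensionality reduction, classifier) predictive model.

    Parameters
    ----------
    features
        Feature matrix covering at least all labelled genes.
    labels
        Positive (aging-related) and negative (non-aging-related) genes.
    dim_reduction
        ``"none"`` or ``"PCA"`` (fitted on training folds only).
    classifier
        ``"LR"``, ``"NB"`` or ``"SVM_rbf"``.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        labels: LabelSet,
        dim_reduction: str = "none",
        classifier: str = "LR",
        cv: CVConfig | None = None,
    ):
        self.cv = cv or CVConfig()
        missing = sorted(g for g in labels.genes if g not in set(features.genes))
        if missing:
            raise DataError(
                f"labelled genes missing from feature matrix {features.name!r}: "
                f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
            )
        if dim_reduction not in DIM_REDUCTIONS:
            raise ValueError(f"dim_reduction must be one of {DIM_REDUCTIONS}")
        if classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        self.features = features
        self.labels = labels
        self.dim_reduction = dim_reduction
        self.classifier = classifier
        self.genes = sorted(labels.positives, key=str) + sorted(labels.negatives, key=str)
        sub = features.subset(self.genes)
        self.X = sub.X
        self.y = np.array([1] * len(labels.positives) + [0] * len(labels.negatives))
        if self.y.sum() < self.cv.n_folds:
            raise DataError(
                f"{int(self.y.sum())} positives cannot be stratified into "
                f"{self.cv.n_folds} folds; reduce n_folds"
            )

    @property
    def spec(self) -> str:
        """Model identifier in the ``X+Y+Z`` convention."""
        y = "None" if self.dim_reduction == "none" else self.dim_reduction
        z = self.classifier.replace("_", "-")
        return f"{self.features.name}+{y}+{z}"

    def fit(self, y_override: np.ndarray | None = None) -> "GenePredictionResults":
        """Run repeated stratified CV and collect out-of-fold predictions."""
        y = self.y if y_override is None else np.asarray(y_override)
        n = len(self.genes)
        scores = np.zeros((self.cv.n_repeats, n))
        preds = np.zeros((self.cv.n_repeats, n), dtype=int)
        auprs = np.zeros(self.cv.n_repeats)
        for rep in range(self.cv.n_repeats):
            rs = (self.cv.seed + 7919 * rep) % _MAX_SEED
            skf = StratifiedKFold(
                n_splits=self.cv.n_folds, shuffle=True, random_state=rs
            )
            for train, test in skf.split(self.X, y):
                if y[train].sum() == 0:
                    raise DataError("a training fold contains no positives")
                est = _make_estimator(self.classifier, self.dim_reduction)
                est.fit(self.X[train], y[train])
                if hasattr(est, "predict_proba"):
                    s = est.predict_proba(self.X[test])[:, 1]
                else:
                    s = est.decision_function(self.X[test])
                scores[rep, test] = s
                preds[rep, test] = est.predict(self.X[test])
            auprs[rep] = aupr(scores[rep], y)
        return GenePredictionResults(model=self, y=y, scores=scores, preds=preds, auprs=auprs)


@dataclass
class GenePredictionResults:
    """Cross-validated predictions and accuracy measures for one model."""

    model: GenePredictionModel
    y: np.ndarray
    scores: np.ndarray  # repeats x genes, out-of-fold
    preds: np.ndarray  # repeats x genes, hard labels
    auprs: np.ndarray  # one AUPR per repeat

    @property
    def spec(self) -> str:
        return self.model.spec

    @property
    def genes(self) -> list:
        return self.model.genes

    @property
    def mean_aupr(self) -> float:
        return float(self.auprs.mean())

    @property
    def predicted_positives(self) -> frozenset:
        """Genes predicted positive in a majority of repeats."""
        votes = self.preds.mean(axis=0)
        return frozenset(
            g for g, v in zip(self.genes, votes) if v > 0.5
        )

    @property
    def true_positives(self) -> frozenset:
        pos = {g for g, yy in zip(self.genes, self.y) if yy == 1}
        return frozenset(self.predicted_positives & pos)

    @property
    def novel(self) -> frozenset:
        """Predicted-positive genes whose current label is negative."""
        pos = {g for g, yy in zip(self.genes, self.y) if yy == 1}
        return frozenset(self.predicted_positives - pos)

    def accuracy(self) -> dict:
        pos = {g for g, yy in zip(self.genes, self.y) if yy == 1}
        pred = self.predicted_positives
        tp = len(pred & pos)
        fp = len(pred - pos)
        fn = len(pos - pred)
        precision, recall, f = precision_recall_f(tp, fp, fn)
        return {
            "aupr": self.mean_aupr,
            "aupr_sd": float(self.auprs.std(ddof=0)),
            "precision": precision,
            "recall": recall,
            "f_score": f,
            "n_predictions": len(pred),
            "n_true_positives": tp,
            "n_novel": fp,
        }

    def summary(self) -> str:
        acc = self.accuracy()
        lines = [
            "Gene prediction results",
            "=" * 55,
            f"model:            {self.spec}",
            f"genes (pos/neg):  {int(self.y.sum())}/{int((1 - self.y).sum())}",
            f"CV:               {self.model.cv.n_folds}-fold x "
            f"{self.model.cv.n_repeats} repeats (seed {self.model.cv.seed})",
            "-" * 55,
            f"AUPR (mean +- sd):  {acc['aupr']:.4f} +- {acc['aupr_sd']:.4f}",
            f"precision:          {acc['precision']:.4f}",
            f"recall:             {acc['recall']:.4f}",
            f"F-score:            {acc['f_score']:.4f}",
            f"predictions:        {acc['n_predictions']} "
            f"({acc['n_true_positives']} known, {acc['n_novel']} novel)",
        ]
        return "\n".join(lines)


def _model_sort_key(res: GenePredictionResults):
    acc = res.accuracy()
    dim_rank = DIM_REDUCTIONS.index(res.model.dim_reduction)
    clf_rank = CLASSIFIERS.index(res.model.classifier)
    return (-res.mean_aupr, -acc["f_score"], dim_rank, clf_rank)


def select_best_model(results: dict) -> str:
    """Key of the result with the highest mean AUPR.

    Ties break by higher F-score, then by the simpler model (no reduction
    before PCA; LR before NB before SVM-rbf).
    """
    if not results:
        raise ValueError("no results to select from")
    return min(results, key=lambda k: _model_sort_key(results[k]))


@dataclass
class GridResults:
    """Results for every model of a feature x reduction x classifier grid."""

    results: dict  # spec string -> GenePredictionResults

    @property
    def best_spec(self) -> str:
        return select_best_model(self.results)

    @property
    def best(self) -> GenePredictionResults:
        return self.results[self.best_spec]

    def table(self) -> pd.DataFrame:
        rows = []
        for spec, res in self.results.items():
            row = {"model": spec}
            row.update(res.accuracy())
            rows.append(row)
        df = pd.DataFrame(rows).sort_values("aupr", ascending=False)
        return df.reset_index(drop=True)

    def summary(self) -> str:
        df = self.table()
        return (
            "Predictive model grid\n"
            + "=" * 55
            + f"\nbest model: {self.best_spec}\n"
            + "-" * 55
            + "\n"
            + df.to_string(
                index=False,
                float_format=lambda x: f"{x:.4f}",
            )
        )


def fit_model_grid(
    features,
    labels: LabelSet,
    cv: CVConfig | None = None,
    dim_reductions=DIM_REDUCTIONS,
    classifiers=CLASSIFIERS,
) -> GridResults:
    """Fit every (feature, reduction, classifier) combination.

    *features* is a mapping name -> FeatureMatrix or an iterable of
    FeatureMatrix.
    """
    if isinstance(features, dict):
        fms = list(features.values())
    elif isinstance(features, FeatureMatrix):
        fms = [features]
    else:
        fms = list(features)
    results = {}
    for fm in fms:
        for dim in dim_reductions:
            for clf in classifiers:
                model = GenePredictionModel(
                    fm, labels, dim_reduction=dim, classifier=clf, cv=cv
                )
                results[model.spec] = model.fit()
    return GridResults(results=results)


# ---------------------------------------------------------------------------
# baselines and significance


def random_baseline(
    features: FeatureMatrix,
    labels: LabelSet,
    cv: CVConfig | None = None,
    n_draws: int = 100,
    dim_reduction: str = "none",
    classifier: str = "LR",
    seed: int | None = None,
) -> np.ndarray:
    """Label-permutation baseline: mean AUPR per shuffled-label draw.

    Uses the same CV scheme as the observed model, with the labels permuted
    (seeded) before each draw.
    """
    cv = cv or CVConfig()
    model = GenePredictionModel(
        features, labels, dim_reduction=dim_reduction, classifier=classifier, cv=cv
    )
    rng = np.random.default_rng(cv.seed if seed is None else seed)
    out = np.zeros(n_draws)
    for d in range(n_draws):
        y_perm = rng.permutation(model.y)
        out[d] = model.fit(y_override=y_perm).mean_aupr
    return out


def compare_to_baseline(observed: float, baseline) -> float:
    """One-sided empirical p-value of *observed* against baseline draws."""
    base = np.asarray(baseline, dtype=float)
    return float((1 + np.sum(base >= observed)) / (1 + base.size))


def adjust_pvalues(ps, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini--Hochberg by default)."""
    ps = np.asarray(list(ps), dtype=float)
    if ps.size == 0:
        return ps
    _, adj, _, _ = multipletests(ps, method=method)
    return adj


# ---------------------------------------------------------------------------
# overlap analysis and cancer validation


def jaccard(a, b) -> float:
    """|a n b| / |a u b|; 0 (warned) when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        logger.warning("Jaccard of two empty sets reported as 0")
        return 0.0
    return len(a & b) / len(union)


def hypergeometric_overlap_test(a, b, universe) -> float:
    """Upper-tail hypergeometric p-value for the overlap of two gene sets.

    Probability of drawing >= |a n b| marked genes when |b| genes are drawn
    from *universe* with |a| marked.
    """
    a, b, universe = set(a), set(b), set(universe)
    if not a <= universe or not b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))


@dataclass(frozen=True)
class OverlapReport:
    jaccard: float
    raw_overlap: int
    p_value: float
    adjusted_p: float | None = None


def overlap_report(a, b, universe) -> OverlapReport:
    a, b = set(a), set(b)
    return OverlapReport(
        jaccard=jaccard(a, b),
        raw_overlap=len(a & b),
        p_value=hypergeometric_overlap_test(a, b, universe),
    )


def novel_predictions(result: GenePredictionResults, labels: LabelSet) -> frozenset:
    """Predicted-positive genes currently labelled non-aging-related."""
    return frozenset(result.predicted_positives & set(labels.negatives))


def cancer_validation(novel, cancer) -> float | None:
    """Percentage of novel predictions present in the cancer gene list.

    Returns ``None`` (not applicable) when there are no novel predictions.
    """
    novel, cancer = set(novel), set(cancer)
    if not novel:
        logger.warning("no novel predictions; cancer validation not applicable")
        return None
    return 100.0 * len(novel & cancer) / len(novel)


def assemble_labels(positive_source, all_aging_sources, suite) -> LabelSet:
    """Build the label set shared by every suite member.

    Positives: genes of the positive ground-truth source present in all
    eight (sub)networks.  Negatives: genes present in all eight
    (sub)networks but absent from *every* aging-related ground-truth
    source.  The same labels are used for classification on each member so
    accuracy is comparable across members.
    """
    common = suite.common_nodes()
    positives = frozenset(set(positive_source) & common)
    union_sources: set = set(positive_source)
    for src in all_aging_sources:
        union_sources |= set(src)
    negatives = frozenset(common - union_sources)
    if len(positives) < 2 or len(negatives) < 2:
        raise DataError(
            f"too few labelled genes after intersection "
            f"({len(positives)} positives, {len(negatives)} negatives)"
        )
    return LabelSet(positives=positives, negatives=negatives)
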