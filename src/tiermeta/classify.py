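"""Case/control classification used to vet gene selections.

Two uses: (1) pick the most informative multiple-testing correction per
disease by cross-validated accuracy of the gene sets each correction
selects, and (2) measure the discriminatory power of pathway-overlap genes
against matched-size random gene sets.

Classifiers are deliberately plain: linear-kernel SVM (C=1), k-nearest
neighbor (k=5), linear discriminant analysis, and Gaussian naive Bayes.
Features are standardized with training-fold statistics only (no leakage),
inside a scikit-learn pipeline, under stratified k-fold CV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import ExpressionStudy
from .meta_genes import CORRECTIONS

logger = logging.getLogger(__name__)

CLASSIFIERS = ("svm", "knn", "lda", "nb")

# most conservative first: ties in FDR-method selection resolve leftward
_CONSERVATIVE_ORDER = ("bonferroni", "by", "bh", "none")


@dataclass
class CVResult:
    study_id: str
    feature_set_label: str
    classifier: str
    fold_accuracies: list[float]
    mean_accuracy: float


def _make_classifier(name: str):
    if name == "svm":
        return SVC(kernel="linear", C=1.0)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "nb":
        return GaussianNB()
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


def cv_accuracy(
    X: np.ndarray,
    y: Sequence[str],
    classifier: str = "svm",
    folds: int = 3,
    seed: int = 0,
    study_id: str = "",
    feature_set_label: str = "",
) -> CVResult:
    """Stratified k-fold cross-validated accuracy with in-fold standardization."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} samples; cannot run {folds}-fold CV"
        )
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need a samples x features matrix with >= 1 feature")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        model = make_pipeline(StandardScaler(), _make_classifier(classifier))
        model.fit(X[train], y[train])
        accs.append(float(np.mean(model.predict(X[test]) == y[test])))
    return CVResult(
        study_id=study_id,
        feature_set_label=feature_set_label,
        classifier=classifier,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
    )


def study_features(study: ExpressionStudy, genes: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
    """Samples x features matrix for the study's measured subset of ``genes``."""
    wanted = set(genes)
    idx = [i for i, g in enumerate(study.genes) if g in wanted]
    X = study.values[idx].T
    y = np.asarray(study.labels)
    return X, y


def _majority_baseline(study: ExpressionStudy) -> float:
    n = len(study.samples)
    return max(study.n_case, study.n_control) / n


def select_fdr_method(
    studies: Sequence[ExpressionStudy],
    gene_sets: Mapping[str, Iterable[str]],
    classifiers: Sequence[str] = CLASSIFIERS,
    folds: int = 3,
    seed: int = 0,
) -> tuple[str, pd.DataFrame]:
    """Choose the correction whose gene set classifies the disease best.

    ``gene_sets`` maps correction name -> significant genes under it.  For
    each correction the genes (intersected with each study's measured
    genes) are used as features for every classifier under ``folds``-fold
    CV; the correction maximizing the disease-level mean accuracy wins,
    with ties broken toward the more conservative correction.  An empty
    gene set scores as the majority-class baseline.
    """
    unknown = set(gene_sets) - set(CORRECTIONS)
    if unknown:
        raise ValueError(f"unknown correction name(s) {sorted(unknown)}")
    rows = []
    means: dict[str, float] = {}
    for correction in _CONSERVATIVE_ORDER:
        if correction not in gene_sets:
            continue
        genes = set(gene_sets[correction])
        accs = []
        for study in studies:
            for clf in classifiers:
                X, y = study_features(study, genes)
                if X.shape[1] == 0:
                    acc = _majority_baseline(study)
                    folds_acc = [acc] * folds
                else:
                    res = cv_accuracy(
                        X, y, classifier=clf, folds=folds, seed=seed,
                        study_id=study.study_id, feature_set_label=correction,
                    )
                    acc, folds_acc = res.mean_accuracy, res.fold_accuracies
                accs.append(acc)
                rows.append((study.study_id, correction, clf, *folds_acc, acc))
        means[correction] = float(np.mean(accs))
    if not means:
        raise ValueError("no gene sets supplied")
    if all(len(set(gene_sets[c])) == 0 for c in means):
        logger.warning("every correction's gene set is empty; falling back to 'none'")
        chosen = "none" if "none" in means else next(iter(means))
    else:
        chosen = max(means, key=lambda c: (means[c], -_CONSERVATIVE_ORDER.index(c)))
    table = pd.DataFrame(
        rows,
        columns=["study_id", "correction", "classifier"]
        + [f"fold{i + 1}" for i in range(folds)]
        + ["mean_accuracy"],
    )
    return chosen, table


def pathway_discrimination(
    studies: Sequence[ExpressionStudy],
    sig_genes: Iterable[str],
    union_genes: Iterable[str],
    n_random: int = 100,
    folds: int = 3,
    classifier: str = "svm",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pathway-overlap genes vs matched-size random gene sets as features.

    Per study, the feature set is ``sig_genes & union_genes`` (restricted
    to genes the study measured); each of ``n_random`` random draws picks
    an equal-sized set from the study's measured genes *disjoint from the
    union set* and is scored identically.  Returns the per-study table
    (``pathway_accuracy``, ``random_mean``, ``random_sd``, ``n_features``)
    and a summary dict with disease-level means.
    """
    union = set(union_genes)
    overlap = set(sig_genes) & union
    rng = np.random.default_rng(seed)
    rows = []
    for study in studies:
        measured = set(study.genes)
        feats = sorted(overlap & measured)
        if not feats:
            continue
        X, y = study_features(study, feats)
        res = cv_accuracy(
            X, y, classifier=classifier, folds=folds, seed=seed,
            study_id=study.study_id, feature_set_label="pathway-overlap",
        )
        pool = np.array(sorted(measured - union))
        if n_random > 0 and pool.size < len(feats):
            raise ValueError(
                f"study {study.study_id}: not enough non-pathway genes for random draws"
            )
        rand_accs = []
        for _ in range(n_random):
            draw = rng.choice(pool, size=len(feats), replace=False)
            Xr, _ = study_features(study, draw)
            rand_accs.append(
                cv_accuracy(
                    Xr, y, classifier=classifier, folds=folds, seed=seed,
                    study_id=study.study_id, feature_set_label="random",
                ).mean_accuracy
            )
        rows.append(
            (
                study.study_id,
                len(feats),
                res.mean_accuracy,
                float(np.mean(rand_accs)) if rand_accs else np.nan,
                float(np.std(rand_accs)) if rand_accs else np.nan,
            )
        )
    if not rows:
        raise ValueError("pathway-overlap genes are measured in no study")
    table = pd.DataFrame(
        rows,
        columns=["study_id", "n_features", "pathway_accuracy", "random_mean", "random_sd"],
    )
    summary = {
        "pathway_accuracy": float(table["pathway_accuracy"].mean()),
        "random_mean": float(table["random_mean"].mean()),
    }
    return table, summary
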