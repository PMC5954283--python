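"""Pair classification: feature assembly, gradient-boosted trees, and CV.

A pair is represented by the concatenation of its enhancer and promoter
embedding vectors (200 dimensions at the default d = 100), optionally
extended with an external per-pair feature table.  A gradient-boosted
ensemble of regression trees with logistic loss scores pairs, and stratified
10-fold cross-validation reports F1, auROC and auPRC per fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .corpus import PairDataset
from .embedding import EmbeddingModel, infer_vector

log = logging.getLogger(__name__)


@dataclass
class GBRTConfig:
    """Gradient-boosting hyper-parameters: learning rate, tree count, depth."""

    learning_rate: float = 1e-3
    n_trees: int = 4000
    depth: int = 25
    seed: int = 1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.n_trees < 1 or self.depth < 1:
            raise ValueError("n_trees and depth must be >= 1")


@dataclass
class CVReport:
    f1: np.ndarray
    auroc: np.ndarray
    auprc: np.ndarray
    predictions: Optional[list] = None  # (enh_id, prom_id, label, score, fold)

    @property
    def n_folds(self) -> int:
        return len(self.f1)

    def summary(self) -> dict[str, float]:
        out = {}
        for name in ("f1", "auroc", "auprc"):
            vals = getattr(self, name)
            out[f"{name}_mean"] = float(np.mean(vals))
            out[f"{name}_std"] = float(np.std(vals))
        return out

    def to_kv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"n_folds={self.n_folds}\n")
            for key, val in sorted(self.summary().items()):
                fh.write(f"{key}={val:.6f}\n")
            for name in ("f1", "auroc", "auprc"):
                vals = ",".join(f"{v:.6f}" for v in getattr(self, name))
                fh.write(f"{name}_folds={vals}\n")

    def __str__(self) -> str:
        s = self.summary()
        return (
            f"{self.n_folds}-fold CV: "
            f"F1 {s['f1_mean']:.3f} ({s['f1_std']:.3f}), "
            f"auROC {s['auroc_mean']:.3f} ({s['auroc_std']:.3f}), "
            f"auPRC {s['auprc_mean']:.3f} ({s['auprc_std']:.3f})"
        )


def assemble_features(
    dataset: PairDataset,
    enh_model: EmbeddingModel,
    prom_model: EmbeddingModel,
    external: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Row per pair: [enhancer vector | promoter vector | external features]."""
    if external is None:
        external = dataset.external_features
    rows = []
    for pair in dataset.pairs:
        rows.append(
            np.concatenate([enh_model.embed(pair.enh_id), prom_model.embed(pair.prom_id)])
        )
    features = np.vstack(rows)
    if external is not None:
        external = np.asarray(external, dtype=np.float64)
        if external.shape[0] != len(dataset):
            raise ValueError(
                f"external feature rows ({external.shape[0]}) != pairs ({len(dataset)})"
            )
        features = np.hstack([features, external])
    if not np.all(np.isfinite(features)):
        raise ValueError("assembled features contain non-finite values")
    return features


def train_classifier(
    features: np.ndarray, labels: np.ndarray, config: GBRTConfig
) -> GradientBoostingClassifier:
    """Fit the gradient-boosted regression-tree ensemble with logistic loss."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes present to train a classifier")
    clf = GradientBoostingClassifier(
        learning_rate=config.learning_rate,
        n_estimators=config.n_trees,
        max_depth=config.depth,
        random_state=config.seed,
    )
    clf.fit(features, labels)
    return clf


def stratified_folds(labels: np.ndarray, n_folds: int = 10, seed: int = 1) -> list[np.ndarray]:
    """Disjoint fold index sets whose class proportions match the whole set."""
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    if n_folds > counts.min():
        raise ValueError(
            f"n_folds = {n_folds} exceeds minority class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(labels)), labels)]


def f1_score(predictions: np.ndarray, labels: np.ndarray) -> float:
    """F1 = 2rp/(r+p) from binary predictions; 0 when precision+recall is 0."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2 * r * p / (r + p)


def cross_validate(
    dataset: PairDataset,
    features: np.ndarray,
    config: GBRTConfig,
    n_folds: int = 10,
    seed: int = 1,
    threshold: float = 0.5,
    strict: bool = False,
    strict_context: Optional[dict] = None,
) -> CVReport:
    """Stratified k-fold cross-validation of the pair classifier.

    By default features come from the single transductive embedding run
    shared by all folds (the unsupervised stage never sees labels).  With
    ``strict=True``, held-out pairs are re-embedded with
    :func:`~epipair.embedding.infer_vector` so the test fold's document
    vectors come from frozen word vectors only; ``strict_context`` must then
    supply ``enh_model``, ``prom_model``, ``enh_sentences`` and
    ``prom_sentences`` (dicts keyed by doc id).
    """
    labels = dataset.labels
    folds = stratified_folds(labels, n_folds=n_folds, seed=seed)
    f1s, aurocs, auprcs = [], [], []
    predictions = []
    for fold_no, test_idx in enumerate(folds):
        train_mask = np.ones(len(labels), dtype=bool)
        train_mask[test_idx] = False
        clf = train_classifier(features[train_mask], labels[train_mask], config)
        test_features = features[test_idx]
        if strict:
            if not strict_context:
                raise ValueError("strict mode requires strict_context")
            test_features = _reinfer_features(
                dataset, test_idx, test_features, strict_context
            )
        scores = clf.predict_proba(test_features)[:, 1]
        y = labels[test_idx]
        pred = (scores >= threshold).astype(int)
        f1s.append(f1_score(pred, y))
        aurocs.append(roc_auc_score(y, scores))
        auprcs.append(average_precision_score(y, scores))
        for idx, score in zip(test_idx, scores):
            pair = dataset.pairs[idx]
            predictions.append((pair.enh_id, pair.prom_id, pair.label, float(score), fold_no))
    report = CVReport(
        f1=np.array(f1s), auroc=np.array(aurocs), auprc=np.array(auprcs),
        predictions=predictions,
    )
    log.info("%s", report)
    return report


def _reinfer_features(dataset, test_idx, test_features, ctx) -> np.ndarray:
    enh_model: EmbeddingModel = ctx["enh_model"]
    prom_model: EmbeddingModel = ctx["prom_model"]
    enh_sent = ctx["enh_sentences"]
    prom_sent = ctx["prom_sentences"]
    seed = ctx.get("seed", 1)
    d = enh_model.d
    out = test_features.copy()
    for row, idx in enumerate(test_idx):
        pair = dataset.pairs[idx]
        out[row, :d] = infer_vector(enh_model, enh_sent[pair.enh_id], seed=seed)
        out[row, d : 2 * d] = infer_vector(prom_model, prom_sent[pair.prom_id], seed=seed)
    return out


def write_predictions_tsv(report: CVReport, path) -> None:
    if report.predictions is None:
        raise ValueError("report carries no per-pair predictions")
    with open(path, "w") as fh:
        fh.write("enh_id\tprom_id\tlabel\tscore\tfold\n")
        for enh_id, prom_id, label, score, fold in report.predictions:
            fh.write(f"{enh_id}\t{prom_id}\t{label}\t{score:.6f}\t{fold}\n")
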