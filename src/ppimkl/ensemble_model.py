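"""Kernel ensembling, Gram-matrix repair, SVM training and cross-validated evaluation."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-9
PSD_TOL = 1e-9


class GramError(ValueError):
    pass


@dataclass
class GramMatrix:
    """Symmetric instance-by-instance kernel matrix with provenance."""

    matrix: np.ndarray
    ids: tuple[str, ...]
    name: str = "kernel"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.ids = tuple(self.ids)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise GramError(
                f"matrix shape {self.matrix.shape} does not match {n} instance ids"
            )
        if len(set(self.ids)) != n:
            raise GramError("instance ids are not unique")
        asym = float(np.abs(self.matrix - self.matrix.T).max()) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise GramError(f"matrix asymmetric beyond tolerance ({asym:g})")


def ensemble(grams: Sequence[GramMatrix], weights: Optional[Sequence[float]] = None) -> GramMatrix:
    """Weighted sum of Gram matrices, renormalized to unit diagonal.

    All inputs must share the same instance-id ordering; the error for a
    mismatch names the first divergence.
    """
    if not grams:
        raise GramError("no Gram matrices to ensemble")
    ids = grams[0].ids
    for g in grams[1:]:
        if g.ids != ids:
            for k, (a, b) in enumerate(zip(ids, g.ids)):
                if a != b:
                    raise GramError(
                        f"instance-id mismatch between {grams[0].name!r} and "
                        f"{g.name!r} at position {k}: {a!r} != {b!r}"
                    )
            raise GramError(
                f"instance count mismatch: {len(ids)} vs {len(g.ids)}"
            )
    if weights is None:
        weights = [1.0] * len(grams)
    if len(weights) != len(grams):
        raise GramError("one weight per Gram matrix required")
    if any(w < 0 for w in weights):
        raise GramError("weights must be nonnegative")
    if sum(weights) <= 0:
        raise GramError("at least one weight must be positive")
    M = sum(w * g.matrix for w, g in zip(weights, grams))
    d = np.diag(M).copy()
    bad = d <= SYMMETRY_TOL
    if bad.any():
        logger.warning("%d zero-diagonal entries left unscaled in ensemble", int(bad.sum()))
        d[bad] = 1.0
    s = 1.0 / np.sqrt(d)
    M = s[:, None] * M * s[None, :]
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, np.where(bad, np.diag(M), 1.0))
    return GramMatrix(
        M,
        ids,
        name="+".join(g.name for g in grams),
        params={"weights": list(map(float, weights)),
                "components": [g.name for g in grams]},
    )


def make_psd(G: GramMatrix, tol: float = PSD_TOL) -> GramMatrix:
    """Clip negative eigenvalues to zero; returns the input object when the
    matrix is already PSD within ``tol`` (fast path)."""
    M = G.matrix
    asym = float(np.abs(M - M.T).max()) if M.size else 0.0
    if asym > SYMMETRY_TOL:
        raise GramError(f"matrix asymmetric beyond tolerance ({asym:g})")
    eigvals = np.linalg.eigvalsh(M)
    if eigvals.size == 0 or eigvals[0] >= -tol:
        return G
    w, V = np.linalg.eigh(M)
    w = np.clip(w, 0.0, None)
    R = (V * w) @ V.T
    R = (R + R.T) / 2.0
    params = dict(G.params)
    params["psd_clipped"] = True
    return GramMatrix(R, G.ids, G.name, params)


def write_gram(G: GramMatrix, path: str | Path) -> None:
    """Persist a Gram matrix as TSV: header of ids, one labeled row per instance."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\t" + "\t".join(G.ids) + "\n")
        for rid, row in zip(G.ids, G.matrix):
            fh.write(rid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_gram(path: str | Path, name: str = "kernel") -> GramMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "id":
            raise GramError(f"{path}: malformed Gram TSV header")
        ids = tuple(header[1:])
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    return GramMatrix(np.array(rows), ids, name=name)


# ---------------------------------------------------------------------------
# SVM on precomputed kernels
# ---------------------------------------------------------------------------


def train(G: GramMatrix | np.ndarray, labels: Sequence[int], C: float = 1.0) -> SVC:
    """Fit an SVM on a precomputed train-by-train kernel block."""
    K = G.matrix if isinstance(G, GramMatrix) else np.asarray(G, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = SVC(C=C, kernel="precomputed")
    model.fit(K, y)
    return model


def predict(model: SVC, test_rows: np.ndarray) -> np.ndarray:
    """Decision scores for test-by-train kernel rows."""
    return model.decision_function(np.asarray(test_rows, dtype=float))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f_score = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f_score


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoidal AUC with half-credit tie handling.

    Equals the Mann-Whitney statistic U / (n+ * n-).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        tp += int((labels[i:j] == 1).sum())
        fp += int((labels[i:j] == 0).sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


@dataclass
class EvalReport:
    """Pooled and per-fold precision/recall/F, ROC points and AUC."""

    precision: float
    recall: float
    f_score: float
    auc: float
    tp: int
    tn: int
    fp: int
    fn: int
    roc: list[tuple[float, float]]
    folds: list[dict]

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "auc": self.auc,
            "confusion": {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn},
            "roc": [[float(x), float(y)] for x, y in self.roc],
            "folds": self.folds,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def make_folds(
    doc_ids: Sequence[str],
    folds: int = 10,
    split: str = "document",
    seed: int = 0,
) -> list[np.ndarray]:
    """Index arrays of test folds.  Document split keeps all instances of a
    document in one fold."""
    n = len(doc_ids)
    rng = np.random.default_rng(seed)
    if split == "document":
        docs = list(dict.fromkeys(doc_ids))  # first-appearance order
        if len(docs) < folds:
            raise ValueError(
                f"document split needs >= {folds} documents, got {len(docs)}"
            )
        docs = list(np.array(docs, dtype=object)[rng.permutation(len(docs))])
        doc_fold = {doc: k % folds for k, doc in enumerate(docs)}
        assignment = np.array([doc_fold[d] for d in doc_ids])
    elif split == "instance":
        if n < folds:
            raise ValueError(f"instance split needs >= {folds} instances, got {n}")
        perm = rng.permutation(n)
        assignment = np.empty(n, dtype=int)
        assignment[perm] = np.arange(n) % folds
    else:
        raise ValueError(f"unknown split {split!r}")
    return [np.flatnonzero(assignment == k) for k in range(folds)]


def cross_validate(
    G: GramMatrix,
    labels: Sequence[int],
    doc_ids: Sequence[str],
    folds: int = 10,
    split: str = "document",
    seed: int = 0,
    C: float = 1.0,
) -> EvalReport:
    """K-fold cross-validation of an SVM on a precomputed Gram matrix.

    Deterministic for a fixed seed; pooled confusion counts are the sums over
    folds, the ROC/AUC is computed over the pooled decision scores.
    """
    K = G.matrix
    y = np.asarray(labels)
    if len(y) != len(G.ids) or len(doc_ids) != len(G.ids):
        raise GramError("labels/doc_ids length must match the Gram matrix")
    test_folds = make_folds(doc_ids, folds, split, seed)
    all_idx = np.arange(len(y))
    fold_reports = []
    pooled_scores = np.zeros(len(y))
    tp = tn = fp = fn = 0
    for k, test_idx in enumerate(test_folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        model = train(K[np.ix_(train_idx, train_idx)], y[train_idx], C=C)
        scores = predict(model, K[np.ix_(test_idx, train_idx)])
        pooled_scores[test_idx] = scores
        preds = (scores > 0).astype(int)
        yt = y[test_idx]
        ftp = int(((preds == 1) & (yt == 1)).sum())
        ffp = int(((preds == 1) & (yt == 0)).sum())
        ffn = int(((preds == 0) & (yt == 1)).sum())
        ftn = int(((preds == 0) & (yt == 0)).sum())
        tp, fp, fn, tn = tp + ftp, fp + ffp, fn + ffn, tn + ftn
        p, r, f = prf(ftp, ffp, ffn)
        fold_reports.append(
            {"fold": k, "size": int(len(test_idx)), "tp": ftp, "fp": ffp,
             "fn": ffn, "tn": ftn, "precision": p, "recall": r, "f_score": f}
        )
    precision, recall, f_score = prf(tp, fp, fn)
    roc, auc = roc_auc(pooled_scores, y)
    return EvalReport(
        precision=precision,
        recall=recall,
        f_score=f_score,
        auc=auc,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        roc=roc,
        folds=fold_reports,
    )
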