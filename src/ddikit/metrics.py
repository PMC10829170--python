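"""Evaluation metrics for imbalanced multiclass DDI prediction.

Threshold metrics (accuracy, precision, recall, F1) are support-weighted
across classes; the rank metrics AUROC and AUPRC are macro (unweighted)
one-vs-rest averages, with classes that have no positives — or no negatives
— in ``y_true`` skipped rather than zero-filled. Also provides the dataset
diversity metrics SNN (mean nearest-neighbor Tanimoto) and Scaff (cosine
similarity of scaffold-frequency profiles).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .chemio import Fingerprint, MoleculeRecord
from .errors import ShapeError

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    acc: float
    f1_weighted: float
    precision_weighted: float
    recall_weighted: float
    auroc_macro: float
    auprc_macro: float
    per_class: pd.DataFrame
    n: int

    def as_dict(self) -> dict:
        return {
            "acc": self.acc,
            "f1_weighted": self.f1_weighted,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
            "auroc_macro": self.auroc_macro,
            "auprc_macro": self.auprc_macro,
            "n": self.n,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def classification_report(y_true: np.ndarray, prob: np.ndarray) -> MetricReport:
    """Weighted threshold metrics + macro rank metrics from class probabilities."""
    y_true = np.asarray(y_true)
    prob = np.asarray(prob, dtype=np.float64)
    if prob.ndim != 2 or len(y_true) != prob.shape[0]:
        raise ShapeError(f"y_true ({len(y_true)}) and prob ({prob.shape}) do not align")
    if np.any(np.abs(prob.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    n, C = prob.shape
    y_pred = prob.argmax(axis=1)
    labels = np.arange(C)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    aurocs, auprcs = {}, {}
    for c in labels:
        pos = y_true == c
        if pos.sum() == 0 or pos.sum() == n:
            if pos.sum() == 0:
                logger.info("class %d absent from y_true; excluded from macro averages", c)
            continue
        aurocs[c] = roc_auc_score(pos, prob[:, c])
        auprcs[c] = average_precision_score(pos, prob[:, c])
    if not aurocs:
        raise ValueError("no class admits a ROC curve (need positives and negatives)")
    per_class = pd.DataFrame(
        {
            "class": labels,
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "support": support,
            "auroc": [aurocs.get(c, np.nan) for c in labels],
            "auprc": [auprcs.get(c, np.nan) for c in labels],
        }
    )
    w = support / support.sum()
    return MetricReport(
        acc=float(accuracy_score(y_true, y_pred)),
        f1_weighted=float(np.sum(w * f1)),
        precision_weighted=float(np.sum(w * prec)),
        recall_weighted=float(np.sum(w * rec)),
        auroc_macro=float(np.mean(list(aurocs.values()))),
        auprc_macro=float(np.mean(list(auprcs.values()))),
        per_class=per_class,
        n=int(n),
    )


def snn(query_fps: list[Fingerprint], reference_fps: list[Fingerprint]) -> float:
    """Mean over queries of the maximum Tanimoto similarity to any reference.

    High SNN means the query set sits close to the reference set — low
    structural novelty.
    """
    if not query_fps or not reference_fps:
        raise ValueError("both fingerprint lists must be non-empty")
    if {fp.n_bits for fp in query_fps} | {fp.n_bits for fp in reference_fps} != {
        query_fps[0].n_bits
    }:
        raise ValueError("all fingerprints must share n_bits")
    Q = np.stack([fp.bits for fp in query_fps]).astype(np.float64)
    R = np.stack([fp.bits for fp in reference_fps]).astype(np.float64)
    inter = Q @ R.T
    union = Q.sum(axis=1)[:, None] + R.sum(axis=1)[None, :] - inter
    sim = np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)
    return float(sim.max(axis=1).mean())


def scaffold_similarity(set_a: list[MoleculeRecord], set_b: list[MoleculeRecord]) -> float:
    """Scaff: cosine similarity of the two sets' scaffold-frequency vectors.

    Acyclic molecules (empty scaffold) share one "no-scaffold" bucket.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    ca = Counter(r.scaffold for r in set_a)
    cb = Counter(r.scaffold for r in set_b)
    keys = sorted(set(ca) | set(cb))
    va = np.array([ca.get(k, 0) for k in keys], dtype=np.float64)
    vb = np.array([cb.get(k, 0) for k in keys], dtype=np.float64)
    return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
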