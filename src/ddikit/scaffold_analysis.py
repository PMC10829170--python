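"""Scaffold-level mining: frequent patterns, profiles, clustering, similarity.

The pipeline mirrors a scaffold-centric analysis of a DDI table: treat each
drug pair as a transaction of scaffold (and optionally side-effect) items,
mine frequent itemsets with FP-Growth and score association rules; build
binary scaffold interaction / side-effect profile matrices; cluster rows by
Jaccard distance; and summarize structural similarity within and across
clusters with a suite of five binary similarity metrics.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .chemio import Fingerprint, murcko_scaffold
from .errors import DegenerateVectorError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransactionSet:
    """Itemset transactions (scaffold SMILES and/or side-effect labels)."""

    transactions: tuple[frozenset, ...]

    @classmethod
    def from_iterables(cls, rows) -> "TransactionSet":
        return cls(tuple(frozenset(r) for r in rows))

    def __len__(self) -> int:
        return len(self.transactions)


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset
    consequent: frozenset
    support: float
    confidence: float
    lift: float


@dataclass
class ProfileMatrix:
    """Binary matrix with named axes.

    ``kind`` is "interaction" (position-1 scaffolds x position-2 scaffolds)
    or "side_effect" (scaffolds x side-effect labels).
    """

    values: np.ndarray
    row_names: list[str]
    col_names: list[str]
    kind: str = "interaction"

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.row_names, columns=self.col_names).to_csv(path)


# ---------------------------------------------------------------------------
# FP-Growth
# ---------------------------------------------------------------------------


class _FPNode:
    __slots__ = ("item", "count", "parent", "children", "link")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict = {}
        self.link: _FPNode | None = None


def _build_tree(transactions, counts, min_count):
    """FP-tree over frequency-ordered items; returns (root, header table)."""
    order = {
        item: i
        for i, (item, _) in enumerate(
            sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
        )
    }
    root = _FPNode(None, None)
    header: dict = {}
    for trans, mult in transactions:
        items = sorted(
            (it for it in trans if counts.get(it, 0) >= min_count), key=order.__getitem__
        )
        node = root
        for it in items:
            child = node.children.get(it)
            if child is None:
                child = _FPNode(it, node)
                node.children[it] = child
                if it in header:
                    child.link = header[it]
                header[it] = child
            child.count += mult
            node = child
    return root, header


def _mine(header, counts, min_count, suffix, out):
    for item in sorted(counts, key=str):
        support_count = counts[item]
        itemset = suffix | {item}
        out.append((frozenset(itemset), support_count))
        # conditional pattern base: prefix paths of every node holding `item`
        cond: list[tuple[frozenset, int]] = []
        node = header.get(item)
        while node is not None:
            path = []
            p = node.parent
            while p is not None and p.item is not None:
                path.append(p.item)
                p = p.parent
            if path:
                cond.append((frozenset(path), node.count))
            node = node.link
        cond_counts: Counter = Counter()
        for trans, mult in cond:
            for it in trans:
                cond_counts[it] += mult
        cond_counts = Counter({k: v for k, v in cond_counts.items() if v >= min_count})
        if cond_counts:
            _, sub_header = _build_tree(cond, cond_counts, min_count)
            _mine(sub_header, cond_counts, min_count, itemset, out)


def fp_growth(transactions: TransactionSet, min_support: float) -> list[tuple[frozenset, float]]:
    """All itemsets with support >= min_support (fraction of transactions).

    Exhaustive and duplicate-free; supports are exact fractions.
    """
    if not 0.0 < min_support <= 1.0:
        raise ValueError("min_support must be in (0, 1]")
    n = len(transactions)
    if n == 0:
        raise ValueError("need at least one transaction")
    min_count = int(np.ceil(min_support * n - 1e-9))
    min_count = max(min_count, 1)
    counts: Counter = Counter()
    for t in transactions.transactions:
        counts.update(t)
    counts = Counter({k: v for k, v in counts.items() if v >= min_count})
    weighted = [(t, 1) for t in transactions.transactions]
    _, header = _build_tree(weighted, counts, min_count)
    out: list[tuple[frozenset, int]] = []
    _mine(header, counts, min_count, frozenset(), out)
    return sorted(
        ((iset, c / n) for iset, c in out),
        key=lambda kv: (-kv[1], len(kv[0]), sorted(map(str, kv[0]))),
    )


def association_rules(
    frequent: list[tuple[frozenset, float]],
    transactions: TransactionSet,
    min_confidence: float = 0.0,
) -> list[AssociationRule]:
    """Score every antecedent/consequent bipartition of each frequent itemset."""
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must be in [0, 1]")
    support = dict(frequent)
    rules: list[AssociationRule] = []
    for itemset, supp_ab in frequent:
        if len(itemset) < 2:
            continue
        items = sorted(itemset, key=str)
        for r in range(1, len(items)):
            for ante in combinations(items, r):
                a = frozenset(ante)
                b = itemset - a
                conf = supp_ab / support[a]
                if conf < min_confidence:
                    continue
                rules.append(
                    AssociationRule(
                        antecedent=a,
                        consequent=b,
                        support=supp_ab,
                        confidence=conf,
                        lift=conf / support[b],
                    )
                )
    return sorted(rules, key=lambda r: (-r.confidence, -r.support, str(sorted(r.antecedent))))


def pair_transactions(pairs: list, include_labels: bool = False, scaffold_fn=murcko_scaffold,
                      label_names: list[str] | None = None) -> TransactionSet:
    """Scaffold-pair transactions from a DDI table, optionally with the label.

    Each pair becomes {scaffold1, scaffold2} (acyclic drugs contribute the
    "no-scaffold" empty-string family); with ``include_labels`` the
    side-effect label joins the transaction as an extra item.
    """
    cache: dict[str, str] = {}

    def scaf(s: str) -> str:
        if s not in cache:
            cache[s] = scaffold_fn(s)
        return cache[s]

    rows = []
    for ex in pairs:
        items = {scaf(ex.drug1_smiles), scaf(ex.drug2_smiles)}
        if include_labels:
            items.add(label_names[ex.label] if label_names else f"label:{ex.label}")
        rows.append(items)
    return TransactionSet.from_iterables(rows)


# ---------------------------------------------------------------------------
# Profile matrices and clustering
# ---------------------------------------------------------------------------


def build_profile_matrix(pairs: list, mode: str, scaffold_fn=murcko_scaffold,
                         label_names: list[str] | None = None) -> ProfileMatrix:
    """Binary scaffold profile matrix from a DDI pair table.

    interaction mode: rows are scaffolds observed at position 1, columns
    scaffolds at position 2; a cell is 1 iff any pair exhibits that scaffold
    combination (deliberately binarized, not counted). side_effect mode:
    rows are scaffolds from either position, columns side-effect labels.
    """
    if mode not in ("interaction", "side_effect"):
        raise ValueError(f"unknown mode {mode!r}")
    cache: dict[str, str] = {}

    def scaf(s: str) -> str:
        if s not in cache:
            cache[s] = scaffold_fn(s)
        return cache[s]

    hits: set[tuple[str, str]] = set()
    for ex in pairs:
        s1, s2 = scaf(ex.drug1_smiles), scaf(ex.drug2_smiles)
        if mode == "interaction":
            hits.add((s1, s2))
        else:
            lab = label_names[ex.label] if label_names else f"label:{ex.label}"
            hits.add((s1, lab))
            hits.add((s2, lab))
    rows = sorted({r for r, _ in hits})
    cols = sorted({c for _, c in hits})
    values = np.zeros((len(rows), len(cols)), dtype=np.uint8)
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: i for i, c in enumerate(cols)}
    for r, c in hits:
        values[ri[r], ci[c]] = 1
    return ProfileMatrix(values=values, row_names=rows, col_names=cols, kind=mode)


_METRICS = ("tanimoto", "dice", "kulczynski", "asymmetric", "rogot_goldberg")


def bit_similarity(a: np.ndarray, b: np.ndarray, metric: str = "tanimoto") -> float:
    """Binary-vector similarity.

    With popcounts a=|A|, b=|B|, common bits c=|A and B|, length N and
    d = N - a - b + c (common zeros):
    tanimoto = c/(a+b-c); dice = 2c/(a+b); kulczynski = c(a+b)/(2ab);
    asymmetric = c/min(a,b); rogot_goldberg = c/(a+b) + d/(2N-a-b).
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and equal length")
    na, nb = int(a.sum()), int(b.sum())
    c = int((a & b).sum())
    N = a.size
    d = N - na - nb + c
    if metric == "tanimoto":
        if na + nb - c == 0:
            raise DegenerateVectorError("tanimoto undefined for two empty vectors")
        return c / (na + nb - c)
    if metric == "dice":
        if na + nb == 0:
            raise DegenerateVectorError("dice undefined for two empty vectors")
        return 2 * c / (na + nb)
    if metric == "kulczynski":
        if na == 0 or nb == 0:
            raise DegenerateVectorError("kulczynski undefined for an empty vector")
        return c * (na + nb) / (2 * na * nb)
    if metric == "asymmetric":
        if min(na, nb) == 0:
            raise DegenerateVectorError("asymmetric undefined for an empty vector")
        return c / min(na, nb)
    # rogot_goldberg
    if na + nb == 0 or 2 * N - na - nb == 0:
        raise DegenerateVectorError("rogot-goldberg undefined for this input")
    return c / (na + nb) + d / (2 * N - na - nb)


def cluster_binary_profiles(
    matrix: ProfileMatrix, threshold: float = 1.0, criterion: str = "inconsistent"
) -> np.ndarray:
    """Single-linkage clustering of rows on Jaccard distance.

    The dendrogram is cut at ``threshold`` under the given flat-clustering
    ``criterion`` (default: the inconsistency coefficient; "distance" cuts
    at a raw Jaccard-distance height instead).
    Rows with identical profiles always co-cluster (their distance is 0);
    all-zero rows have undefined Jaccard distance and are singleton-clustered
    with a warning. Returns one integer label per row.
    """
    rows = matrix.values.astype(bool)
    if rows.shape[0] < 1:
        raise ValueError("need at least one row")
    nz = np.flatnonzero(rows.any(axis=1))
    zeros = np.flatnonzero(~rows.any(axis=1))
    if len(zeros):
        logger.warning("%d all-zero rows singleton-clustered (Jaccard undefined)", len(zeros))
    labels = np.zeros(rows.shape[0], dtype=np.int64)
    next_label = 1
    if len(nz) == 1:
        labels[nz[0]] = next_label
        next_label += 1
    elif len(nz) > 1:
        Z = linkage(pdist(rows[nz], metric="jaccard"), method="single")
        sub = fcluster(Z, t=threshold, criterion=criterion)
        labels[nz] = sub
        next_label = int(sub.max()) + 1
    for z in zeros:
        labels[z] = next_label
        next_label += 1
    return labels


def cluster_similarity_summary(
    clusters: np.ndarray, fingerprints: list[Fingerprint], metric: str = "tanimoto"
) -> tuple[float, float, pd.DataFrame]:
    """Mean pairwise structural similarity within vs across clusters.

    intra pools all pairs inside clusters of size >= 2; inter pools all
    pairs whose members carry different cluster labels. The per-cluster
    table reports size, pair count and mean within-cluster similarity.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != len(fingerprints):
        raise ValueError("labels and fingerprints must align")
    by_cluster = defaultdict(list)
    for lab, fp in zip(clusters, fingerprints):
        by_cluster[int(lab)].append(fp)
    if not any(len(v) >= 2 for v in by_cluster.values()):
        raise ValueError("intra-cluster similarity undefined: no cluster of size >= 2")
    intra_vals, table = [], []
    for lab in sorted(by_cluster):
        fps = by_cluster[lab]
        sims = [
            bit_similarity(x.bits, y.bits, metric) for x, y in combinations(fps, 2)
        ]
        intra_vals.extend(sims)
        table.append(
            {
                "cluster": lab,
                "size": len(fps),
                "n_pairs": len(sims),
                "mean_similarity": float(np.mean(sims)) if sims else np.nan,
            }
        )
    inter_vals = [
        bit_similarity(fingerprints[i].bits, fingerprints[j].bits, metric)
        for i, j in combinations(range(len(fingerprints)), 2)
        if clusters[i] != clusters[j]
    ]
    inter = float(np.mean(inter_vals)) if inter_vals else float("nan")
    return float(np.mean(intra_vals)), inter, pd.DataFrame(table)
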