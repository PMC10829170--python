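"""Dataset partitioning: MaxMin diversity split and the three DDI schemes.

The DDI evaluation schemes model increasingly hard deployment scenarios:
``random`` (Task 1) tests unseen *pairs* of known drugs, ``one_unseen``
(Task 2) tests pairs of one known and one new drug, and ``both_unseen``
(Task 3) tests pairs of two new drugs. The two cold-start schemes share the
same training examples so their results are directly comparable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .chemio import Fingerprint
from .errors import DegenerateSplitError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """Index sets of one train/val/test partition of a DDI pair table."""

    scheme: str  # random | one_unseen | both_unseen
    train_ids: tuple[int, ...]
    val_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    holdout_drugs: frozenset[str] = field(default_factory=frozenset)
    seed: int = 0

    def validate(self, examples: list) -> None:
        """Check the bucket invariants against the pair table; raise on violation."""
        t, v, s = set(self.train_ids), set(self.val_ids), set(self.test_ids)
        if (t & v) or (t & s) or (v & s):
            raise ValueError("partitions are not pairwise disjoint")
        if self.scheme == "random":
            if t | v | s != set(range(len(examples))):
                raise ValueError("random split must cover the whole table")
        else:
            hold = self.holdout_drugs
            for i in self.train_ids + self.val_ids:
                ex = examples[i]
                if ex.drug1_smiles in hold or ex.drug2_smiles in hold:
                    raise ValueError("train/val pair touches a holdout drug")
            want = 1 if self.scheme == "one_unseen" else 2
            for i in self.test_ids:
                ex = examples[i]
                n_new = (ex.drug1_smiles in hold) + (ex.drug2_smiles in hold)
                if n_new != want:
                    raise ValueError(
                        f"{self.scheme} test pair has {n_new} holdout drugs, wanted {want}"
                    )


def save_split(spec: SplitSpec, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "scheme": spec.scheme,
                "seed": spec.seed,
                "train_ids": list(spec.train_ids),
                "val_ids": list(spec.val_ids),
                "test_ids": list(spec.test_ids),
                "holdout_drugs": sorted(spec.holdout_drugs),
            },
            fh,
        )


def load_split(path: str) -> SplitSpec:
    with open(path) as fh:
        d = json.load(fh)
    return SplitSpec(
        scheme=d["scheme"],
        train_ids=tuple(d["train_ids"]),
        val_ids=tuple(d["val_ids"]),
        test_ids=tuple(d["test_ids"]),
        holdout_drugs=frozenset(d["holdout_drugs"]),
        seed=d["seed"],
    )


def maxmin_split(
    fingerprints: list[Fingerprint], select_fraction: float, seed: int
) -> tuple[list[int], list[int]]:
    """Greedy MaxMin diversity picking on Tanimoto distance.

    The seed picks the first compound uniformly; each later pick maximizes
    its minimum distance (1 - Tanimoto) to the already-selected set, with
    ties broken toward the lowest index. Returns (selected, remainder) with
    ``ceil(select_fraction * N)`` compounds selected — the diverse side,
    used as the pre-training validation set.
    """
    if not 0.0 < select_fraction < 1.0:
        raise ValueError("select_fraction must be in (0, 1)")
    n = len(fingerprints)
    if n < 2:
        raise ValueError("need at least 2 fingerprints")
    bits = np.stack([fp.bits for fp in fingerprints]).astype(np.float64)
    pop = bits.sum(axis=1)
    n_select = math.ceil(select_fraction * n)
    rng = np.random.default_rng(seed)
    first = int(rng.integers(0, n))
    selected = [first]
    # min distance of every compound to the selected set so far
    min_dist = np.full(n, np.inf)

    def dist_to(j: int) -> np.ndarray:
        inter = bits @ bits[j]
        union = pop + pop[j] - inter
        sim = np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)
        return 1.0 - sim

    min_dist = np.minimum(min_dist, dist_to(first))
    min_dist[first] = -np.inf
    while len(selected) < n_select:
        pick = int(np.argmax(min_dist))  # argmax takes the lowest index on ties
        selected.append(pick)
        min_dist = np.minimum(min_dist, dist_to(pick))
        min_dist[pick] = -np.inf
    remainder = [i for i in range(n) if i not in set(selected)]
    return selected, remainder


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Integer allocation of n among len(ratios) buckets, totals exact."""
    raw = [n * r for r in ratios]
    counts = [int(math.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _stratified_assignment(
    labels: np.ndarray, ratios: tuple[float, float, float], rng: np.random.Generator
) -> np.ndarray:
    """Assign each index to partition 0/1/2, per class, ratios within +-1."""
    part = np.empty(len(labels), dtype=np.int64)
    nonzero = [p for p in (2, 1, 0) if ratios[p] > 0]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        if len(idx) < 3:
            logger.warning(
                "class %s has only %d examples; pooling best-effort into val/test", cls, len(idx)
            )
            for k, i in enumerate(idx):
                part[i] = nonzero[k % len(nonzero)]
            continue
        counts = _largest_remainder(len(idx), ratios)
        bounds = np.cumsum(counts)
        part[idx[: bounds[0]]] = 0
        part[idx[bounds[0] : bounds[1]]] = 1
        part[idx[bounds[1] :]] = 2
    return part


def stratified_random_split(
    examples: list, ratios: tuple[float, float, float], seed: int
) -> SplitSpec:
    """Class-stratified random split (Task 1); default protocol is 80:10:10."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    labels = np.array([ex.label for ex in examples])
    rng = np.random.default_rng(seed)
    part = _stratified_assignment(labels, tuple(ratios), rng)
    return SplitSpec(
        scheme="random",
        train_ids=tuple(np.flatnonzero(part == 0).tolist()),
        val_ids=tuple(np.flatnonzero(part == 1).tolist()),
        test_ids=tuple(np.flatnonzero(part == 2).tolist()),
        seed=seed,
    )


def unseen_drug_splits(
    examples: list,
    holdout_fraction: float = 0.1,
    seed: int = 0,
    val_fraction: float = 0.1,
) -> tuple[SplitSpec, SplitSpec]:
    """Build the Task 2 (one-unseen) and Task 3 (both-unseen) splits.

    A fraction of drugs is held out as "new". Pairs with both drugs known
    form the shared train pool (validation is carved from it, stratified);
    pairs with exactly one new drug are the Task 2 test set and pairs with
    two new drugs the Task 3 test set, so every pair lands in exactly one
    bucket.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must be in (0, 1)")
    drugs = sorted({ex.drug1_smiles for ex in examples} | {ex.drug2_smiles for ex in examples})
    rng = np.random.default_rng(seed)
    n_hold = max(1, round(holdout_fraction * len(drugs)))
    if n_hold >= len(drugs):
        raise DegenerateSplitError("holdout would consume every drug")
    holdout = frozenset(
        np.array(drugs, dtype=object)[rng.choice(len(drugs), size=n_hold, replace=False)]
    )
    pool, test2, test3 = [], [], []
    for i, ex in enumerate(examples):
        n_new = (ex.drug1_smiles in holdout) + (ex.drug2_smiles in holdout)
        (pool, test2, test3)[n_new].append(i)
    if not pool or not test2 or not test3:
        raise DegenerateSplitError(
            f"empty bucket: train_pool={len(pool)} one_unseen={len(test2)} "
            f"both_unseen={len(test3)}"
        )
    pool_labels = np.array([examples[i].label for i in pool])
    part = _stratified_assignment(pool_labels, (1.0 - val_fraction, val_fraction, 0.0), rng)
    train_ids = tuple(pool[j] for j in np.flatnonzero(part == 0))
    val_ids = tuple(pool[j] for j in np.flatnonzero(part == 1))
    if not train_ids or not val_ids:
        raise DegenerateSplitError("train or validation bucket is empty")
    task2 = SplitSpec("one_unseen", train_ids, val_ids, tuple(test2), holdout, seed)
    task3 = SplitSpec("both_unseen", train_ids, val_ids, tuple(test3), holdout, seed)
    return task2, task3
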