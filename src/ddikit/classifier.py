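"""Transfer stage: frozen-encoder pair features into a multiclass classifier.

Each drug of a pair is embedded with the (frozen) pre-trained encoder; the
two representations are concatenated and fed to a feed-forward network
trained with the negative log-likelihood objective. Three samplers address
class imbalance: balanced batches (equal per-class counts per batch),
inverse-frequency class sampling, and a per-example weighted random sampler.
The epoch with the best validation weighted F1 is kept for inference. The
un-pretrained ablation arm substitutes a frozen randomly-initialized encoder
of identical shape.
"""

from __future__ import annotations

import logging
from collections.abc import Iterator
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _nn
from .chemio import canonicalize
from .encoder import EncoderConfig, PretrainState, SmilesEncoder
from .errors import ConfigError, ParseError, SchemaError, ShapeError
from .metrics import MetricReport, classification_report

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DDIExample:
    """An ordered drug pair with an integer side-effect class label."""

    drug1_smiles: str
    drug2_smiles: str
    label: int

    def __post_init__(self) -> None:
        if self.label < 0:
            raise ValueError("label must be non-negative")

    def validated(self) -> "DDIExample":
        """Return a copy with both SMILES canonicalized (raises ParseError)."""
        return DDIExample(
            canonicalize(self.drug1_smiles), canonicalize(self.drug2_smiles), self.label
        )


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_dims: tuple[int, ...] = (1024, 512)
    dropout: float = 0.2
    n_classes: int = 2
    batch_size: int = 256
    epochs: int = 200
    sampler: str = "balanced_batch"  # | class_weight | weighted_random
    symmetrize_pairs: bool = False
    lr: float = 1e-3
    weight_decay: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("need at least 2 classes")
        if self.sampler not in ("balanced_batch", "class_weight", "weighted_random"):
            raise ConfigError(f"unknown sampler {self.sampler!r}")


def featurize_pair(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Order-sensitive concatenation [h1 || h2] of the two representations."""
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    if h1.shape[-1] != h2.shape[-1]:
        raise ShapeError(f"representation widths differ: {h1.shape} vs {h2.shape}")
    return np.concatenate([h1, h2], axis=-1)


def nll_loss(log_probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true classes."""
    lp = np.asarray(log_probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    if np.any(np.abs(np.exp(lp).sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("rows must be log-probabilities summing (in exp) to 1")
    if np.any(labels >= lp.shape[1]) or np.any(labels < 0):
        raise ValueError("label outside 0..C-1")
    return float(-lp[np.arange(len(labels)), labels].mean())


def make_sampler(
    labels: np.ndarray, strategy: str, batch_size: int, seed: int
) -> Iterator[np.ndarray]:
    """One epoch of minibatch index arrays under an imbalance-aware strategy.

    balanced_batch: per-class counts within each batch differ by at most 1,
    minority classes resampled with replacement (when classes outnumber the
    batch size, each batch covers ``batch_size`` distinct classes, rotating).
    class_weight: classes drawn inversely proportional to frequency, then a
    uniform member. weighted_random: examples drawn with replacement with
    probability proportional to 1/(class frequency).
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() == 0 or len(classes) == 0:
        raise ValueError("every class must be present at least once")
    rng = np.random.default_rng(seed)
    n = len(labels)
    n_batches = max(1, int(np.ceil(n / batch_size)))
    members = {c: np.flatnonzero(labels == c) for c in classes}
    C = len(classes)

    if strategy == "balanced_batch":
        if C > batch_size:
            logger.warning(
                "%d classes exceed batch_size=%d; rotating class coverage", C, batch_size
            )
        for b in range(n_batches):
            if C > batch_size:
                sel = classes[(np.arange(batch_size) + b * batch_size) % C]
                per = {c: 1 for c in sel}
            else:
                base, extra = divmod(batch_size, C)
                per = {
                    c: base + (1 if (i + b) % C < extra else 0) for i, c in enumerate(classes)
                }
            batch = np.concatenate(
                [rng.choice(members[c], size=k, replace=True) for c, k in per.items() if k]
            )
            yield batch[rng.permutation(len(batch))]
    elif strategy == "class_weight":
        # class weight 1/n_c spread over its n_c members: class marginals
        # equalize, so every class is drawn with the same probability
        w = (counts * (1.0 / counts)) / (counts * (1.0 / counts)).sum()
        for _ in range(n_batches):
            cls_draw = rng.choice(len(classes), size=batch_size, p=w)
            yield np.array([rng.choice(members[classes[c]]) for c in cls_draw])
    else:  # weighted_random
        freq = counts[np.searchsorted(classes, labels)]
        p = (1.0 / freq) / (1.0 / freq).sum()
        for _ in range(n_batches):
            yield rng.choice(n, size=batch_size, replace=True, p=p)


class _MLP:
    """Feed-forward log-softmax classifier head."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], n_out: int, dropout: float, seed: int):
        rng = np.random.default_rng(seed)
        layers: list[_nn.Layer] = []
        prev = n_in
        for h in hidden:
            layers += [_nn.Dense(prev, h, rng), _nn.ReLU(), _nn.Dropout(dropout, rng)]
            prev = h
        layers.append(_nn.Dense(prev, n_out, rng))
        self.net = _nn.Sequential(layers)

    def log_probs(self, x: np.ndarray, train: bool) -> np.ndarray:
        logits = self.net.forward(x, train)
        mx = logits.max(axis=1, keepdims=True)
        return (logits - mx) - np.log(np.exp(logits - mx).sum(axis=1, keepdims=True))

    def train_step(self, x: np.ndarray, y: np.ndarray, opt: _nn.AdamW, lr: float) -> float:
        lp = self.log_probs(x, train=True)
        loss = nll_loss(lp, y)
        grad = np.exp(lp)
        grad[np.arange(len(y)), y] -= 1.0
        grad /= len(y)
        _nn.zero_grads(self.net.params())
        self.net.backward(grad)
        opt.step(lr)
        return loss


class DDIClassifier:
    """Frozen encoder + fitted classification head."""

    def __init__(self, encoder: SmilesEncoder, enc_config: EncoderConfig, mlp: _MLP):
        self.encoder = encoder
        self.enc_config = enc_config
        self.mlp = mlp
        self._repr_cache: dict[str, np.ndarray] = {}

    def _representations(self, smiles: list[str]) -> np.ndarray:
        from . import tokenizer as tok

        missing = sorted({s for s in smiles if s not in self._repr_cache})
        if missing:
            vocab = tok.build_vocabulary()
            ids = tok.encode_batch(missing, vocab, self.enc_config.max_len)
            h = self.encoder.embed(ids, mode="representation")
            for s, row in zip(missing, h):
                self._repr_cache[s] = row
        return np.stack([self._repr_cache[s] for s in smiles])

    def features(self, examples: list[DDIExample]) -> np.ndarray:
        h1 = self._representations([ex.drug1_smiles for ex in examples])
        h2 = self._representations([ex.drug2_smiles for ex in examples])
        return featurize_pair(h1, h2)

    def predict_log_proba(self, examples: list[DDIExample]) -> np.ndarray:
        return self.mlp.log_probs(self.features(examples), train=False)

    def predict_proba(self, examples: list[DDIExample]) -> np.ndarray:
        p = np.exp(self.predict_log_proba(examples))
        return p / p.sum(axis=1, keepdims=True)


def train_and_evaluate(
    train: list[DDIExample],
    val: list[DDIExample],
    test: list[DDIExample],
    encoder: PretrainState | None,
    config: ClassifierConfig,
    seed: int,
    encoder_config: EncoderConfig | None = None,
) -> tuple[DDIClassifier, dict[str, MetricReport]]:
    """Fit the transfer classifier and report metrics per partition.

    The encoder is used as a frozen feature extractor; ``encoder=None`` is
    the un-pretrained ablation arm — a randomly initialized encoder of
    identical shape, also frozen. The epoch with the best validation
    weighted F1 is restored before reporting.
    """
    if not train or not val or not test:
        raise ConfigError("all partitions must be non-empty")
    C = config.n_classes
    for part in (train, val, test):
        if any(ex.label >= C for ex in part):
            raise ConfigError("label outside the configured class space")

    master = np.random.default_rng(seed)
    if encoder is not None:
        enc, enc_cfg = encoder.encoder, encoder.config
    else:
        enc_cfg = encoder_config or EncoderConfig()
        enc = SmilesEncoder(enc_cfg, seed=int(master.integers(0, 2**31 - 1)))

    if config.symmetrize_pairs:
        train = train + [DDIExample(ex.drug2_smiles, ex.drug1_smiles, ex.label) for ex in train]

    mlp = _MLP(
        2 * enc_cfg.repr_dim,
        config.hidden_dims,
        C,
        config.dropout,
        seed=int(master.integers(0, 2**31 - 1)),
    )
    clf = DDIClassifier(enc, enc_cfg, mlp)
    X_train = clf.features(train)
    y_train = np.array([ex.label for ex in train])
    X_val = clf.features(val)
    y_val = np.array([ex.label for ex in val])

    opt = _nn.AdamW(mlp.net.params(), weight_decay=config.weight_decay)
    sampler_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
    best_f1, best_state = -1.0, None
    for epoch in range(config.epochs):
        lr_t = _nn.cosine_annealed_lr(config.lr, epoch, config.epochs)
        epoch_seed = int(sampler_rng.integers(0, 2**31 - 1))
        for batch in make_sampler(y_train, config.sampler, config.batch_size, epoch_seed):
            mlp.train_step(X_train[batch], y_train[batch], opt, lr_t)
        lp_val = mlp.log_probs(X_val, train=False)
        p_val = np.exp(lp_val)
        p_val /= p_val.sum(axis=1, keepdims=True)
        f1 = classification_report(y_val, p_val).f1_weighted
        if f1 > best_f1:
            best_f1 = f1
            best_state = _nn.get_state(mlp.net.params())
    if best_state is not None:
        _nn.set_state(mlp.net.params(), best_state)

    reports = {}
    for name, part in (("train", train), ("val", val), ("test", test)):
        prob = clf.predict_proba(part)
        reports[name] = classification_report(np.array([ex.label for ex in part]), prob)
    return clf, reports


def load_pair_table(path: str, validate: bool = True) -> tuple[list[DDIExample], list[str]]:
    """Read a CSV/TSV pair table; returns examples and the label registry.

    Expects columns drug1_smiles, drug2_smiles and label (string labels are
    mapped through the returned sorted registry). Unparsable rows are
    skipped with a warning when ``validate`` is on.
    """
    sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    needed = {"drug1_smiles", "drug2_smiles", "label"}
    if not needed <= set(df.columns):
        raise SchemaError(f"pair table needs columns {sorted(needed)}, got {list(df.columns)}")
    registry = sorted(df["label"].astype(str).unique())
    to_idx = {lab: i for i, lab in enumerate(registry)}
    out: list[DDIExample] = []
    n_skipped = 0
    for _, row in df.iterrows():
        ex = DDIExample(row["drug1_smiles"], row["drug2_smiles"], to_idx[str(row["label"])])
        if validate:
            try:
                ex = ex.validated()
            except ParseError:
                n_skipped += 1
                logger.warning("skipping unparsable pair %r / %r", ex.drug1_smiles, ex.drug2_smiles)
                continue
        out.append(ex)
    if n_skipped:
        logger.warning("skipped %d unparsable pairs", n_skipped)
    return out, registry


def save_pair_table(examples: list[DDIExample], path: str, registry: list[str] | None = None) -> None:
    labels = [registry[ex.label] if registry else ex.label for ex in examples]
    pd.DataFrame(
        {
            "drug1_smiles": [ex.drug1_smiles for ex in examples],
            "drug2_smiles": [ex.drug2_smiles for ex in examples],
            "label": labels,
        }
    ).to_csv(path, index=False)
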