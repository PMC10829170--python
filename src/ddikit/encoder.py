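"""Contrastive SMILES representation model.

A token embedding followed by a stack of 1D convolutions encodes a padded
SMILES sequence into a fixed-width representation ``h`` (global max-pool over
positions, then a linear map). A two-layer projection head ``g`` maps ``h``
into the space where the InfoNCE contrastive objective is applied: each
molecule contributes two views — its canonical SMILES and one freshly
enumerated randomized SMILES — and the loss pulls the two views of a molecule
together while pushing apart all other views in the minibatch, with a
temperature scaling the cosine similarities. After pre-training, the
projection head is discarded and ``h`` is the transferable feature vector.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn, tokenizer as tok
from .chemio import MoleculeRecord, circular_fingerprint, enumerate_randomized, VIEW_CAP
from .errors import ConfigError, DegenerateVectorError, ShapeError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture and loss hyper-parameters for the contrastive encoder.

    Defaults: a 148-token vocabulary embedded at width 116, three
    convolutional blocks, a 262-wide representation and a 256->128
    projection head; temperature 0.5.
    """

    vocab_size: int = 148
    embed_dim: int = 116
    conv_channels: tuple[int, ...] = (128, 192, 256)
    kernel_sizes: tuple[int, ...] = (5, 5, 3)
    dropout: float = 0.1
    repr_dim: int = 262
    proj_dims: tuple[int, int] = (256, 128)
    temperature: float = 0.5
    max_len: int = tok.DEFAULT_MAX_LEN

    def __post_init__(self) -> None:
        if len(self.conv_channels) != len(self.kernel_sizes) or not self.conv_channels:
            raise ConfigError("conv_channels and kernel_sizes must align and be non-empty")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")


@dataclass
class ContrastiveBatch:
    """2m projected views plus the index of each view's positive partner."""

    projections: np.ndarray  # (2m, proj_dim)
    pair_index: np.ndarray  # involution without fixed points

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=np.float64)
        self.pair_index = np.asarray(self.pair_index, dtype=np.int64)
        n = self.projections.shape[0]
        idx = np.arange(n)
        if self.pair_index.shape != (n,):
            raise ShapeError("pair_index length must match number of views")
        if np.any(self.pair_index == idx) or np.any(self.pair_index[self.pair_index] != idx):
            raise ValueError("pair_index must be a fixed-point-free involution")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors, clamped to [-1, 1]."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ShapeError(f"vector lengths differ: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateVectorError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _info_nce_loss_and_grad(
    z: np.ndarray, pair_index: np.ndarray, temperature: float
) -> tuple[float, np.ndarray]:
    """Mean InfoNCE over all 2m ordered positive pairs, plus d(loss)/dz.

    Per anchor i with partner j: -log softmax over cosine similarities to all
    other views, scaled by the temperature; computed with max-subtracted
    log-sum-exp for stability.
    """
    n = z.shape[0]
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms == 0.0):
        raise DegenerateVectorError("zero-norm projection row")
    zn = z / norms[:, None]
    logits = (zn @ zn.T) / temperature
    np.fill_diagonal(logits, -np.inf)
    mx = logits.max(axis=1, keepdims=True)
    expd = np.exp(logits - mx)
    denom = expd.sum(axis=1)
    log_probs = (logits - mx) - np.log(denom)[:, None]
    loss = float(-log_probs[np.arange(n), pair_index].mean())
    # gradient: softmax minus the one-hot positive, averaged over anchors
    P = expd / denom[:, None]
    P[np.arange(n), pair_index] -= 1.0
    G = P / (n * temperature)
    dzn = G @ zn + G.T @ zn
    dz = (dzn - (dzn * zn).sum(axis=1, keepdims=True) * zn) / norms[:, None]
    return loss, dz


def info_nce_loss(batch: ContrastiveBatch, temperature: float) -> float:
    """InfoNCE loss of a batch of projected views (mean over ordered pairs)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if batch.projections.shape[0] < 2:
        raise ValueError("need at least 2 views")
    loss, _ = _info_nce_loss_and_grad(batch.projections, batch.pair_index, temperature)
    return loss


def top1_accuracy(z_anchor: np.ndarray, z_candidates: np.ndarray) -> float:
    """Fraction of anchors whose own partner is the strict nearest candidate.

    Row i of ``z_candidates`` is the positive partner of row i of
    ``z_anchor``; ties count as failures.
    """
    z_anchor = np.asarray(z_anchor, dtype=np.float64)
    z_candidates = np.asarray(z_candidates, dtype=np.float64)
    if z_anchor.shape[1] != z_candidates.shape[1]:
        raise ShapeError("anchor and candidate widths differ")
    if z_anchor.shape[0] != z_candidates.shape[0] or z_anchor.shape[0] < 2:
        raise ShapeError("need equal row counts m >= 2")
    na = np.linalg.norm(z_anchor, axis=1, keepdims=True)
    nc = np.linalg.norm(z_candidates, axis=1, keepdims=True)
    if np.any(na == 0) or np.any(nc == 0):
        raise DegenerateVectorError("zero-norm row")
    sims = (z_anchor / na) @ (z_candidates / nc).T
    m = sims.shape[0]
    own = sims[np.arange(m), np.arange(m)]
    other_max = np.where(np.eye(m, dtype=bool), -np.inf, sims).max(axis=1)
    return float(np.mean(own > other_max))


class SmilesEncoder:
    """Embedding + conv1D encoder e(.) and projection head g(.)."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        layers: list[_nn.Layer] = [_nn.Embedding(config.vocab_size, config.embed_dim, rng)]
        in_ch = config.embed_dim
        for ch, k in zip(config.conv_channels, config.kernel_sizes):
            layers += [
                _nn.Conv1d(in_ch, ch, k, rng),
                _nn.BatchNorm(ch),
                _nn.ReLU(),
                _nn.Dropout(config.dropout, rng),
            ]
            in_ch = ch
        layers += [_nn.GlobalMaxPool(), _nn.Dense(in_ch, config.repr_dim, rng)]
        self.encoder = _nn.Sequential(layers)
        p0, p1 = config.proj_dims
        self.projection = _nn.Sequential(
            [_nn.Dense(config.repr_dim, p0, rng), _nn.ReLU(), _nn.Dense(p0, p1, rng)]
        )

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[_nn.Param]:
        return self.encoder.params() + self.projection.params()

    def state(self) -> dict:
        bn_stats = [
            (layer.running_mean.copy(), layer.running_var.copy())
            for layer in self.encoder.layers
            if isinstance(layer, _nn.BatchNorm)
        ]
        return {"params": _nn.get_state(self.params()), "bn": bn_stats}

    def load_state(self, state: dict) -> None:
        _nn.set_state(self.params(), state["params"])
        bns = [l for l in self.encoder.layers if isinstance(l, _nn.BatchNorm)]
        for layer, (mu, var) in zip(bns, state["bn"], strict=True):
            layer.running_mean[...] = mu
            layer.running_var[...] = var

    # -- forward / backward -------------------------------------------------
    def _check_tokens(self, tokens: np.ndarray) -> np.ndarray:
        tokens = np.asarray(tokens)
        if tokens.ndim != 2 or tokens.shape[1] != self.config.max_len:
            raise ShapeError(
                f"token batch must be (n, {self.config.max_len}), got {tokens.shape}"
            )
        return tokens

    def embed(self, tokens: np.ndarray, mode: str = "representation") -> np.ndarray:
        """Evaluation-mode forward pass: ``h`` or the projected ``z``."""
        tokens = self._check_tokens(tokens)
        h = self.encoder.forward(tokens, train=False)
        if mode == "representation":
            return h
        if mode == "projection":
            return self.projection.forward(h, train=False)
        raise ValueError(f"unknown mode {mode!r}")

    def forward_train(self, tokens: np.ndarray) -> np.ndarray:
        tokens = self._check_tokens(tokens)
        h = self.encoder.forward(tokens, train=True)
        return self.projection.forward(h, train=True)

    def backward(self, dz: np.ndarray) -> None:
        self.encoder.backward(self.projection.backward(dz))


@dataclass
class PretrainState:
    """A pre-trained encoder, its per-epoch history and best checkpoint."""

    encoder: SmilesEncoder
    config: EncoderConfig
    history: list[dict] = field(default_factory=list)
    best_val_loss: float = float("inf")

    def embed_smiles(self, smiles_list: list[str], mode: str = "representation") -> np.ndarray:
        vocab = tok.build_vocabulary()
        ids = tok.encode_batch(smiles_list, vocab, self.config.max_len)
        return self.encoder.embed(ids, mode=mode)


def _view_pools(
    molecules: list[MoleculeRecord], rng: np.random.Generator, view_cap: int
) -> list[list[str]]:
    pools = []
    for rec in molecules:
        seed = int(rng.integers(0, 2**31 - 1))
        pools.append(enumerate_randomized(rec.smiles_canonical, view_cap, seed))
    return pools


def pretrain(
    molecules: list[MoleculeRecord],
    config: EncoderConfig,
    epochs: int,
    batch_size: int,
    seed: int,
    val_fraction: float = 0.2,
    lr: float = 1e-3,
    weight_decay: float = 1e-6,
    view_cap: int = VIEW_CAP,
) -> PretrainState:
    """Contrastively pre-train the encoder on a molecule library.

    Each epoch every training molecule contributes its canonical SMILES plus
    one randomized view drawn (seeded) from its enumeration pool of at most
    ``view_cap`` strings. Optimization is AdamW (decoupled weight decay) with
    a cosine-annealed learning rate; the validation molecules are the diverse
    side of a MaxMin split; the checkpoint with the lowest validation loss is
    retained. Fully reproducible under ``seed``.
    """
    from .splits import maxmin_split  # local import to avoid a cycle

    if len(molecules) < 2:
        raise ConfigError("need at least 2 molecules")
    if batch_size < 2:
        raise ConfigError("contrastive loss needs batch_size >= 2")

    master = np.random.default_rng(seed)
    model_seed = int(master.integers(0, 2**31 - 1))
    split_seed = int(master.integers(0, 2**31 - 1))
    pool_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
    epoch_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))

    vocab = tok.build_vocabulary()
    enc_cache: dict[str, np.ndarray] = {}

    def ids_of(s: str) -> np.ndarray:
        if s not in enc_cache:
            enc_cache[s] = tok.encode(s, vocab, config.max_len).ids
        return enc_cache[s]

    pools = _view_pools(molecules, pool_rng, view_cap)
    fps = [circular_fingerprint(m.smiles_canonical) for m in molecules]
    val_idx, train_idx = maxmin_split(fps, val_fraction, split_seed)
    val_idx, train_idx = sorted(val_idx), sorted(train_idx)
    if not train_idx or not val_idx:
        raise ConfigError("val_fraction leaves an empty partition")

    model = SmilesEncoder(config, seed=model_seed)
    state = PretrainState(encoder=model, config=config)
    if epochs == 0:
        return state

    opt = _nn.AdamW(model.params(), weight_decay=weight_decay)
    best_state = None

    def batch_views(indices: list[int], rng: np.random.Generator) -> np.ndarray:
        rows = []
        for i in indices:
            rows.append(ids_of(molecules[i].smiles_canonical))
            pool = pools[i]
            rows.append(ids_of(pool[rng.integers(0, len(pool))]))
        return np.stack(rows)

    def pair_index_for(m: int) -> np.ndarray:
        idx = np.arange(2 * m)
        return idx ^ 1  # views are interleaved canonical/randomized

    for epoch in range(epochs):
        lr_t = _nn.cosine_annealed_lr(lr, epoch, epochs)
        rng_e = np.random.default_rng(int(epoch_rng.integers(0, 2**31 - 1)))
        order = rng_e.permutation(len(train_idx))
        losses = []
        for start in range(0, len(order), batch_size):
            chunk = [train_idx[i] for i in order[start : start + batch_size]]
            if len(chunk) < 2:
                continue
            x = batch_views(chunk, rng_e)
            z = model.forward_train(x)
            loss, dz = _info_nce_loss_and_grad(z, pair_index_for(len(chunk)), config.temperature)
            _nn.zero_grads(model.params())
            model.backward(dz)
            opt.step(lr_t)
            losses.append(loss)
        # validation in evaluation mode, with an epoch-seeded view draw
        xv = batch_views(val_idx, rng_e)
        zv = model.embed(xv, mode="projection")
        val_loss, _ = _info_nce_loss_and_grad(zv, pair_index_for(len(val_idx)), config.temperature)
        acc = top1_accuracy(zv[0::2], zv[1::2])
        state.history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": float(val_loss),
                "acc_top1": float(acc),
                "lr": lr_t,
            }
        )
        if val_loss < state.best_val_loss:
            state.best_val_loss = float(val_loss)
            best_state = copy.deepcopy(model.state())
    if best_state is not None:
        model.load_state(best_state)
    return state


def export_embeddings(state: PretrainState, records: list[MoleculeRecord], path: str) -> None:
    """Write an id + repr_dim-column CSV of representations h."""
    import pandas as pd

    h = state.embed_smiles([r.smiles_canonical for r in records])
    df = pd.DataFrame(h, columns=[f"h{i}" for i in range(h.shape[1])])
    df.insert(0, "id", [r.id for r in records])
    df.to_csv(path, index=False)


def save_checkpoint(state: PretrainState, path: str) -> None:
    """Single-archive checkpoint: parameters, config, history, vocab hash."""
    import hashlib

    model_state = state.encoder.state()
    vocab_text = "\n".join(tok.build_vocabulary().tokens)
    meta = {
        "config": asdict(state.config),
        "history": state.history,
        "best_val_loss": state.best_val_loss,
        "vocab_sha1": hashlib.sha1(vocab_text.encode()).hexdigest(),
        "n_bn": len(model_state["bn"]),
    }
    arrays = {f"p{i}": v for i, v in enumerate(model_state["params"])}
    for i, (mu, var) in enumerate(model_state["bn"]):
        arrays[f"bn_mu{i}"] = mu
        arrays[f"bn_var{i}"] = var
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str) -> PretrainState:
    data = np.load(path if path.endswith(".npz") else path + ".npz", allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg_d = meta["config"]
    for k in ("conv_channels", "kernel_sizes", "proj_dims"):
        cfg_d[k] = tuple(cfg_d[k])
    config = EncoderConfig(**cfg_d)
    model = SmilesEncoder(config, seed=0)
    n_params = len(model.params())
    model.load_state(
        {
            "params": [data[f"p{i}"] for i in range(n_params)],
            "bn": [(data[f"bn_mu{i}"], data[f"bn_var{i}"]) for i in range(meta["n_bn"])],
        }
    )
    return PretrainState(
        encoder=model,
        config=config,
        history=meta["history"],
        best_val_loss=meta["best_val_loss"],
    )
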