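"""SMILES tokenization against a frozen 148-token vocabulary.

The vocabulary covers every element symbol of the periodic table, the
aromatic organic-subset symbols, ring-closure digits and SMILES punctuation
(including ``@`` and ``\\``), plus a dedicated pad token — 148 entries in
total, shipped as a versioned plain-text file so encodings are reproducible.

Tokenization is greedy longest-match: two-character element symbols such as
``Cl`` and ``Br`` consume two characters; everything else is one character.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import UnknownTokenError

logger = logging.getLogger(__name__)

PAD_TOKEN = "<pad>"
DEFAULT_MAX_LEN = 250


@dataclass(frozen=True)
class Vocabulary:
    tokens: tuple[str, ...]
    pad_index: int
    index_of: dict[str, int]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class TokenSequence:
    """One SMILES as a fixed-length padded integer id vector."""

    ids: np.ndarray
    length_unpadded: int
    source_smiles: str


def build_vocabulary() -> Vocabulary:
    """Load the frozen token list (line number = index)."""
    text = resources.files("ddikit.data").joinpath("vocab.txt").read_text()
    tokens = tuple(line for line in text.splitlines() if line)
    index_of = {t: i for i, t in enumerate(tokens)}
    if len(index_of) != len(tokens):
        raise RuntimeError("vocabulary file contains duplicate tokens")
    return Vocabulary(tokens=tokens, pad_index=index_of[PAD_TOKEN], index_of=index_of)


def tokenize(smiles: str, vocab: Vocabulary) -> list[str]:
    """Split a SMILES string into vocabulary tokens (greedy longest match)."""
    out: list[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        two = smiles[i : i + 2]
        if len(two) == 2 and two in vocab.index_of:
            out.append(two)
            i += 2
        elif smiles[i] in vocab.index_of:
            out.append(smiles[i])
            i += 1
        else:
            raise UnknownTokenError(
                f"character {smiles[i]!r} at position {i} of {smiles!r} "
                "is not in the vocabulary"
            )
    return out


def encode(smiles: str, vocab: Vocabulary, max_len: int = DEFAULT_MAX_LEN) -> TokenSequence:
    """Encode a SMILES to a padded (or truncated, prefix-kept) id vector."""
    if not smiles:
        raise ValueError("smiles must be non-empty")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    toks = tokenize(smiles, vocab)
    if len(toks) > max_len:
        logger.warning(
            "truncating SMILES of %d tokens to max_len=%d: %r", len(toks), max_len, smiles
        )
        toks = toks[:max_len]
    ids = np.full(max_len, vocab.pad_index, dtype=np.int64)
    for k, t in enumerate(toks):
        ids[k] = vocab.index_of[t]
    return TokenSequence(ids=ids, length_unpadded=len(toks), source_smiles=smiles)


def decode(seq: TokenSequence, vocab: Vocabulary) -> str:
    """Invert :func:`encode` (exact for non-truncated sequences)."""
    return "".join(vocab.tokens[i] for i in seq.ids[: seq.length_unpadded])


def encode_batch(
    smiles_list: list[str], vocab: Vocabulary, max_len: int = DEFAULT_MAX_LEN
) -> np.ndarray:
    """Encode many SMILES into an (n, max_len) id matrix."""
    return np.stack([encode(s, vocab, max_len).ids for s in smiles_list])
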