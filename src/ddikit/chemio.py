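"""SMILES parsing, canonicalization, enumeration, scaffolds, fingerprints and I/O.

All chemistry goes through RDKit; this module wraps it behind a small, typed
surface so the rest of the package never touches ``rdkit`` directly.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import ParseError, SchemaError

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Maximum number of enumerated SMILES views kept per molecule.
VIEW_CAP = 50


@dataclass(frozen=True)
class MoleculeRecord:
    """A molecule with its canonical SMILES and Bemis-Murcko scaffold.

    ``scaffold`` is the canonical SMILES of the ring-systems-plus-linkers
    framework; acyclic molecules get the empty string and form their own
    "no-scaffold" family downstream.
    """

    id: str
    smiles_canonical: str
    scaffold: str


@dataclass(frozen=True)
class Fingerprint:
    """A hashed circular (Morgan/ECFP-style) fingerprint as a dense bit array."""

    bits: np.ndarray  # uint8 vector of 0/1, length n_bits
    n_bits: int
    radius: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=np.uint8))
        if self.bits.shape != (self.n_bits,):
            raise ValueError("bits length does not match n_bits")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles:
        raise ParseError(f"not a non-empty SMILES string: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"could not parse SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES; equal for all encodings of one molecule."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def enumerate_randomized(smiles: str, n_requested: int, seed: int) -> list[str]:
    """Enumerate distinct randomized-atom-order SMILES for one molecule.

    Atom order is shuffled with a seeded RNG and the molecule re-emitted
    without canonicalization, so different orders can yield different strings.
    At most ``min(n_requested, VIEW_CAP)`` distinct strings are returned;
    every one canonicalizes back to ``canonicalize(smiles)``.
    """
    if n_requested < 1:
        raise ValueError("n_requested must be >= 1")
    mol = _mol_from_smiles(smiles)
    target = min(n_requested, VIEW_CAP)
    rng = np.random.default_rng(seed)
    n_atoms = mol.GetNumAtoms()
    seen: list[str] = []
    # Bounded retries: small/symmetric molecules admit few distinct strings.
    for _ in range(10 * target):
        perm = rng.permutation(n_atoms).tolist()
        shuffled = Chem.RenumberAtoms(mol, perm)
        s = Chem.MolToSmiles(shuffled, canonical=False)
        if s not in seen:
            seen.append(s)
        if len(seen) >= target:
            break
    return seen


def murcko_scaffold(smiles: str) -> str:
    """Canonical SMILES of the Bemis-Murcko scaffold; "" for acyclic input."""
    mol = _mol_from_smiles(smiles)
    core = MurckoScaffold.GetScaffoldForMol(mol)
    if core is None or core.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(core)


def circular_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Hashed circular fingerprint (ECFP-style; radius 2 / 2048 bits by default)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)
    return Fingerprint(bits=arr, n_bits=n_bits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity between two fingerprints."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprints have different lengths")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    return inter / union if union else 0.0


def record_from_smiles(smiles: str, mol_id: str) -> MoleculeRecord:
    """Canonicalize one SMILES and attach its scaffold."""
    canon = canonicalize(smiles)
    return MoleculeRecord(id=mol_id, smiles_canonical=canon, scaffold=murcko_scaffold(canon))


def load_molecule_table(path: str, smiles_column: str = "smiles") -> list[MoleculeRecord]:
    """Load molecules from CSV/TSV (named column) or a .smi file.

    Rows that fail canonicalization are skipped with a logged warning; the
    skip count is logged at the end. ``.smi`` files hold one SMILES per line
    with an optional whitespace-separated id.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    rows: list[tuple[str, str]] = []  # (id, smiles)
    if path.endswith((".smi", ".txt")):
        with open(path) as fh:
            for i, line in enumerate(fh):
                parts = line.split()
                if not parts:
                    continue
                rows.append((parts[1] if len(parts) > 1 else f"mol{i}", parts[0]))
    else:
        sep = "\t" if path.endswith((".tsv", ".tab")) else ","
        try:
            df = pd.read_csv(path, sep=sep)
        except pd.errors.EmptyDataError:
            return []
        if smiles_column not in df.columns:
            raise SchemaError(f"column {smiles_column!r} not in {list(df.columns)}")
        ids = df["id"].astype(str) if "id" in df.columns else pd.Series(
            [f"mol{i}" for i in range(len(df))]
        )
        rows = list(zip(ids, df[smiles_column].astype(str)))
    records: list[MoleculeRecord] = []
    n_skipped = 0
    for mol_id, smi in rows:
        try:
            records.append(record_from_smiles(smi, str(mol_id)))
        except ParseError:
            n_skipped += 1
            logger.warning("skipping unparsable SMILES %r (id=%s)", smi, mol_id)
    if n_skipped:
        logger.warning("skipped %d unparsable rows out of %d", n_skipped, len(rows))
    return records


def save_molecule_table(records: list[MoleculeRecord], path: str) -> None:
    """Write a canonicalized molecule table as CSV (id, smiles, scaffold)."""
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles_canonical for r in records],
            "scaffold": [r.scaffold for r in records],
        }
    ).to_csv(path, index=False)
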