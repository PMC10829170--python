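"""Synthetic scaffold-structured molecule libraries and DDI tables.

The generator emulates the structure the scaffold-centric analyses assume:
molecules come in scaffold families (a ring template decorated with small
substituents), and a drug pair's side-effect label is a deterministic
function of its scaffold combination — so scaffold-aware representations
carry genuine signal — with controllable geometric class imbalance and
label noise. Everything is reproducible under a seed and requires no
download.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chemio import MoleculeRecord, canonicalize, murcko_scaffold
from .classifier import DDIExample
from .errors import ConfigError

#: Ring templates, each defining one scaffold family.
DEFAULT_TEMPLATES: tuple[str, ...] = (
    "c1ccccc1",        # benzene
    "c1ccncc1",        # pyridine
    "c1ccc2ccccc2c1",  # naphthalene
    "C1CCCCC1",        # cyclohexane
    "C1CCNCC1",        # piperidine
    "c1ccsc1",         # thiophene
    "c1ccoc1",         # furan
    "c1ccc2ncccc2c1",  # quinoline
    "c1cncnc1",        # pyrimidine
    "C1CCOCC1",        # tetrahydropyran
)

#: Single-attachment substituents (attachment atom is atom 0 of the fragment).
SUBSTITUENTS: tuple[str, ...] = ("C", "N", "O", "F", "Cl", "OC", "CC", "C#N", "C(F)(F)F")


@dataclass(frozen=True)
class FixtureConfig:
    n_scaffold_families: int = 8
    per_family: int = 25
    scaffold_templates: tuple[str, ...] = DEFAULT_TEMPLATES
    n_classes: int = 6
    imbalance_decay: float = 0.5
    label_noise: float = 0.05
    n_pairs: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.imbalance_decay <= 1.0:
            raise ConfigError("imbalance_decay must be in (0, 1]")
        if not 0.0 <= self.label_noise < 1.0:
            raise ConfigError("label_noise must be in [0, 1)")
        if self.n_scaffold_families > len(self.scaffold_templates):
            raise ConfigError(
                f"{self.n_scaffold_families} families requested but only "
                f"{len(self.scaffold_templates)} templates available"
            )


def _attach(core: Chem.Mol, positions: tuple[int, ...], frags: tuple[str, ...]) -> str | None:
    """Attach substituent fragments at core atom positions; canonical SMILES or None."""
    mol = Chem.RWMol(core)
    for pos, frag_smiles in zip(positions, frags):
        frag = Chem.MolFromSmiles(frag_smiles)
        offset = mol.GetNumAtoms()
        mol = Chem.RWMol(Chem.CombineMols(mol, frag))
        mol.AddBond(pos, offset, Chem.BondType.SINGLE)
    try:
        out = mol.GetMol()
        Chem.SanitizeMol(out)
        return Chem.MolToSmiles(out)
    except Exception:
        return None


def _decoration_sites(core: Chem.Mol) -> list[int]:
    """Carbon atoms with at least one hydrogen: safe substitution points."""
    return [
        a.GetIdx()
        for a in core.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def generate_molecule_library(config: FixtureConfig) -> list[MoleculeRecord]:
    """Emit ``per_family`` distinct decorated molecules per scaffold template.

    Every emitted molecule's Murcko scaffold equals its template's canonical
    scaffold (substituents are acyclic, so the ring framework is preserved).
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records: list[MoleculeRecord] = []
    for fam, template in enumerate(config.scaffold_templates[: config.n_scaffold_families]):
        core = Chem.MolFromSmiles(template)
        if core is None:
            raise ConfigError(f"template does not parse: {template!r}")
        target_scaffold = murcko_scaffold(template)
        sites = _decoration_sites(core)
        if not sites:
            raise ConfigError(f"template {template!r} has no decoration site")
        emitted: set[str] = set()
        attempts = 0
        max_attempts = 200 * config.per_family
        while len(emitted) < config.per_family and attempts < max_attempts:
            attempts += 1
            k = int(rng.integers(1, min(3, len(sites)) + 1))
            positions = tuple(
                int(p) for p in rng.choice(sites, size=k, replace=False)
            )
            frags = tuple(SUBSTITUENTS[i] for i in rng.integers(0, len(SUBSTITUENTS), size=k))
            smiles = _attach(core, positions, frags)
            if smiles is None or smiles in emitted:
                continue
            if murcko_scaffold(smiles) != target_scaffold:
                continue
            emitted.add(smiles)
            records.append(
                MoleculeRecord(
                    id=f"f{fam}m{len(emitted) - 1}",
                    smiles_canonical=canonicalize(smiles),
                    scaffold=target_scaffold,
                )
            )
        if len(emitted) < config.per_family:
            raise ConfigError(
                f"template {template!r} yielded only {len(emitted)} distinct "
                f"molecules of {config.per_family} requested"
            )
    return records


def scaffold_pair_label_table(
    library: list[MoleculeRecord], config: FixtureConfig
) -> dict[tuple[str, str], int]:
    """Seeded lookup: unordered scaffold combination -> side-effect class.

    Every class receives at least one scaffold combination; raises when
    ``n_classes`` exceeds the number of available combinations.
    """
    scaffolds = sorted({r.scaffold for r in library})
    combos = list(itertools.combinations_with_replacement(scaffolds, 2))
    if config.n_classes > len(combos):
        raise ConfigError(
            f"{config.n_classes} classes but only {len(combos)} scaffold combinations"
        )
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(len(combos))
    return {combos[j]: i % config.n_classes for i, j in enumerate(order)}


def generate_ddi_dataset(
    library: list[MoleculeRecord], config: FixtureConfig
) -> list[DDIExample]:
    """Sample a synthetic DDI pair table from a scaffold-structured library.

    Class marginals follow the geometric profile decay^class (normalized);
    given a class, a scaffold combination mapped to it is drawn, then one
    molecule per family. The label is flipped to a uniformly random other
    class with probability ``label_noise``. Deterministic under seed.
    """
    if config.n_classes < 2:
        raise ConfigError("need at least 2 classes")
    table = scaffold_pair_label_table(library, config)
    by_class: dict[int, list[tuple[str, str]]] = {}
    for combo, cls in table.items():
        by_class.setdefault(cls, []).append(combo)
    members: dict[str, list[MoleculeRecord]] = {}
    for rec in library:
        members.setdefault(rec.scaffold, []).append(rec)
    probs = np.array([config.imbalance_decay**c for c in range(config.n_classes)])
    probs /= probs.sum()
    rng = np.random.default_rng(config.seed + 2)
    out: list[DDIExample] = []
    for _ in range(config.n_pairs):
        cls = int(rng.choice(config.n_classes, p=probs))
        combos = by_class[cls]
        s1, s2 = combos[rng.integers(0, len(combos))]
        m1 = members[s1][rng.integers(0, len(members[s1]))]
        m2 = members[s2][rng.integers(0, len(members[s2]))]
        if m1.id == m2.id and len(members[s2]) > 1:
            while m2.id == m1.id:
                m2 = members[s2][rng.integers(0, len(members[s2]))]
        if rng.random() < 0.5:
            m1, m2 = m2, m1
        label = cls
        if config.label_noise > 0 and rng.random() < config.label_noise:
            label = int((cls + 1 + rng.integers(0, config.n_classes - 1)) % config.n_classes)
        out.append(DDIExample(m1.smiles_canonical, m2.smiles_canonical, label))
    return out
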