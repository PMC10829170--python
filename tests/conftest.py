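"""Shared fixtures: a scaffold-structured library, DDI table and a smoke-pretrained encoder.

The expensive session fixtures define one set of desk-scale study conditions
used across the suite: a 264-molecule library over 8 scaffold families
(200 for pre-training, 64 held out), a 1200-pair DDI table with geometric
class imbalance and 5% label noise, and a 30-epoch contrastive smoke
pre-training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import ddikit as dk


@pytest.fixture(scope="session")
def vocab():
    return dk.build_vocabulary()


@pytest.fixture(scope="session")
def fixture_config():
    return dk.FixtureConfig(
        n_scaffold_families=8,
        per_family=33,
        n_classes=6,
        imbalance_decay=0.5,
        label_noise=0.05,
        n_pairs=1200,
        seed=0,
    )


@pytest.fixture(scope="session")
def molecule_library(fixture_config):
    """264 molecules over 8 scaffold families, shuffled with a fixed seed."""
    lib = dk.generate_molecule_library(fixture_config)
    order = np.random.default_rng(2026).permutation(len(lib))
    return [lib[i] for i in order]


@pytest.fixture(scope="session")
def ddi_pairs(molecule_library, fixture_config):
    return dk.generate_ddi_dataset(molecule_library, fixture_config)


@pytest.fixture(scope="session")
def smoke_encoder_config():
    """Desk-scale architecture: default embedding/representation widths,
    lighter convolution stack, short sequences."""
    return dk.EncoderConfig(
        conv_channels=(64, 96, 128), kernel_sizes=(5, 5, 3), max_len=48
    )


@pytest.fixture(scope="session")
def pretrain_molecules(molecule_library):
    return molecule_library[:200]


@pytest.fixture(scope="session")
def held_out_molecules(molecule_library):
    return molecule_library[200:264]


@pytest.fixture(scope="session")
def smoke_state(pretrain_molecules, smoke_encoder_config):
    """30-epoch contrastive smoke pre-training on 200 fixture molecules."""
    return dk.pretrain(
        pretrain_molecules, smoke_encoder_config, epochs=30, batch_size=32, seed=1
    )
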