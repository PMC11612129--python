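"""Shared fixtures: small phantom datasets and a quickly-trained micro model.

Everything is generated programmatically at test time; nothing is stored on
disk in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from sonodescribe.net import tiny_config, train
from sonodescribe.phantom import make_dataset, make_duplicates


@pytest.fixture(scope="session")
def small_manifest(tmp_path_factory):
    """Twelve phantoms with ground truth (no planted duplicates)."""
    out = tmp_path_factory.mktemp("phantoms")
    return make_dataset(12, seed=11, out_dir=out)


@pytest.fixture(scope="session")
def dup_manifest(tmp_path_factory):
    """Ten unique phantoms plus five planted rotated/zoomed copies."""
    out = tmp_path_factory.mktemp("phantoms_dup")
    manifest = make_dataset(10, seed=5, out_dir=out, extra_info_fraction=0.0)
    return make_duplicates(manifest, n_pairs=5, rotation_max=15.0,
                           zoom_range=(0.8, 1.2), conflict_fraction=0.4,
                           seed=99)


@pytest.fixture(scope="session")
def overfit_model(tmp_path_factory):
    """Tiny network memorizing 8 phantoms (seconds); used where any trained
    model will do (prediction plumbing, checkpoints, CLI describe)."""
    out = tmp_path_factory.mktemp("phantoms_overfit")
    manifest = make_dataset(8, seed=21, out_dir=out, extra_info_fraction=0.0)
    config = tiny_config(epochs=60, batch_size=8, lr=2e-3, seed=3)
    model, history = train(manifest, config)
    return manifest, model, history
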