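"""Shared fixtures: small synthetic datasets and tiny trunk configurations.

All image data is generated programmatically at test time; nothing binary is
checked in.  The tiny trunk (3 stages of 1 block, 8/16/32 channels) is the
standard test vehicle — architecture identical in kind to the full trunk,
scaled to CPU test budgets.
"""

import numpy as np
import pandas as pd
import pytest

from grainkit.dataio import load_manifest, make_split
from grainkit.network.backbone import BackboneConfig, init_params
from grainkit.synthetic import SyntheticDatasetSpec, default_styles, generate_dataset


@pytest.fixture(scope="session")
def tiny_config() -> BackboneConfig:
    return BackboneConfig.tiny()


@pytest.fixture(scope="session")
def tiny_params(tiny_config):
    return init_params(tiny_config, seed=0)


def _make_dataset(tmp_path_factory, name, n_classes, per_class, seed,
                  height_range=(64, 80), width_range=(96, 160)):
    styles = tuple(default_styles()[:n_classes])
    spec = SyntheticDatasetSpec(
        styles=styles,
        counts_per_class=(per_class,) * n_classes,
        height_range_px=height_range,
        width_range_px=width_range,
        seed=seed,
    )
    out = tmp_path_factory.mktemp(name)
    manifest_path = generate_dataset(spec, out)
    return load_manifest(manifest_path)


@pytest.fixture(scope="session")
def small_manifest(tmp_path_factory) -> pd.DataFrame:
    """3 species x 8 boards of heterogeneous rectangular sizes."""
    return _make_dataset(tmp_path_factory, "ds3x8", n_classes=3, per_class=8, seed=101)


@pytest.fixture(scope="session")
def small_plan(small_manifest):
    return make_split(small_manifest, k=4, test_fraction=0.2, seed=101)


@pytest.fixture(scope="session")
def medium_manifest(tmp_path_factory) -> pd.DataFrame:
    """3 species x 20 boards: the scaled-down end-to-end study conditions."""
    return _make_dataset(tmp_path_factory, "ds3x20", n_classes=3, per_class=20, seed=11)


@pytest.fixture(scope="session")
def medium_plan(medium_manifest):
    return make_split(medium_manifest, k=4, test_fraction=0.2, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
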