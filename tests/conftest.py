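import numpy as np
import pytest

import hep2cad as h
from hep2cad.config import RunConfig
from hep2cad.pipeline import train_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """A small labelled training dataset: 3 wells per pattern, seed 11."""
    out = tmp_path_factory.mktemp("trainset")
    cfg = RunConfig()
    cfg.seed = 11
    h.generate_dataset(
        {p: 3 for p in h.PATTERNS}, seed=11, out_dir=out, config=cfg.simulator
    )
    return out


@pytest.fixture(scope="session")
def tiny_bundle(tiny_dataset_dir):
    """A bundle trained on the tiny dataset (shared across tests)."""
    cfg = RunConfig()
    cfg.seed = 11
    cfg.classifier.seed = 11
    bundle, _ = train_bundle(tiny_dataset_dir, cfg)
    return bundle


@pytest.fixture(scope="session")
def tiny_test_dataset_dir(tmp_path_factory):
    """A disjoint-seed dataset for held-out classification checks."""
    out = tmp_path_factory.mktemp("testset")
    cfg = RunConfig()
    cfg.seed = 12
    h.generate_dataset(
        {p: 2 for p in h.PATTERNS}, seed=12, out_dir=out, config=cfg.simulator
    )
    return out
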