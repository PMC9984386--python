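import numpy as np
import pytest

from swinpoly.data import SyntheticSpec, generate_synthetic_dataset
from swinpoly.model import SwinConfig, SwinClassifier


def tiny_config(**overrides) -> SwinConfig:
    """A two-stage model small enough for sub-second CPU forwards."""
    kwargs = dict(input_size=32, patch_size=4, embed_dim=24, depths=(2, 2),
                  num_heads=(2, 4), window_size=4, num_classes=4,
                  in_channels=1)
    kwargs.update(overrides)
    return SwinConfig(**kwargs)


def micro_config(**overrides) -> SwinConfig:
    """A one-stage model for tests that only need a working classifier."""
    kwargs = dict(input_size=16, patch_size=4, embed_dim=8, depths=(2,),
                  num_heads=(2,), window_size=4, num_classes=4, in_channels=1)
    kwargs.update(overrides)
    return SwinConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_model() -> SwinClassifier:
    return SwinClassifier(tiny_config(), rng=0)


@pytest.fixture(scope="session")
def micro_model() -> SwinClassifier:
    return SwinClassifier(micro_config(), rng=0)


@pytest.fixture(scope="session")
def mini_dataset(tmp_path_factory):
    """A small rendered 4-class tree shared across data/pipeline tests."""
    spec = SyntheticSpec(
        images_per_class={"train": 6, "val": 2, "test": 4},
        image_size=64, seed=11)
    root = tmp_path_factory.mktemp("mini_oct")
    manifest = generate_synthetic_dataset(spec, root)
    return spec, root, manifest


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
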