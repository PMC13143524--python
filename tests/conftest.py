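import numpy as np
import pytest

from ocufusion.data import load_manifest
from ocufusion.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """48 synthetic images (8 per class), 64 px, mild nuisance."""
    root = tmp_path_factory.mktemp("synth48")
    manifest = generate_dataset(
        SyntheticSpec(n_per_class=8, image_size=64, seed=7, nuisance_strength=0.3),
        root,
    )
    return root, manifest


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """Nuisance-free dataset for signal-statistics checks (50 per class)."""
    root = tmp_path_factory.mktemp("synth_clean")
    manifest = generate_dataset(
        SyntheticSpec(n_per_class=50, image_size=64, seed=3, nuisance_strength=0.0),
        root,
    )
    return root, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


class ScriptedRNG:
    """Deterministic stand-in for a Generator: returns scripted draws."""

    def __init__(self, random_draws=(), uniform_draws=()):
        self._random = list(random_draws)
        self._uniform = list(uniform_draws)

    def random(self):
        return self._random.pop(0)

    def uniform(self, lo, hi, size=None):
        v = self._uniform.pop(0)
        return v


@pytest.fixture
def scripted_rng_factory():
    return ScriptedRNG
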