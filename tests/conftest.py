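"""Shared fixtures.

Trained toy models are expensive (minutes each), so a session-scoped cache
trains each (variant, seed) pair at most once; the learnability, ablation
and Grad-CAM localisation tests all draw from the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from leaffusionnet import experiments


class ToyRunCache:
    def __init__(self):
        self._data: dict[int, experiments.ToyData] = {}
        self._runs: dict[tuple[str, int], tuple] = {}

    def data(self, seed: int) -> experiments.ToyData:
        if seed not in self._data:
            self._data[seed] = experiments.prepare_toy_data(seed)
        return self._data[seed]

    def run(self, variant: str, seed: int):
        key = (variant, seed)
        if key not in self._runs:
            model, history, report, _ = experiments.train_toy_model(
                variant, seed=seed, data=self.data(seed))
            self._runs[key] = (model, history, report)
        return self._runs[key]


@pytest.fixture(scope="session")
def toy_runs() -> ToyRunCache:
    return ToyRunCache()


@pytest.fixture(scope="session")
def small_leaf_batch():
    """A small labelled batch of synthetic leaves (no training involved)."""
    from leaffusionnet.synthetic_leaves import generate_arrays
    X, y, masks = generate_arrays(6, image_side=64, seed=123)
    return X, y, masks


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
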