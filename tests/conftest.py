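import numpy as np
import pytest

from smartbed.classifier import ClassifierConfig
from smartbed.fuzzy import FuzzyEngine
from smartbed.preprocess import N_HOPB


@pytest.fixture(scope="session")
def engine() -> FuzzyEngine:
    """One shared default engine (full 8000-rule base)."""
    return FuzzyEngine()


class TemplatePosturePredictor:
    """Deterministic stand-in classifier for simulator tests: predicts by
    nearest clean posture template on the pooled grid (no training)."""

    def __init__(self, window_length: int = 5):
        from smartbed.preprocess import pool_frame
        from smartbed.synthetic import BodyParams, generate_frame

        self.config = ClassifierConfig(window_length=window_length)
        body = BodyParams(noise_sd=0.0)
        self._templates = np.stack([
            pool_frame(generate_frame(k, body, seed=0)).values for k in range(10)
        ])

    def predict(self, window: np.ndarray) -> int:
        mean_grid = np.asarray(window).mean(axis=0)
        scale = mean_grid.sum() / np.maximum(
            self._templates.sum(axis=(1, 2)), 1e-12)
        diffs = self._templates * scale[:, None, None] - mean_grid[None]
        return int(np.argmin((diffs ** 2).sum(axis=(1, 2))))


@pytest.fixture(scope="session")
def stub_classifier() -> TemplatePosturePredictor:
    return TemplatePosturePredictor()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def random_heats(rng) -> np.ndarray:
    """A heat sample with both zero and nonzero slats."""
    heats = rng.uniform(0.0, 30.0, N_HOPB)
    heats[rng.choice(N_HOPB, 4, replace=False)] = 0.0
    return heats
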