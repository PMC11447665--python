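import numpy as np
import pytest

from zonexplain import ModelAdapter, SpectraSet, Spectrum, ZoneSet
from zonexplain.zones import Zone


def make_zones(grid: np.ndarray, boundaries: list[int]) -> ZoneSet:
    """ZoneSet from interior boundary indices."""
    edges = [0, *boundaries, grid.size]
    zones = [
        Zone(lo=float(grid[a]), hi=float(grid[b - 1]), start=a, end=b)
        for a, b in zip(edges[:-1], edges[1:])
    ]
    return ZoneSet(zones=zones, grid=grid)


@pytest.fixture
def grid100() -> np.ndarray:
    return np.linspace(400.0, 1800.0, 100)


@pytest.fixture
def three_zones(grid100) -> ZoneSet:
    return make_zones(grid100, [30, 70])


@pytest.fixture
def instance(grid100) -> Spectrum:
    rng = np.random.default_rng(7)
    y = 0.5 + 0.3 * np.sin(grid100 / 100.0) + 0.05 * rng.standard_normal(100)
    return Spectrum(grid100, y, id="x")


@pytest.fixture
def reference(grid100) -> SpectraSet:
    rng = np.random.default_rng(11)
    mat = 0.4 + 0.1 * rng.standard_normal((6, 100))
    return SpectraSet(grid=grid100, matrix=mat, ids=[f"r{i}" for i in range(6)])


def constant_model(value: float = 0.3, n_classes: int = 2) -> ModelAdapter:
    probs = np.array([value] + [(1 - value) / (n_classes - 1)] * (n_classes - 1))

    def predict(X):
        return np.tile(probs, (len(X), 1))

    return ModelAdapter(predict_fn=predict,
                        class_names=[f"c{i}" for i in range(n_classes)])
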