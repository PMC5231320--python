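import numpy as np
import pytest

from ifcml.containers import CellRecord, ChannelImage, ImageSet
from ifcml.synthetic_cells import (
    Population,
    SimulationConfig,
    default_phase_params,
    generate_population,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phase_params():
    return default_phase_params()


def make_imageset(
    n: int,
    channels=("BF", "DF"),
    shape=(8, 8),
    rng=None,
    variable_shapes=False,
    labels=None,
) -> ImageSet:
    """Small random ImageSet for IO tests (not a cell model)."""
    rng = rng or np.random.default_rng(0)
    cells = []
    for i in range(n):
        if variable_shapes:
            h = int(rng.integers(4, 12))
            w = int(rng.integers(4, 12))
        else:
            h, w = shape
        chans = {
            ch: ChannelImage(ch, rng.uniform(size=(h, w))) for ch in channels
        }
        label = labels[i] if labels else None
        cells.append(CellRecord(f"cell{i:05d}", chans, label))
    return ImageSet(cells, list(channels))


@pytest.fixture(scope="session")
def small_population() -> Population:
    """A modest mixed-phase population shared across read-only tests."""
    cfg = SimulationConfig(
        counts={"Int": 20, "Pro": 6, "Meta": 4, "Ana": 4, "Telo": 5}, seed=11
    )
    return generate_population(cfg)
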