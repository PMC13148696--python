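import numpy as np
import pytest

from nichescape import (ClimateStack, GridTransform, OccurrenceSet,
                        make_landscape, simulate_tree)


@pytest.fixture
def small_stack():
    """10x10 two-layer stack on a 1-km grid, deterministic values."""
    rng = np.random.default_rng(42)
    layers = {
        "temperature": rng.normal(20, 3, (10, 10)),
        "precipitation": rng.normal(1000, 150, (10, 10)),
    }
    return ClimateStack(layers=layers, transform=GridTransform(0.0, 10.0, 1.0))


@pytest.fixture
def landscape():
    return make_landscape(60, 60, 3, seed=7)


@pytest.fixture
def tree10():
    return simulate_tree(10, seed=3)


def make_occ(points, species="spX"):
    """OccurrenceSet from (x, y) pairs with 3-decimal raw coordinates."""
    records = [(float(x), float(y), str(i)) for i, (x, y) in enumerate(points)]
    raw = [(f"{x:.3f}", f"{y:.3f}") for x, y in points]
    return OccurrenceSet(species_id=species, records=records, raw_coords=raw)
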