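import numpy as np
import pytest

from microtrack.simulate import SimConfig, emit_ground_truth, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def two_rod_labels(gap: int = 1) -> np.ndarray:
    """Two horizontal rods (9 px wide) separated by ``gap`` background rows:
    the canonical touching-cells fixture for weight-map contracts."""
    labels = np.zeros((40, 60), dtype=np.int32)
    labels[6:15, 8:52] = 1
    labels[15 + gap:24 + gap, 8:52] = 2
    return labels


@pytest.fixture
def two_cell_frame():
    return two_rod_labels(gap=1)


@pytest.fixture(scope="session")
def small_colony():
    """A rendered 30-frame colony reaching ~60 cells with >= 10 divisions,
    plus its ground truth (masks, tracking, lineage)."""
    cfg = SimConfig(seed=5, n_founders=16, n_frames=30, field_px=(256, 256))
    result = simulate(cfg)
    masks, tracking, lineage = emit_ground_truth(result)
    return result, masks, tracking, lineage


@pytest.fixture(scope="session")
def deep_colony():
    """A long two-founder movie whose lines reach 3-letter pole histories."""
    cfg = SimConfig(seed=3, n_founders=1, n_frames=68, field_px=(320, 320))
    result = simulate(cfg)
    masks, tracking, lineage = emit_ground_truth(result)
    return result, masks, tracking, lineage
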