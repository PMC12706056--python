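import numpy as np
import pytest

from polasym import geometry, synthetic_data as syn


@pytest.fixture(scope="session")
def straight_cell():
    """Plain 60x12 capsule with its medial axis."""
    mask, gt = syn.make_cell_mask(60, 12, 0, None, 0, seed=1)
    axis = geometry.compute_medial_axis(mask)
    return mask, gt, axis


@pytest.fixture(scope="session")
def constricted_cell():
    """80x14 capsule constricted to half width at relative position 0.55."""
    mask, gt = syn.make_cell_mask(80, 14, 0, 0.55, 0.5, seed=1)
    axis = geometry.compute_medial_axis(mask)
    return mask, gt, axis


@pytest.fixture(scope="session")
def snapshot_dataset():
    """Default 200-cell snapshot population (seeded)."""
    return syn.make_snapshot_dataset(200, seed=3)


def folded_position_error(rel_measured, rel_true):
    """Constriction-position error invariant to the arbitrary axis
    orientation of snapshot cells (pole identity is unassigned there)."""
    rel_measured = np.asarray(rel_measured, dtype=float)
    rel_true = np.asarray(rel_true, dtype=float)
    return np.minimum(np.abs(rel_measured - rel_true), np.abs(1.0 - rel_measured - rel_true))
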