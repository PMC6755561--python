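import numpy as np
import pytest

from cfscreen import data, synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic screening dataset shared by read-only tests."""
    cfg = synthetic.SimulationConfig(
        n_targets=40,
        n_ligands=200,
        true_rank=4,
        density=0.25,
        active_fraction=0.3,
        label_noise=0.05,
        seed=123,
    )
    truth = synthetic.simulate_ground_truth(cfg)
    matrix = synthetic.simulate_assays(truth, cfg)
    return cfg, truth, matrix


@pytest.fixture(scope="session")
def small_split(small_dataset):
    _, _, matrix = small_dataset
    return data.stratified_split(matrix, 0.3, seed=9)


def make_records(rows):
    """rows: iterable of (ligand, target, measure, value)."""
    return [data.AssayRecord(l, t, m, v) for l, t, m, v in rows]
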