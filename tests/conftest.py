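import numpy as np
import pandas as pd
import pytest

from chromdyn import SampleMatrix, SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at generator defaults, shared across tests."""
    return simulate_all(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down configuration for fast smoke tests."""
    return SimulationConfig(
        seed=5,
        peaks_per_archetype=40,
        n_static_peaks=80,
        depth=500_000.0,
        n_background_genes=60,
        n_decoy_gene_sets=2,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_all(small_cfg)


def make_matrix(values, conditions=None, totals=None, lengths=None):
    """Build a SampleMatrix from a plain array with generated metadata."""
    values = np.asarray(values, dtype=float)
    n_peaks, n_samples = values.shape
    sample_ids = [f"s{j}" for j in range(n_samples)]
    peak_ids = [f"p{i}" for i in range(n_peaks)]
    if conditions is None:
        conditions = ["c0"] * n_samples
    samples = pd.DataFrame(
        {"condition": conditions, "replicate": list(range(1, n_samples + 1))},
        index=sample_ids,
    )
    return SampleMatrix(
        values=pd.DataFrame(values, index=peak_ids, columns=sample_ids),
        samples=samples,
        totals=pd.Series(
            totals if totals is not None else np.ones(n_samples),
            index=sample_ids,
            dtype=float,
        )
        if totals is not None or (values < 0).any() or (values.sum(axis=0) <= 0).any()
        else None,
        lengths=None if lengths is None else pd.Series(lengths, index=peak_ids, dtype=float),
        nonnegative=bool((values >= 0).all()),
    )
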