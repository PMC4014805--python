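import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ldcontrast import GenotypeDataset, SimConfig, marker_table, simulate_pair

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def toy_dataset(dosages, population="POP1", chrom="1", spacing=1000,
                sample_prefix="s"):
    """Small dataset builder: dosages is an (n_samples, n_markers) list."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    markers = marker_table([
        (f"m{j}", chrom, (j + 1) * spacing, "A", "G") for j in range(m)
    ])
    ids = [f"{sample_prefix}{i}" for i in range(n)]
    return GenotypeDataset(ids, population, markers, d)


@pytest.fixture(scope="session")
def sim_pair_small():
    """A small simulated pair with one sweep; shared across tests."""
    cfg = SimConfig(
        n_samples=(80, 80), n_chromosomes=1, markers_per_chromosome=1500,
        sweeps=(), seed=11,
    )
    return simulate_pair(cfg)


@pytest.fixture(scope="session")
def sim_pair_sweep():
    """Simulated pair with the default 300-kb sweep, moderate size."""
    cfg = SimConfig(
        n_samples=(100, 100), n_chromosomes=1, markers_per_chromosome=4000,
        seed=7,
    )
    return simulate_pair(cfg)
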