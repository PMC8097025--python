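"""Shared fixtures: small synthetic datasets and a scan pool of 366 scans."""

import numpy as np
import pandas as pd
import pytest

from scndev.synthetic import SyntheticConfig, generate_dataset, generate_parcellation


@pytest.fixture(scope="session")
def pool_366():
    """366 single-scan participants with sorted random ages in 8.5-14.5."""
    rng = np.random.default_rng(42)
    ages = np.sort(rng.uniform(8.5, 14.5, 366))
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(366)],
            "scan_id": [f"S{i:03d}" for i in range(366)],
            "age": ages,
        }
    )


@pytest.fixture(scope="session")
def parcellation60():
    return generate_parcellation(n_regions=60, n_modules=7, seed=7)


@pytest.fixture(scope="session")
def default_dataset(parcellation60):
    """Default synthetic cohort (192 participants, ~366 scans, 60 regions)."""
    cfg = SyntheticConfig(seed=11)
    table, truth = generate_dataset(cfg, parcellation60)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_parcellation():
    return generate_parcellation(n_regions=20, n_modules=4, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_parcellation):
    """A small, fast cohort for pipeline-shaped tests."""
    cfg = SyntheticConfig(
        seed=5, n_regions=20, n_modules=4, n_participants=80, target_scans=150
    )
    table, truth = generate_dataset(cfg, small_parcellation)
    return cfg, table, truth
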