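"""Shared fixtures: small synthetic data built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from allokin.containers import VariantTable
from allokin.simulate import (
    AllotetraploidSpec,
    SimulationConfig,
    simulate_complex,
)


@pytest.fixture()
def toy_variant_table() -> VariantTable:
    """Five sites x four individuals exercising each filter rule.

    site 0: QUAL 150, fully covered            -> retained
    site 1: QUAL 90                            -> dropped (quality)
    site 2: QUAL 150 but triallelic            -> dropped (multiallelic)
    site 3: QUAL 150, 3/4 genotypes below DP 5 -> dropped (call rate 0.25)
    site 4: QUAL 100, half covered             -> retained (call rate 0.5)
    """
    sites = pd.DataFrame({
        "contig": [f"locus_{k}" for k in range(5)],
        "pos": 1,
        "ref": "A",
        "alt": ["T", "T", "T,G", "T", "T"],
        "qual": [150.0, 90.0, 150.0, 150.0, 100.0],
    })
    N = np.array([
        [20, 20, 20, 20],
        [20, 20, 20, 20],
        [20, 20, 20, 20],
        [2, 2, 2, 10],
        [20, 20, 0, 0],
    ])
    D = np.minimum(N, 5)
    return VariantTable(sites=sites, samples=["s1", "s2", "s3", "s4"],
                        N=N, D=D, eps=np.full(5, 0.001),
                        missing=np.zeros((5, 4), dtype=bool))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced complex for fast integration tests."""
    tets = [
        AllotetraploidSpec("T1", "A1", "B1", 100, 4),
        AllotetraploidSpec("T2", "B1", "A1", 2000, 4),
        AllotetraploidSpec("T3", "A2", "B2", 500, 4),
    ]
    return SimulationConfig(
        n_loci=800, n_ind=4, tets=tets,
        f_is={"A1": 0.1, "B1": 0.3},
        invariant_sites=5000, plastid_sites=120, depth=80.0)


@pytest.fixture(scope="session")
def small_complex(small_config):
    return simulate_complex(small_config, seed=11)
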