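"""Shared fixtures.

The Monte Carlo trajectories are expensive, so they are generated once per
session and reused by every test that only needs sampled configurations.
"""

from __future__ import annotations

import numpy as np
import pytest

from idpbench.bead_necklace import SimulationConfig, run_simulation
from idpbench.dataset import load_benchmark
from idpbench.sequence_props import assign_charges
from idpbench.synthetic import SequenceSpec, make_sequence

#: Histatin 5, the 24-residue salivary peptide the bead-necklace model was
#: originally parametrized on
HST5_SEQUENCE = "DSHAKRHHGYKRKFHEKHHSHRGY"


@pytest.fixture(scope="session")
def benchmark():
    return load_benchmark()


@pytest.fixture(scope="session")
def charged50():
    """Synthetic 50-mer with FCR = NCPR = 0.5 (a Prothymosin-alpha-like polyelectrolyte)."""
    seq = make_sequence(SequenceSpec(length=50, target_fcr=0.5, target_ncpr=0.5, seed=11))
    return assign_charges(seq).per_bead_charge


@pytest.fixture(scope="session")
def salt_runs(charged50):
    """Two replicates of the charged 50-mer at 0 mM and at 150 mM salt."""
    out = {}
    for salt in (0.0, 150.0):
        out[salt] = [
            run_simulation(
                charged50,
                SimulationConfig(
                    salt_mM=salt,
                    n_equil_cycles=1500,
                    n_prod_cycles=5000,
                    sample_interval=10,
                    seed=100 + rep,
                ),
            )
            for rep in range(2)
        ]
    return out


@pytest.fixture(scope="session")
def hst5_run():
    """Bead-necklace trajectory of Histatin 5 at 150 mM, pH 7."""
    charges = assign_charges(HST5_SEQUENCE).per_bead_charge
    config = SimulationConfig(
        salt_mM=150.0, n_equil_cycles=2000, n_prod_cycles=15000, sample_interval=10, seed=42
    )
    return run_simulation(charges, config)


@pytest.fixture(scope="session")
def phantom_run():
    """Neutral 10-mer with interactions switched off: ideal-chain statistics."""
    config = SimulationConfig(
        bead_radius=0.01,
        ion_radius=0.01,
        attraction_contact=0.0,
        salt_mM=0.0,
        n_equil_cycles=2000,
        n_prod_cycles=30000,
        sample_interval=10,
        seed=3,
    )
    return run_simulation([0] * 10, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
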