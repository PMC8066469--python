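import numpy as np
import pandas as pd
import pytest

from coupledomics.io_tables import CountTable, ProteinRecord, SampleMeta
from coupledomics.simulate import SimulationConfig, simulate


@pytest.fixture
def four_protein_records():
    """Worked evidence-filter fixture: unique peptides (1,2,3,2),
    probabilities (0.95, 0.99, 0.90, 0.95)."""
    runs = {"r1": 3.0, "r2": 5.0}
    return [
        ProteinRecord("P1", 300, 0.95, 1, dict(runs)),
        ProteinRecord("P2", 300, 0.99, 2, dict(runs)),
        ProteinRecord("P3", 300, 0.90, 3, dict(runs)),
        ProteinRecord("P4", 300, 0.95, 2, dict(runs)),
    ]


@pytest.fixture
def proteome_meta():
    """Six metaproteome runs: two biological samples x triplicate injections."""
    metas = []
    for tank, day in (("T1", 1), ("T2", 1)):
        group = f"s_{tank}"
        for rep in range(1, 4):
            metas.append(
                SampleMeta(
                    sample_id=f"{group}_r{rep}",
                    day=day,
                    treatment="pH8.2",
                    tank=tank,
                    layer="metaproteome",
                    tech_replicate_group=group,
                )
            )
    return metas


@pytest.fixture
def taxon_table():
    data = pd.DataFrame(
        {"s1": [2.0, 3.0, 5.0], "s2": [1.0, 1.0, 2.0]},
        index=["Alphaproteobacteria", "Flavobacteriia", "Cytophagia"],
    )
    return CountTable(data=data, layer="metagenome", feature_kind="taxon")


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated dataset shared across tests (read-only)."""
    cfg = SimulationConfig.default(seed=7, n_reads=50_000, n_psm=8_000)
    return simulate(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
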