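import numpy as np
import pandas as pd
import pytest

from qsiplab.simulate import simulate_experiment, tiny_config
from qsiplab.tables import FractionMetadata, OTUTable


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small simulated experiment shared across tests (8 taxa + 2 contaminants,
    one substrate with and without H2, 3+3 replicates)."""
    return simulate_experiment(tiny_config(seed=42))


@pytest.fixture()
def toy_metadata():
    """Hand-built metadata: one comparison, 2 replicates x 2 arms x 3 fractions."""
    rows = []
    for label in ("13C", "control"):
        for rep in (1, 2):
            for k, dens in enumerate([1.68, 1.70, 1.72]):
                rows.append(dict(
                    sample_id=f"{label}_r{rep}_f{k}", treatment=f"bicarbonate_{label}",
                    substrate="bicarbonate", h2=False, label=label, replicate=rep,
                    fraction=k, density_g_ml=dens, qpcr_copies=1000.0,
                ))
    return FractionMetadata(pd.DataFrame(rows))


@pytest.fixture()
def toy_table(toy_metadata):
    sample_ids = toy_metadata.sample_ids
    rng = np.random.default_rng(0)
    counts = rng.integers(20, 100, size=(3, len(sample_ids)))
    return OTUTable([f"OTU_{i}" for i in range(1, 4)], sample_ids, counts)
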