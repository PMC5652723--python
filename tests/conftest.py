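import numpy as np
import pandas as pd
import pytest

from cistrome_compare import synthetic


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic dataset at the default study conditions."""
    return synthetic.simulate(synthetic.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def true_affinities(default_sim):
    """Genes x cell-lines 0/1 matrix built from the planted target sets."""
    universe = [g.gene_id for g in default_sim.genes]
    return pd.DataFrame(
        {
            line: np.array([g in targets for g in universe], dtype=np.int8)
            for line, targets in default_sim.truth.true_targets.items()
        },
        index=pd.Index(universe, name="gene_id"),
    )
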