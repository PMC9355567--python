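import numpy as np
import pandas as pd
import pytest

from barfit import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    return sim.simulate_study(
        sim.EvolutionConfig(n_populations=3,
                            generations=(1500, 4500, 7500, 9000)),
        sim.EffectConfig(n_mutations=20, n_neutral=5),
        sim.AssaySimConfig(n_barcodes_per_mutation=10, depth=60_000,
                           n_timepoints=5),
        seed=11,
    )


@pytest.fixture
def toy_counts():
    """Four lineages over four timepoints with comfortable totals."""
    filler = pd.DataFrame(
        {t: [3000, 3000] for t in range(4)}, index=["fill_a", "fill_b"]
    )
    lineages = pd.DataFrame(
        {
            0: [100, 100, 100, 3],
            1: [200, 100, 110, 0],
            2: [400, 100, 95, 50],
            3: [800, 100, 105, 100],
        },
        index=["doubling", "flat", "noisyflat", "late"],
    )
    return pd.concat([lineages, filler])
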