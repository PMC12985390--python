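import numpy as np
import pandas as pd
import pytest

from cfends import io_core, synthetic_data


@pytest.fixture(scope="session")
def toy_genome():
    """20-bp single-contig genome used for hand-checked motif examples."""
    return io_core.ReferenceGenome({"chr1": "AACCGGTTACGTAACCGGTT"})


@pytest.fixture(scope="session")
def sim_genome():
    cfg = synthetic_data.SimulationConfig(seed=101, genome_length=60_000)
    return synthetic_data.simulate_reference(cfg)


@pytest.fixture(scope="session")
def random_fragments(sim_genome):
    """2,000 random fragments on both strands of the simulated genome."""
    rng = np.random.default_rng(7)
    n = 2000
    L = sim_genome.lengths["sim1"]
    sizes = rng.integers(20, 400, n)
    starts = rng.integers(8, L - sizes - 8)
    return pd.DataFrame(
        {
            "chrom": "sim1",
            "start": starts,
            "end": starts + sizes,
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
        }
    )
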