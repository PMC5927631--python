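import numpy as np
import pytest

from clonaltiming import synthetic


@pytest.fixture(scope="session")
def gain_truth():
    """A clonal patient with a timed region gain, moderate depth, two regions."""
    return synthetic.single_clone_truth(
        rate=87.0,
        age=40.0,
        purity=0.9,
        depth=150,
        t_dup=20.0,
        region_length=4.0e8,
        samples=("R1", "R2"),
    )


@pytest.fixture(scope="session")
def gain_tables(gain_truth):
    return synthetic.simulate_mutation_table(gain_truth, seed=11)


@pytest.fixture(scope="session")
def two_clone_tables():
    truth = synthetic.two_clone_truth(
        rate=20.0,
        age=60.0,
        mrca_age=40.0,
        subclone_ccf=0.4,
        purity=1.0,
        depth=100,
        t_dup=None,
        samples=("R1",),
    )
    table, cn = synthetic.simulate_mutation_table(truth, seed=3)
    return truth, table, cn


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
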