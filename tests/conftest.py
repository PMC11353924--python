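import numpy as np
import pandas as pd
import pytest

import fermflavor as ff


@pytest.fixture(scope="session")
def design():
    return ff.StageDesign()


@pytest.fixture(scope="session")
def small_design():
    return ff.StageDesign(stages=("S1", "S2", "S3"), replicates_per_stage=2)


@pytest.fixture(scope="session")
def community(design):
    """One deterministic simulated community (modest size, 9 x 3 samples)."""
    params = ff.CommunitySimParams(n_otus=80, library_size_mean=4000)
    return ff.generate_otu_experiment(design, params, seed=11)


@pytest.fixture(scope="session")
def flavor(design, community):
    otus, _ = community
    params = ff.FlavorSimParams(n_compounds=15, linked_pairs=[(5, 3, 0.9)])
    return ff.generate_flavor_experiment(design, otus, params, seed=12)


@pytest.fixture()
def toy_content():
    values = pd.DataFrame(
        {"S1": [10.0, 20.0, 5.0], "S2": [0.0, 4.0, 2.0]},
        index=["ald_a", "ald_b", "est_a"],
    )
    records = [
        ff.CompoundRecord("ald_a", "aldehyde", threshold=2.0),
        ff.CompoundRecord("ald_b", "aldehyde", threshold=10.0),
        ff.CompoundRecord("est_a", "ester", threshold=None),
    ]
    return ff.ContentMatrix(values=values), records
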