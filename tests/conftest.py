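import numpy as np
import pytest

from surprisep3 import synthetic as syn


@pytest.fixture(scope="session")
def small_truth():
    return syn.make_ground_truth(4, seed=20240)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    cmo, sst = syn.cohort_sequences(small_truth)
    return {"truth": small_truth, "cmo": cmo, "sst": sst}


@pytest.fixture(scope="session")
def subject0_epochs(small_cohort):
    t = small_cohort["truth"]
    return syn.gen_subject_epochs(t, 0, small_cohort["cmo"][0], small_cohort["sst"][0])


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
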