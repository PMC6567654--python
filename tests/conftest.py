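"""Shared fixtures: synthetic datasets and trained classifiers.

Training the small CNNs is the expensive part of the suite, so one
on-target and one off-target model are fitted once per session and reused
wherever a trained classifier is needed.
"""

import numpy as np
import pytest

from cpf1kit import synthetic
from cpf1kit.model import Cpf1ActivityModel, Cpf1OffTargetModel


@pytest.fixture(scope="session")
def on_target_records():
    return synthetic.simulate_on_target(synthetic.GeneratorConfig(n=1000, seed=11))


@pytest.fixture(scope="session")
def activity_results(on_target_records):
    model = Cpf1ActivityModel.from_records(on_target_records)
    return model.fit(epochs=15, seed=11)


@pytest.fixture(scope="session")
def mismatch_records():
    return synthetic.simulate_mismatch(synthetic.GeneratorConfig(n=2000, seed=12))


@pytest.fixture(scope="session")
def offtarget_results(mismatch_records):
    model = Cpf1OffTargetModel.from_records(mismatch_records)
    return model.fit(epochs=15, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_sequence(rng, length=27, pam=True):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    if pam:
        seq = "TTT" + seq[3:]
    return seq
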