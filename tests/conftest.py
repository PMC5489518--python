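import numpy as np
import pytest

from wolfselect.data import Dataset
from wolfselect.fitness import FitnessEvaluator
from wolfselect.synth import SynthSpec, generate


@pytest.fixture(scope="session")
def tiny_dataset() -> Dataset:
    """3x2 toy dataset with string labels."""
    X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    return Dataset(X, np.array(["A", "B", "A"]), ["f1", "f2"], name="tiny")


@pytest.fixture(scope="session")
def easy_synth():
    """Strong-signal synthetic dataset: 30 features, 5 informative, delta=2.5."""
    spec = SynthSpec(n_samples=100, n_features=30, n_informative=5,
                     effect_size=2.5, n_redundant=3, seed=11)
    return generate(spec)


@pytest.fixture(scope="session")
def oracle_problem():
    """8-feature dataset (3 informative, delta=3) small enough to enumerate."""
    spec = SynthSpec(n_samples=100, n_features=8, n_informative=3,
                     effect_size=3.0, n_redundant=0, seed=5)
    return generate(spec)


@pytest.fixture(scope="session")
def oracle_evaluator(oracle_problem) -> FitnessEvaluator:
    ds, _ = oracle_problem
    return FitnessEvaluator(ds, scheme="kfold", k=3, elm_seed=7, split_seed=7)
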