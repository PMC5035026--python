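import numpy as np
import pytest

from antioxpred.io_formats import ProteinRecord, PssmMatrix, RsaAnnotation, SsAnnotation
from antioxpred import synthetic_data as sim


@pytest.fixture
def record4():
    return ProteinRecord("p1", "ACDE")


@pytest.fixture
def tiny_bundle():
    """A 10+10 bundle with the default class signal, small and fast."""
    config = sim.shifted_config(n_pos=10, n_neg=10, length_range=(20, 40), seed=7)
    return sim.generate(config)


@pytest.fixture
def separable_xy():
    """A trivially separable 2-feature binary problem."""
    rng = np.random.default_rng(0)
    n = 40
    y = np.repeat([0, 1], n // 2)
    X = np.column_stack([y + 0.01 * rng.normal(size=n), rng.normal(size=n)])
    return X, y


def make_pssm(sequence: str, scores=None) -> PssmMatrix:
    if scores is None:
        scores = np.zeros((len(sequence), 20), dtype=int)
    return PssmMatrix(sequence, np.asarray(scores, dtype=int))
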