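import itertools

import numpy as np
import pytest

from lesionfuse import ClassCatalog, PredictionMatrix, WeightMatrix

MODELS = ("m1", "m2", "m3")


@pytest.fixture
def catalog() -> ClassCatalog:
    return ClassCatalog()


@pytest.fixture
def published_weights(catalog) -> WeightMatrix:
    """The three-network per-class F1 weight matrix used in worked examples."""
    return WeightMatrix.from_dict(
        {
            "m1": {"mel": 0.82, "nv": 0.90, "bcc": 0.85, "bkl": 0.67},
            "m2": {"mel": 0.85, "nv": 0.91, "bcc": 0.89, "bkl": 0.74},
            "m3": {"mel": 0.85, "nv": 0.92, "bcc": 0.86, "bkl": 0.63},
        },
        catalog,
    )


def one_hot_matrix(catalog: ClassCatalog, votes: tuple[str, ...]) -> PredictionMatrix:
    """PredictionMatrix with one one-hot row per vote, models m1..mN."""
    rows = np.zeros((len(votes), len(catalog)))
    for i, v in enumerate(votes):
        rows[i, catalog.index(v)] = 1.0
    return PredictionMatrix(catalog, MODELS[: len(votes)], rows)


def all_hard_vote_combos(catalog: ClassCatalog, n_models: int = 3):
    """All K^n hard-decision vote combinations (4^3 = 64 by default)."""
    return list(itertools.product(catalog.labels, repeat=n_models))
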