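"""Shared fixtures: small synthetic corpora and a cheaply trained model."""

import numpy as np
import pytest

from anochem import synthdata
from anochem.anomaly import AutoencoderSpec
from anochem.model import AnoChem


@pytest.fixture(scope="session")
def fixture_smiles():
    return synthdata.load_fixture_smiles()


@pytest.fixture(scope="session")
def tiny_corpus():
    """Desk-scale corpus kept deliberately small for unit tests."""
    return synthdata.benchmark_corpus(1, n_real=150, n_generated=150, min_window_yield=30)


@pytest.fixture(scope="session")
def tiny_results(tiny_corpus):
    """A fully fitted (but minimally tuned) three-stage model."""
    model = AnoChem(
        tiny_corpus.real,
        tiny_corpus.generated,
        ae_grid=[AutoencoderSpec(layer_widths=(256, 64), max_epochs=12)],
        families=("gbt", "logreg"),
        search_spaces={
            "gbt": {
                "n_estimators": [50], "learning_rate": [0.3], "max_depth": [4],
                "min_child_weight": [1], "subsample": [1.0],
                "colsample_bytree": [1.0], "gamma": [0.0],
            },
            "logreg": {"penalty": ["l2"], "solver": ["lbfgs"], "max_iter": [500], "C": [1.0]},
        },
    )
    return model.fit(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
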