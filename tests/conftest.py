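from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from methdrift.simulate import generate_dataset, preset_config


@pytest.fixture(scope="session")
def null_dataset():
    """Small no-effect synthetic dataset shared across tests."""
    return generate_dataset(preset_config("null", seed=11, n_genes=600))


@pytest.fixture(scope="session")
def drift_dataset():
    """Small dataset with planted age-related methylation drift."""
    return generate_dataset(preset_config("drift", seed=11, n_genes=600))


@pytest.fixture(scope="session")
def tes_dataset():
    """Small dataset with planted density and 3'-localisation effects."""
    return generate_dataset(preset_config("tes_effect", seed=11, n_genes=600))


@pytest.fixture(scope="session")
def expr_classes(tes_dataset):
    from methdrift import subdomain

    classes = subdomain.classify_expression_table(tes_dataset.expression)
    classes.index = pd.Index(tes_dataset.expression["gene_id"])
    return classes
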