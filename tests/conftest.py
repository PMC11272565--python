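import numpy as np
import pandas as pd
import pytest

import stromapat as sp
import stromapat.synthetic as syn


@pytest.fixture(scope="session")
def planted_basis():
    """900-gene, 6-pattern planted basis: 180 markers + 720 background genes."""
    W_true, assignment = sp.generate_patterns(
        n_genes=900, k=6, markers_per_pattern=30, background_level=0.05, seed=1)
    return W_true, assignment


@pytest.fixture(scope="session")
def planted_expression(planted_basis):
    """Expression with 10% relative noise on the planted patterns."""
    W_true, _ = planted_basis
    noiseless, _ = syn.generate_expression_matrix(W_true, 60, noise_sd=0.0, seed=1)
    sig = float(noiseless.to_numpy().std())
    X, H_true = syn.generate_expression_matrix(W_true, 60, noise_sd=0.1 * sig,
                                               seed=1)
    return X, H_true


@pytest.fixture(scope="session")
def reference_panel():
    """Methylation reference: 3 cell types, planted informative loci."""
    panel, informative = sp.generate_reference_methylation(
        n_loci=2000, cell_types=["cancer", "stromal", "immune"],
        n_informative=200, profiles_per_type=20, delta=0.5, noise_sd=0.03,
        seed=7)
    return panel, informative


@pytest.fixture
def toy_survival():
    """Six subjects, events at t=1..6, first three in group A."""
    return pd.DataFrame({
        "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "event": [1, 1, 1, 1, 1, 1],
        "group": ["A", "A", "A", "B", "B", "B"],
    })
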