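import numpy as np
import pandas as pd
import pytest

from metaphenet import SyntheticConfig

# Printed centrality rows for the condition-associated genes (betweenness,
# degree) and the published network-wide means they are summarized against.
TABLE2_ROWS = {
    "glycine": [
        ("4.3.1.1", 0.0320, 6),
        ("1.1.1.30", 0.0176, 4),
        ("3.1.1.75", 0.0081, 4),
        ("2.6.1.66", 0.0064, 3),
        ("1.1.1.36", 0.0026, 2),
        ("3.1.1.22", 0.0006, 2),
        ("2.8.3.5", 0.0000, 2),
        ("3.2.1.22", 0.0000, 1),
    ],
    "wet": [
        ("1.2.1.60", 0.0035, 8),
        ("4.1.3.1", 0.0142, 4),
        ("1.1.1.42", 0.0031, 6),
    ],
    "dry": [
        ("5.4.99.15", 0.0089, 6),
        ("2.2.1.1", 0.0532, 21),
        ("5.4.99.16", 0.0303, 10),
        ("6.5.1.1", 0.0180, 9),
        ("3.2.1.141", 0.0156, 9),
        ("5.4.2.6", 0.0108, 17),
        ("3.4.11.5", 0.0157, 6),
        ("2.7.1.29", 0.0001, 2),
    ],
}
NETWORK_MEAN_BETWEENNESS = 0.006
NETWORK_MEAN_DEGREE = 3.72


@pytest.fixture
def table2():
    rows = []
    labels: dict[str, set[str]] = {}
    for cond, entries in TABLE2_ROWS.items():
        labels[cond] = {ec for ec, _, _ in entries}
        for ec, b, d in entries:
            rows.append({"gene": ec, "betweenness": b, "degree": d})
    table = pd.DataFrame(rows).set_index("gene")
    return table, labels


@pytest.fixture
def small_config():
    """Compact synthetic study used by fast end-to-end tests."""
    return SyntheticConfig(
        seed=7,
        n_genes=120,
        n_metabolites=50,
        n_reactions=60,
        n_modules=3,
        module_size=8,
        pathway_length=3,
        n_core_metabolites=12,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
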