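import numpy as np
import pandas as pd
import pytest

from scmalig import GeneratorConfig, LabeledExpressionMatrix, synthgen


def make_matrix(values, labels, genes=None, cells=None, **kw):
    """Small hand-built LabeledExpressionMatrix for unit tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    return LabeledExpressionMatrix(
        values=values,
        gene_names=pd.Index(genes or [f"G{i}" for i in range(n_genes)]),
        cell_ids=pd.Index(cells or [f"c{i}" for i in range(n_cells)]),
        labels=np.asarray(labels, dtype=object),
        **kw,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """300-cell cohort, 3 informative + 250 noise genes, 20% malignant."""
    cfg = GeneratorConfig(
        n_malignant=60,
        n_normal=240,
        informative_genes=(("INF1", 0.95, "up"), ("INF2", 0.85, "up"),
                           ("INF3", 0.75, "down")),
        n_noise_genes=250,
        seed=123,
    )
    return synthgen.generate(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
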