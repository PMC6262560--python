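import numpy as np
import pandas as pd
import pytest

from heatmod import preprocess as pp
from heatmod import synthetic_data as sd
from heatmod.preprocess import FoldTable


def make_fold_table(values, genes=None, detected_control=None, detected_treated=None):
    """Build a FoldTable from raw fold values (helper for unit tests)."""
    values = np.asarray(values, dtype=float)
    if genes is None:
        genes = [f"g{i}" for i in range(values.size)]
    table = pd.DataFrame(
        {
            "log2_fold": values,
            "detected_control": detected_control
            if detected_control is not None
            else [True] * values.size,
            "detected_treated": detected_treated
            if detected_treated is not None
            else [True] * values.size,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return FoldTable(table)


@pytest.fixture
def fold_table_factory():
    return make_fold_table


@pytest.fixture(scope="session")
def small_truth():
    """A 2,000-gene planted-truth bundle shared across the session."""
    return sd.plan_truth(n_genes=2000, n_sequence_genes=200, seed=7)


@pytest.fixture(scope="session")
def small_counts(small_truth):
    return sd.generate_counts(small_truth)


@pytest.fixture(scope="session")
def small_folds(small_counts):
    filtered = pp.filter_low_counts(small_counts)
    nm = pp.quantile_normalize(pp.log_cpm(filtered))
    return pp.compute_folds(nm, filtered)
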