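"""Count filtering, normalization, and per-gene log2 fold computation.

The normalization front end is log-CPM (counts per million on the log2
scale, with a small prior count to avoid log of zero) followed by quantile
normalization across samples, so that every library shares the same value
distribution.  Per-gene log2 folds are the unweighted difference of
condition means of the normalized values; detection flags record whether a
gene's raw counts reached the detection threshold in each condition and
feed the switched-on/off selection downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from heatmod.data_io import CONTROL, TREATED, CountMatrix
from heatmod.errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Gene x sample real values on the log2 scale."""

    values: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class FoldTable:
    """Per-gene treated-minus-control log2 fold plus detection flags.

    ``table`` is indexed by gene id with columns ``log2_fold``,
    ``detected_control`` and ``detected_treated``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"log2_fold", "detected_control", "detected_treated"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"FoldTable missing columns {sorted(missing)}")
        if not np.isfinite(self.table["log2_fold"].to_numpy()).all():
            raise ValidationError("log2_fold contains non-finite values")

    @property
    def log2_fold(self) -> pd.Series:
        return self.table["log2_fold"]

    @property
    def universe(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def filter_low_counts(cm: CountMatrix, threshold: int = 10) -> CountMatrix:
    """Discard genes whose counts are below ``threshold`` in every sample.

    A gene is retained iff at least one sample count reaches the
    threshold; the sample set is unchanged.  Idempotent.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    keep = (cm.counts >= threshold).any(axis=1)
    if not keep.any():
        logger.warning("filter_low_counts retained no genes at threshold %d", threshold)
    return CountMatrix(cm.counts.loc[keep], dict(cm.conditions))


def log_cpm(cm: CountMatrix, prior: float = 0.5) -> NormalizedMatrix:
    """log2 counts-per-million with a prior count.

    value(g, s) = log2((count + prior) / (libsize + 2 * prior) * 1e6).
    """
    lib = cm.library_sizes
    zero = lib[lib <= 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero library size")
    values = np.log2(
        (cm.counts.to_numpy(dtype=float) + prior)
        / (lib.to_numpy(dtype=float) + 2.0 * prior)
        * 1e6
    )
    return NormalizedMatrix(pd.DataFrame(values, index=cm.counts.index, columns=cm.counts.columns))


def quantile_normalize(nm: NormalizedMatrix) -> NormalizedMatrix:
    """Force every sample column onto the across-sample mean distribution.

    Each column's sorted values are replaced by the mean of sorted values
    across columns; within-column rank order is preserved, and tied
    entries receive the mean of the reference values their ranks span.
    """
    x = nm.values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # average reference values across tied input values
        s = pd.Series(assigned).groupby(col, sort=False).transform("mean")
        out[:, j] = s.to_numpy()
    return NormalizedMatrix(pd.DataFrame(out, index=nm.values.index, columns=nm.values.columns))


def compute_folds(
    nm: NormalizedMatrix, cm: CountMatrix, detect_threshold: int = 10
) -> FoldTable:
    """Treated-minus-control mean log2 difference with detection flags.

    A gene is "detected" in a condition iff any raw count in that
    condition reaches ``detect_threshold``.
    """
    if list(nm.values.index) != list(cm.counts.index) or list(nm.values.columns) != list(
        cm.counts.columns
    ):
        raise ValidationError("normalized matrix and count matrix must share genes/samples")
    control = cm.samples_of(CONTROL)
    treated = cm.samples_of(TREATED)
    if not control or not treated:
        raise ValidationError("both conditions need at least one sample")
    fold = nm.values[treated].mean(axis=1) - nm.values[control].mean(axis=1)
    table = pd.DataFrame(
        {
            "log2_fold": fold,
            "detected_control": (cm.counts[control] >= detect_threshold).any(axis=1),
            "detected_treated": (cm.counts[treated] >= detect_threshold).any(axis=1),
        },
        index=cm.counts.index,
    )
    return FoldTable(table)
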