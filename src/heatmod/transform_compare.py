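"""Cross-dataset fold-change comparison by linear regression.

Correlates this experiment's per-gene log2 folds with an external
stage-wise fold table (e.g. expression changes at successive stages of
hTERT-driven transformation) over a declared shared gene list.  The
absence of correlation across all stages is the evidence that the
treated cells have not acquired a transformation-like expression
programme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from heatmod.errors import ValidationError
from heatmod.preprocess import FoldTable

logger = logging.getLogger(__name__)


@dataclass
class CompareResult:
    stage_label: str
    n_shared: int
    pearson_r: float
    p_value: float
    slope: float


def align_gene_folds(
    folds_a: FoldTable,
    folds_b: pd.Series,
    gene_list: Iterable[str],
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Pair folds for genes present in both tables and the declared list.

    Returns (x, y, dropped) where x holds this study's folds, y the
    external folds, and ``dropped`` counts the list genes missing from
    each source.
    """
    genes = list(dict.fromkeys(gene_list))
    if not genes:
        raise ValidationError("gene list is empty")
    in_a = set(folds_a.table.index)
    in_b = set(folds_b.index)
    shared = [g for g in genes if g in in_a and g in in_b]
    dropped = {
        "missing_from_a": sum(g not in in_a for g in genes),
        "missing_from_b": sum(g not in in_b for g in genes),
    }
    if not shared:
        raise ValidationError("no shared genes between the two fold tables")
    if dropped["missing_from_a"] or dropped["missing_from_b"]:
        logger.info("align_gene_folds dropped %s", dropped)
    x = folds_a.log2_fold.loc[shared].to_numpy(dtype=float)
    y = folds_b.loc[shared].to_numpy(dtype=float)
    return x, y, dropped


def pearson_regression(
    x: np.ndarray, y: np.ndarray, stage_label: str = ""
) -> CompareResult:
    """Pearson r with a two-sided t-transform p-value and LS slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in one coordinate")
    r, p = stats.pearsonr(x, y)
    slope = float(np.cov(x, y, bias=True)[0, 1] / np.var(x))
    return CompareResult(
        stage_label=stage_label,
        n_shared=int(x.size),
        pearson_r=float(r),
        p_value=float(p),
        slope=slope,
    )


def compare_stages(
    folds: FoldTable,
    external: pd.DataFrame,
    gene_list: Iterable[str],
) -> list[CompareResult]:
    """One CompareResult per stage column of the external fold table."""
    genes = list(gene_list)
    results = []
    for stage in external.columns:
        x, y, _ = align_gene_folds(folds, external[stage], genes)
        results.append(pearson_regression(x, y, stage_label=str(stage)))
    return results
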