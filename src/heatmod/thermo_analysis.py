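"""AT-content thermosensitivity scoring and direction-of-change tests.

An AT base pair holds two hydrogen bonds against three in a GC pair, so
AT-rich genes are the least thermostable in the genome and the most
exposed to heat stress.  This module scores genes by AT fraction, flags a
top quantile as thermosensitive, and asks whether the expression changes
of a chosen gene set are skewed toward one direction: an exact two-sided
binomial sign test (at success probability 1/2) plus a two-sided
Mann-Whitney rank test of the member folds against the rest of the
universe.  A bridging tabulation lists high-confidence interactions
between DNA-repair drivers and oncogenes and flags any inhibiting edge as
a departure from the expected neutral-or-inducing pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import binomtest, mannwhitneyu

from heatmod.data_io import SequenceRecord
from heatmod.errors import ValidationError
from heatmod.preprocess import FoldTable

logger = logging.getLogger(__name__)

#: largest group size for which the exact Mann-Whitney distribution is used
_EXACT_MW_MAX = 8


@dataclass
class ATAnnotation:
    gene_id: str
    at_fraction: float
    thermosensitive: bool


@dataclass
class SignTestResult:
    n: int
    n_down: int
    p_binomial: float
    p_rank: float


def at_fraction(record: SequenceRecord | str) -> float:
    """(A + T) / (A + C + G + T); N bases are excluded entirely."""
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    at = seq.count("A") + seq.count("T")
    acgt = at + seq.count("C") + seq.count("G")
    if acgt == 0:
        gene = record.gene_id if isinstance(record, SequenceRecord) else "<sequence>"
        raise ValidationError(f"sequence for {gene} contains no unambiguous bases")
    return at / acgt


def select_thermosensitive(
    fractions: dict[str, float] | Sequence[tuple[str, float]],
    quantile: float = 0.9,
) -> list[ATAnnotation]:
    """Flag genes at or above the empirical AT-fraction quantile.

    Ties at the cut are included, so identical collections flag
    identically regardless of input order.
    """
    if not 0.0 < quantile < 1.0:
        raise ValidationError("quantile must lie in (0, 1)")
    items = list(fractions.items()) if isinstance(fractions, dict) else list(fractions)
    if not items:
        raise ValidationError("empty AT-fraction collection")
    values = np.array([v for _, v in items], dtype=float)
    cut = float(np.quantile(values, quantile))
    return [
        ATAnnotation(gene_id=g, at_fraction=float(v), thermosensitive=bool(v >= cut))
        for g, v in items
    ]


def direction_sign_test(folds: FoldTable, members: Iterable[str]) -> SignTestResult:
    """Is the sign of expression change skewed within a gene set?

    Zero folds are dropped (with a logged count).  The binomial p is the
    exact two-sided test at success probability 1/2 under the minimum-
    likelihood convention (sum of outcome probabilities no larger than
    the observed count's).  The rank p is a two-sided Mann-Whitney of
    member folds against all remaining universe folds — exact when the
    smaller group has at most 8 untied observations, otherwise the normal
    approximation with tie correction.
    """
    members = list(dict.fromkeys(members))
    idx = folds.table.index
    missing = [m for m in members if m not in idx]
    if missing:
        raise ValidationError(f"members not in fold universe: {missing[:5]}")
    member_folds = folds.log2_fold.loc[members].to_numpy()
    nonzero = member_folds != 0
    if (~nonzero).any():
        logger.info("direction_sign_test dropped %d zero folds", int((~nonzero).sum()))
    member_folds = member_folds[nonzero]
    if member_folds.size == 0:
        raise ValidationError("no members left after dropping zero folds")
    n = int(member_folds.size)
    n_down = int((member_folds < 0).sum())
    p_binom = float(binomtest(n_down, n, 0.5, alternative="two-sided").pvalue)
    rest = folds.log2_fold.drop(labels=members).to_numpy()
    if rest.size == 0:
        raise ValidationError("sign test needs a non-member background")
    ties = np.intersect1d(member_folds, rest).size > 0 or (
        np.unique(member_folds).size < member_folds.size
    )
    if min(n, rest.size) <= _EXACT_MW_MAX and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    p_rank = float(
        mannwhitneyu(member_folds, rest, alternative="two-sided", method=method).pvalue
    )
    return SignTestResult(n=n, n_down=n_down, p_binomial=p_binom, p_rank=min(p_rank, 1.0))


@dataclass
class BridgeTable:
    """High-confidence edges bridging two gene classes."""

    edges: pd.DataFrame  # columns: repair_gene, oncogene, score, action
    action_counts: dict[str, int]
    has_inhibiting: bool


def bridge_tabulation(
    graph: nx.Graph,
    repair_genes: Iterable[str],
    oncogenes: Iterable[str],
    confidence_min: float = 0.9,
) -> BridgeTable:
    """Tabulate repair-driver / oncogene edges above the confidence cut.

    Lists every edge with one endpoint in each class at score strictly
    above ``confidence_min`` together with its action label, counts edges
    per action class, and raises a contradiction flag when any bridging
    edge is inhibiting.
    """
    repair = set(repair_genes)
    onco = set(oncogenes)
    rows = []
    for a, b, data in graph.edges(data=True):
        score = data["score"]
        if score <= confidence_min:
            continue
        if a in repair and b in onco:
            pair = (a, b)
        elif b in repair and a in onco:
            pair = (b, a)
        else:
            continue
        rows.append(
            {
                "repair_gene": pair[0],
                "oncogene": pair[1],
                "score": score,
                "action": data.get("action", "unspecified"),
            }
        )
    rows.sort(key=lambda r: (r["repair_gene"], r["oncogene"]))
    df = pd.DataFrame(rows, columns=["repair_gene", "oncogene", "score", "action"])
    counts: dict[str, int] = {}
    for r in rows:
        counts[r["action"]] = counts.get(r["action"], 0) + 1
    return BridgeTable(
        edges=df,
        action_counts=counts,
        has_inhibiting=counts.get("inhibition", 0) > 0,
    )
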