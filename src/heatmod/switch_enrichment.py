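"""Switched-on/off gene selection and hypergeometric pathway enrichment.

A gene is switched on when its expression is undetected in control
samples but reaches the detection threshold after treatment; switched off
is the mirror image.  Over-representation of a selection inside a pathway
is scored with the upper hypergeometric tail against the full
expressed-gene universe: expected overlap k_exp = n * K / N and
p = P(X >= k_obs) for X ~ Hypergeometric(N, K, n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from scipy.stats import hypergeom

from heatmod.errors import ValidationError
from heatmod.gene_sets import GeneSetCollection
from heatmod.module_contrast import storey_qvalues
from heatmod.preprocess import FoldTable


@dataclass
class SwitchSets:
    """Switched-on and switched-off gene sets within a universe."""

    on_genes: frozenset[str]
    off_genes: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if self.on_genes & self.off_genes:
            raise ValidationError("switched-on and switched-off sets overlap")
        if not (self.on_genes <= self.universe and self.off_genes <= self.universe):
            raise ValidationError("switch sets must be subsets of the universe")


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    K: int
    n: int
    k_obs: int
    k_exp: float
    ratio_obs_exp: float
    p_value: float
    q_value: float
    direction: str = field(default="")


def select_switch_genes(folds: FoldTable) -> SwitchSets:
    """Partition genes by detection flags into on / off / background."""
    t = folds.table
    on = frozenset(t.index[t["detected_treated"] & ~t["detected_control"]])
    off = frozenset(t.index[t["detected_control"] & ~t["detected_treated"]])
    return SwitchSets(on_genes=on, off_genes=off, universe=frozenset(t.index))


def hypergeometric_enrichment(
    selection: Iterable[str],
    gsc: GeneSetCollection,
    universe: Iterable[str],
    direction: str = "",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation test per gene set.

    Every set must already be restricted to the universe.  q-values are
    Storey-Tibshirani over the collection.
    """
    uni = set(universe)
    sel = set(selection)
    if not sel <= uni:
        raise ValidationError("selection must be a subset of the universe")
    N, n = len(uni), len(sel)
    rows: list[EnrichmentResult] = []
    for gs in gsc:
        members = gs.member_set
        if not members <= uni:
            raise ValidationError(f"set {gs.set_id!r} is not restricted to the universe")
        K = len(members)
        k_obs = len(members & sel)
        k_exp = n * K / N
        # P(X >= k_obs); sf(k-1) is the inclusive upper tail
        p = float(hypergeom.sf(k_obs - 1, N, K, n))
        p = min(p, 1.0)
        rows.append(
            EnrichmentResult(
                set_id=gs.set_id,
                name=gs.name,
                K=K,
                n=n,
                k_obs=k_obs,
                k_exp=k_exp,
                ratio_obs_exp=(k_obs / k_exp) if k_exp > 0 else float("nan"),
                p_value=p,
                q_value=float("nan"),
                direction=direction,
            )
        )
    if rows:
        qvals = storey_qvalues([r.p_value for r in rows])
        for r, q in zip(rows, qvals):
            r.q_value = float(q)
    rows.sort(key=lambda r: (r.p_value, r.set_id))
    return rows
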