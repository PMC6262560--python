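"""Gene-set collections and ontology-aware module construction.

Gene modules come from two sources: pathway collections (GMT files) and an
ontology whose ``is_a`` hierarchy must be propagated so that a gene
annotated to a term also counts for every ancestor of that term
("true-path" propagation).  Before testing, collections are restricted to
the expressed-gene universe and entries with identical member sets are
united, so that the multiple-testing burden reflects distinct hypotheses
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from heatmod.errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; ``members`` preserves first-occurrence order."""

    set_id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.set_id!r} has duplicate members")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered list of gene sets.

    Construction does not force member-set uniqueness across entries —
    redundancy is a property of real pathway databases and is removed
    explicitly by :func:`deduplicate_collection`.
    """

    sets: list[GeneSet] = field(default_factory=list)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def ids(self) -> list[str]:
        return [s.set_id for s in self.sets]


class OntologyGraph:
    """A directed acyclic ``is_a`` hierarchy over named terms.

    Edges point child -> parent, so walking along edge direction ascends
    toward the root(s).
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValidationError("ontology is_a graph contains a cycle")
        self._graph = graph

    @classmethod
    def from_edges(
        cls,
        terms: Mapping[str, str],
        is_a_edges: Iterable[tuple[str, str]],
    ) -> "OntologyGraph":
        g = nx.DiGraph()
        for term, name in terms.items():
            g.add_node(term, name=name)
        for child, parent in is_a_edges:
            for endpoint in (child, parent):
                if endpoint not in g:
                    raise ValidationError(f"is_a edge endpoint {endpoint!r} is not a known term")
            g.add_edge(child, parent)
        return cls(g)

    @property
    def terms(self) -> list[str]:
        return list(self._graph.nodes)

    def name_of(self, term: str) -> str:
        return self._graph.nodes[term].get("name", term)

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable by ascending is_a edges (excludes ``term``)."""
        return frozenset(nx.descendants(self._graph, term))


def propagate_annotations(
    onto: OntologyGraph, direct: Mapping[str, Iterable[str]]
) -> dict[str, frozenset[str]]:
    """True-path propagation of direct gene->term annotations.

    A gene belongs to a term if it is annotated to that term or to any of
    the term's descendants; equivalently, each directly annotated term
    contributes itself plus all of its is_a ancestors.
    """
    cache: dict[str, frozenset[str]] = {}
    out: dict[str, frozenset[str]] = {}
    for gene, terms in direct.items():
        acc: set[str] = set()
        for term in terms:
            if term not in onto:
                raise ValidationError(f"gene {gene!r} annotated to unknown term {term!r}")
            if term not in cache:
                cache[term] = onto.ancestors(term) | {term}
            acc |= cache[term]
        out[gene] = frozenset(acc)
    return out


def collection_from_annotations(
    onto: OntologyGraph, propagated: Mapping[str, frozenset[str]]
) -> GeneSetCollection:
    """Invert a propagated gene->terms map into term-level gene sets."""
    by_term: dict[str, list[str]] = {}
    for gene in propagated:
        for term in sorted(propagated[gene]):
            by_term.setdefault(term, []).append(gene)
    sets = [
        GeneSet(set_id=term, name=onto.name_of(term), members=tuple(genes))
        for term, genes in sorted(by_term.items())
    ]
    return GeneSetCollection(sets)


def deduplicate_collection(gsc: GeneSetCollection) -> GeneSetCollection:
    """Unite entries with identical member sets.

    The surviving entry keeps the first entry's id and concatenates the
    display names of all united entries ("; "-joined, input order); output
    order is first-occurrence order.
    """
    merged: dict[frozenset[str], tuple[GeneSet, list[str]]] = {}
    order: list[frozenset[str]] = []
    for gs in gsc:
        key = gs.member_set
        if key in merged:
            merged[key][1].append(gs.name)
        else:
            merged[key] = (gs, [gs.name])
            order.append(key)
    out = [
        GeneSet(set_id=first.set_id, name="; ".join(names), members=first.members)
        for first, names in (merged[k] for k in order)
    ]
    return GeneSetCollection(out)


def restrict_to_universe(
    gsc: GeneSetCollection, universe: Iterable[str], min_size: int = 5
) -> GeneSetCollection:
    """Intersect every set with ``universe``; drop sets below ``min_size``.

    ``min_size`` keeps the sampling null away from degenerate one- or
    two-gene modules; the default floor of 5 is configurable.
    """
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    uni = set(universe)
    kept: list[GeneSet] = []
    dropped = 0
    for gs in gsc:
        members = tuple(g for g in gs.members if g in uni)
        if len(members) >= min_size:
            kept.append(GeneSet(gs.set_id, gs.name, members))
        else:
            dropped += 1
    if dropped:
        logger.info("restrict_to_universe dropped %d sets below size %d", dropped, min_size)
    return GeneSetCollection(kept)
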