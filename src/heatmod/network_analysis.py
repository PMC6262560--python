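"""Seed-centered interaction subnetworks, graph clustering, and annotation.

Subnetworks are built around seed regulators (e.g. the DNA-damage-sensing
and homologous-recombination drivers ATM, ATR, BRCA1): a neighbor joins
the subnetwork when it interacts with a seed above the confidence
threshold and its expression change exceeds the fold threshold in the
requested direction.  Two clustering routes are provided — Markov
clustering (MCL) on the score-weighted adjacency, and K-means on a
spectral embedding of the normalized graph Laplacian — and clusters are
annotated by hypergeometric enrichment with Benjamini-Hochberg FDR
control within each cluster's test family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from heatmod.errors import ValidationError
from heatmod.gene_sets import GeneSetCollection
from heatmod.preprocess import FoldTable

logger = logging.getLogger(__name__)

INDUCED = "induced"
INHIBITED = "inhibited"

#: q-value cut below which an enriched set may title a cluster
CLUSTER_TITLE_Q = 1e-4


@dataclass
class SubnetworkSpec:
    """Selection rules for a seed-centered subnetwork.

    Fold thresholds are given in linear units (2 means twofold) and
    applied on the log2 scale; ``confidence_min`` is the strict lower
    bound on interaction scores.
    """

    seeds: tuple[str, ...]
    direction: str = INDUCED
    fold_threshold: float = 2.0
    confidence_min: float = 0.5
    highlight_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1.0:
            raise ValidationError("fold_threshold must exceed 1 (linear scale)")
        if not 0.0 <= self.confidence_min <= 1.0:
            raise ValidationError("confidence_min must lie in [0, 1]")
        if self.direction not in (INDUCED, INHIBITED):
            raise ValidationError(f"unknown direction {self.direction!r}")


@dataclass
class ClusterSet:
    """A partition of subnetwork nodes into disjoint clusters."""

    clusters: list[frozenset[str]]
    unassigned: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if c & seen:
                raise ValidationError("clusters are not pairwise disjoint")
            seen |= c
        if seen & self.unassigned:
            raise ValidationError("unassigned nodes overlap a cluster")

    @property
    def nodes(self) -> frozenset[str]:
        out: set[str] = set(self.unassigned)
        for c in self.clusters:
            out |= c
        return frozenset(out)

    def labels(self) -> dict[str, int]:
        out = {n: i for i, c in enumerate(self.clusters) for n in c}
        out.update({n: -1 for n in self.unassigned})
        return out


def extract_subnetwork(
    graph: nx.Graph, folds: FoldTable, spec: SubnetworkSpec
) -> nx.Graph:
    """Seeds plus their strongly deregulated direct interactants.

    Retains genes interacting with at least one seed at score strictly
    above ``confidence_min`` whose |log2 fold| exceeds
    log2(fold_threshold) with the sign matching ``direction``; edges are
    all graph edges among retained nodes above the confidence threshold.
    Nodes beyond log2(highlight_threshold) carry a ``large`` flag.
    """
    for seed in spec.seeds:
        if seed not in graph:
            raise ValidationError(f"seed {seed!r} absent from interaction graph")
    log_cut = math.log2(spec.fold_threshold)
    log_high = math.log2(spec.highlight_threshold)
    fold = folds.log2_fold

    def _passes(gene: str) -> bool:
        if gene not in fold.index:
            return False
        f = fold[gene]
        if spec.direction == INDUCED:
            return f > log_cut
        return f < -log_cut

    nodes: set[str] = set(spec.seeds)
    for seed in spec.seeds:
        for nbr in graph.neighbors(seed):
            if graph.edges[seed, nbr]["score"] > spec.confidence_min and _passes(nbr):
                nodes.add(nbr)
    sub = nx.Graph()
    for n in nodes:
        f = float(fold[n]) if n in fold.index else float("nan")
        sub.add_node(
            n,
            log2_fold=f,
            large=bool(abs(f) > log_high) if not math.isnan(f) else False,
            seed=n in spec.seeds,
        )
    for a, b, data in graph.edges(nodes, data=True):
        if a in nodes and b in nodes and data["score"] > spec.confidence_min:
            sub.add_edge(a, b, **data)
    return sub


def _weighted_adjacency(graph: nx.Graph) -> tuple[list[str], np.ndarray]:
    order = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(order)}
    a = np.zeros((len(order), len(order)))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("score", 1.0))
        a[index[u], index[v]] = w
        a[index[v], index[u]] = w
    return order, a


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    prune_threshold: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ClusterSet:
    """Markov clustering on the score-weighted adjacency.

    Self-loops are added with weight equal to each node's maximum
    incident score (1 for isolated nodes), the matrix is
    column-normalized, and expansion (matrix square) alternates with
    inflation (entrywise power, renormalize) until the largest entry
    change falls below ``tol``.  Clusters are the connected components of
    the limit matrix's support.  Fully deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("cannot cluster an empty graph")
    if inflation <= 1.0:
        raise ValidationError("inflation must exceed 1")
    order, a = _weighted_adjacency(graph)
    loops = a.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(a, loops)
    m = a / a.sum(axis=0)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = m**inflation
        m[m < prune_threshold] = 0.0
        colsum = m.sum(axis=0)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; interpreting current state", max_iter)
    support = nx.Graph()
    support.add_nodes_from(order)
    rows, cols = np.nonzero(m + m.T)
    for i, j in zip(rows, cols):
        if i != j:
            support.add_edge(order[i], order[j])
    # a node is attracted to whatever component holds its column mass
    for j, node in enumerate(order):
        i = int(np.argmax(m[:, j]))
        if i != j:
            support.add_edge(order[i], node)
    clusters = [frozenset(c) for c in nx.connected_components(support)]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return ClusterSet(clusters=clusters)


def kmeans_cluster_graph(graph: nx.Graph, k: int, rng_seed: int = 0) -> ClusterSet:
    """Spectral K-means partition of a weighted graph.

    Nodes are embedded with the eigenvectors of the k smallest
    eigenvalues of the symmetric-normalized Laplacian
    I - D^{-1/2} W D^{-1/2}; K-means (k-means++ seeding, 10 restarts,
    best inertia kept) runs on those coordinates.
    """
    n = graph.number_of_nodes()
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k = {k} exceeds node count {n}")
    order, w = _weighted_adjacency(graph)
    if k == 1:
        return ClusterSet(clusters=[frozenset(order)])
    deg = w.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :]
    eigvals, eigvecs = np.linalg.eigh(lap)
    embedding = eigvecs[:, :k]
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=rng_seed % (2**32))
    labels = km.fit_predict(embedding)
    clusters = [
        frozenset(node for node, lab in zip(order, labels) if lab == c) for c in range(k)
    ]
    clusters = [c for c in clusters if c]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return ClusterSet(clusters=clusters)


@dataclass
class ClusterAnnotation:
    """Per-cluster enrichment results and title sets passing the q cut."""

    cluster_index: int
    nodes: frozenset[str]
    results: list  # of (set_id, name, K, k_obs, p_value, q_value) dicts
    title: str


def annotate_clusters(
    clusters: ClusterSet,
    gsc: GeneSetCollection,
    universe: Iterable[str],
    title_q: float = CLUSTER_TITLE_Q,
) -> list[ClusterAnnotation]:
    """Hypergeometric enrichment of each cluster against a collection.

    Benjamini-Hochberg adjustment is applied within each cluster's test
    family (one family per cluster); a cluster is titled by the sets that
    pass ``title_q``, best first.
    """
    uni = set(universe)
    N = len(uni)
    annotations: list[ClusterAnnotation] = []
    for ci, cluster in enumerate(clusters.clusters):
        if not cluster <= uni:
            raise ValidationError(f"cluster {ci} contains nodes outside the universe")
        n = len(cluster)
        rows = []
        for gs in gsc:
            members = gs.member_set & uni
            if not members:
                continue
            K = len(members)
            k_obs = len(members & cluster)
            p = float(min(hypergeom.sf(k_obs - 1, N, K, n), 1.0))
            rows.append(
                {"set_id": gs.set_id, "name": gs.name, "K": K, "k_obs": k_obs, "p_value": p}
            )
        if rows:
            _, q, _, _ = multipletests([r["p_value"] for r in rows], method="fdr_bh")
            for r, qv in zip(rows, q):
                r["q_value"] = float(qv)
            rows.sort(key=lambda r: (r["p_value"], r["set_id"]))
        titles = [r["name"] for r in rows if r.get("q_value", 1.0) < title_q]
        annotations.append(
            ClusterAnnotation(
                cluster_index=ci,
                nodes=cluster,
                results=rows,
                title="; ".join(titles),
            )
        )
    return annotations


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (convenience wrapper)."""
    if len(p_values) == 0:
        return np.array([])
    _, q, _, _ = multipletests(list(p_values), method="fdr_bh")
    return q
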