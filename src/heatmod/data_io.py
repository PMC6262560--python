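"""Readers and writers for the pipeline's external formats.

Supported inputs: gene x sample count TSV, GMT gene-set collections,
OBO 1.2 ontologies (only ``id``, ``name`` and ``is_a`` are consumed),
scored interaction edge lists in the STRING-export TSV dialect, and FASTA
nucleotide sequences.  All outputs are TSV.  Every reader validates its
invariants on ingest and raises :class:`~heatmod.errors.IngestError` with
enough context to locate the offending record.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from Bio import SeqIO

from heatmod.errors import IngestError, ValidationError
from heatmod.gene_sets import GeneSet, GeneSetCollection, OntologyGraph

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATED = "treated"
CONDITIONS = (CONTROL, TREATED)

_NUCLEOTIDES = frozenset("ACGTN")


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts with a two-condition design.

    ``counts`` is a DataFrame indexed by gene id with one column per
    sample; ``conditions`` maps every sample to ``"control"`` or
    ``"treated"``.
    """

    counts: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.counts.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample labels")
        for s in self.counts.columns:
            cond = self.conditions.get(s)
            if cond not in CONDITIONS:
                raise ValidationError(
                    f"sample {s!r} has no valid condition (got {cond!r})"
                )
        if not all(self.conditions.get(s) in CONDITIONS for s in self.counts.columns):
            raise ValidationError("every sample must be assigned exactly one condition")
        for cond in CONDITIONS:
            if not any(self.conditions[s] == cond for s in self.counts.columns):
                raise ValidationError(f"condition {cond!r} has no samples")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], dict(self.conditions))


@dataclass(frozen=True)
class SequenceRecord:
    """A gene's nucleotide sequence over the alphabet {A, C, G, T, N}."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"empty sequence for {self.gene_id!r}")
        bad = set(self.sequence) - _NUCLEOTIDES
        if bad:
            raise ValidationError(
                f"sequence for {self.gene_id!r} contains invalid characters {sorted(bad)}"
            )


def read_count_matrix(path: str | Path, design: Mapping[str, str]) -> CountMatrix:
    """Read a count TSV (header = sample labels, column 1 = gene id).

    ``design`` maps each sample label appearing in the file to its
    condition; a file sample missing from the design is an ingest error.
    Row order is preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise IngestError(f"cannot parse count matrix {path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise IngestError(f"duplicate gene id {dup!r} in {path}")
    for sample in df.columns:
        if sample not in design:
            raise IngestError(f"sample {sample!r} in {path} missing from design")
    counts = pd.DataFrame(index=df.index)
    for sample in df.columns:
        col = pd.to_numeric(df[sample], errors="coerce")
        bad = col.isna() | (col % 1 != 0) | (col < 0)
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise IngestError(
                f"non-integer or negative count at gene {gene!r}, sample {sample!r}"
            )
        counts[sample] = col.astype(np.int64)
    try:
        return CountMatrix(counts, {s: design[s] for s in df.columns})
    except ValidationError as exc:
        raise IngestError(str(exc)) from exc


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column sample/condition TSV into a design map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "condition"]:
        raise IngestError(f"design file {path} must have columns 'sample', 'condition'")
    return dict(zip(df["sample"], df["condition"]))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene TAB gene ...).

    Within-set duplicate genes are collapsed, keeping first occurrence.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IngestError(f"{path}: line {lineno} has fewer than 3 fields")
            set_id, description = fields[0], fields[1]
            members = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise IngestError(f"{path}: line {lineno} ({set_id!r}) has no genes")
            sets.append(GeneSet(set_id=set_id, name=description or set_id, members=members))
    return GeneSetCollection(sets)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gsc:
            fh.write("\t".join([gs.set_id, gs.name, *gs.members]) + "\n")


def read_interactions(path: str | Path, score_scale: str = "thousandths") -> nx.Graph:
    """Read a scored edge list (columns node1, node2, combined_score[, action]).

    ``score_scale="thousandths"`` divides raw STRING-style 0-999 integer
    scores by 1000; ``"unit"`` takes scores as-is.  Self-edges are dropped
    with a warning, duplicate unordered pairs keep the maximum score, and
    any score outside [0, 1] after scaling is an ingest error.

    Returns an undirected :class:`networkx.Graph` whose edges carry a
    ``score`` in [0, 1] and an ``action`` in {activation, inhibition,
    unspecified}.
    """
    if score_scale not in ("unit", "thousandths"):
        raise ValidationError(f"unknown score_scale {score_scale!r}")
    df = pd.read_csv(path, sep="\t", dtype={"node1": str, "node2": str})
    for col in ("node1", "node2", "combined_score"):
        if col not in df.columns:
            raise IngestError(f"{path}: missing column {col!r}")
    has_action = "action" in df.columns
    graph = nx.Graph()
    n_self = 0
    for row in df.itertuples(index=False):
        a, b = row.node1, row.node2
        score = float(row.combined_score)
        if score_scale == "thousandths":
            score /= 1000.0
        if not 0.0 <= score <= 1.0:
            raise IngestError(f"{path}: score {score} for ({a}, {b}) outside [0, 1]")
        if a == b:
            n_self += 1
            continue
        action = getattr(row, "action", "unspecified") if has_action else "unspecified"
        if action not in ("activation", "inhibition", "unspecified"):
            raise IngestError(f"{path}: unknown action {action!r} for ({a}, {b})")
        if graph.has_edge(a, b):
            if score > graph.edges[a, b]["score"]:
                graph.edges[a, b].update(score=score, action=action)
        else:
            graph.add_edge(a, b, score=score, action=action)
    if n_self:
        logger.warning("dropped %d self-edges from %s", n_self, path)
    return graph


def write_interactions(graph: nx.Graph, path: str | Path, score_scale: str = "unit") -> None:
    rows = []
    for a, b, data in sorted((min(a, b), max(a, b), d) for a, b, d in graph.edges(data=True)):
        score = data["score"] * 1000 if score_scale == "thousandths" else data["score"]
        rows.append(
            {
                "node1": a,
                "node2": b,
                "combined_score": int(round(score)) if score_scale == "thousandths" else score,
                "action": data.get("action", "unspecified"),
            }
        )
    pd.DataFrame(rows, columns=["node1", "node2", "combined_score", "action"]).to_csv(
        path, sep="\t", index=False
    )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records; sequences are uppercased and validated."""
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise IngestError(f"{path}: empty sequence under header {rec.id!r}")
        try:
            records.append(SequenceRecord(gene_id=rec.id, sequence=seq))
        except ValidationError as exc:
            raise IngestError(str(exc)) from exc
    return records


def read_obo(path: str | Path) -> OntologyGraph:
    """Read an OBO 1.2 ontology, keeping only id, name and is_a edges."""
    raw = obonet.read_obo(str(path))
    g = nx.DiGraph()
    for node, data in raw.nodes(data=True):
        g.add_node(node, name=data.get("name", node))
    for child, parent, key in raw.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    try:
        return OntologyGraph(g)
    except ValidationError as exc:
        raise IngestError(f"{path}: {exc}") from exc


def write_results_table(
    rows: Iterable, path: str | Path, columns: Sequence[str] | None = None
) -> None:
    """Write homogeneous result records as a TSV with a header row.

    Accepts dataclass instances, mappings, or a DataFrame.  Floats are
    rendered with 6 significant digits; row order is input order, so
    re-running with the same input yields a byte-identical file.  For an
    empty row list, ``columns`` supplies the header.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        dicts = []
        for row in rows:
            if dataclasses.is_dataclass(row):
                dicts.append(dataclasses.asdict(row))
            elif isinstance(row, Mapping):
                dicts.append(dict(row))
            else:
                raise ValidationError(f"cannot serialize row of type {type(row).__name__}")
        if dicts:
            df = pd.DataFrame(dicts, columns=list(dicts[0]))
        else:
            df = pd.DataFrame(columns=list(columns) if columns else [])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
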