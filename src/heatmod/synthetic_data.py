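"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a small two-condition
bulk RNA-seq study — three biological replicates per condition,
negative-binomial counts with gene-specific means, a low-count fraction
that fails the expression filter, module-level planted log2-fold shifts,
forced switched-on/off genes (zero counts in one condition, detected in
the other), a stochastic-block interaction graph with confidence scores
and action labels, and AT-content-skewed sequences whose high-AT genes
are preferentially down-shifted.  The accompanying
:class:`TruthBundle` records exactly what was planted, so recovery can be
checked without re-deriving anything from the data.

Everything is reproducible from (parameters, seed); per-component RNG
streams are derived from the master seed by stable hashing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from heatmod.data_io import CONTROL, TREATED, CountMatrix, SequenceRecord
from heatmod.errors import ValidationError
from heatmod.gene_sets import GeneSet, GeneSetCollection
from heatmod.module_contrast import derive_seed

ACTIONS = ("activation", "inhibition", "unspecified")
DEFAULT_ACTION_PROBS = (0.35, 0.15, 0.50)


@dataclass
class TruthBundle:
    """Planted ground truth for a generated dataset."""

    rng_seed: int
    n_genes: int
    planted_shift_modules: dict[str, float] = field(default_factory=dict)
    module_members: dict[str, list[str]] = field(default_factory=dict)
    gene_shifts: dict[str, float] = field(default_factory=dict)
    planted_on_genes: list[str] = field(default_factory=list)
    planted_off_genes: list[str] = field(default_factory=list)
    planted_low_genes: list[str] = field(default_factory=list)
    planted_blocks: list[list[str]] = field(default_factory=list)
    sequence_genes: list[str] = field(default_factory=list)
    planted_thermosensitive: list[str] = field(default_factory=list)
    planted_thermo_down: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        on, off, low = (
            set(self.planted_on_genes),
            set(self.planted_off_genes),
            set(self.planted_low_genes),
        )
        if on & off:
            raise ValidationError("a gene cannot be both switched on and switched off")
        shift = set(self.gene_shifts)
        for name, group in (("on", on), ("off", off)):
            if group & low:
                raise ValidationError(f"planted {name} genes overlap planted low genes")
            if group & shift:
                raise ValidationError(f"planted {name} genes overlap planted shift genes")
        if low & shift:
            raise ValidationError("planted low genes overlap planted shift genes")
        universe = set(self.gene_ids())
        for group in (on, off, low, shift, set(self.planted_thermosensitive)):
            if not group <= universe:
                raise ValidationError("planted gene ids outside the generated universe")

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthBundle":
        with open(path) as fh:
            return cls(**json.load(fh))


def plan_truth(
    n_genes: int = 10_000,
    n_shift_modules: int = 20,
    module_size: int = 30,
    delta: float = 1.0,
    frac_low: float = 0.05,
    n_on: int = 50,
    n_off: int = 30,
    block_sizes: tuple[int, ...] = (12, 12),
    n_sequence_genes: int = 500,
    thermo_quantile: float = 0.9,
    thermo_down_delta: float = -1.0,
    thermo_down_frac: float = 0.9,
    seed: int = 0,
) -> TruthBundle:
    """Assign disjoint planted roles to genes of a fresh universe."""
    rng = np.random.default_rng(derive_seed(seed, "truth"))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_low = int(round(frac_low * n_genes))
    n_shift = n_shift_modules * module_size
    needed = n_shift + n_on + n_off + n_low + sum(block_sizes) + n_sequence_genes
    if needed > n_genes:
        raise ValidationError(f"planted roles need {needed} genes but universe has {n_genes}")
    perm = rng.permutation(n_genes)
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = [genes[i] for i in perm[cursor : cursor + k]]
        cursor += k
        return out

    modules: dict[str, float] = {}
    members: dict[str, list[str]] = {}
    shifts: dict[str, float] = {}
    for i in range(n_shift_modules):
        set_id = f"SHIFT_MOD_{i:03d}"
        modules[set_id] = delta
        members[set_id] = sorted(take(module_size))
        for g in members[set_id]:
            shifts[g] = delta
    on = sorted(take(n_on))
    off = sorted(take(n_off))
    low = sorted(take(n_low))
    blocks = [sorted(take(k)) for k in block_sizes]
    seq_genes = sorted(take(n_sequence_genes))
    n_thermo = int(round((1.0 - thermo_quantile) * n_sequence_genes))
    thermo = sorted(rng.choice(seq_genes, size=n_thermo, replace=False))
    n_down = int(round(thermo_down_frac * n_thermo))
    thermo_down = sorted(rng.choice(thermo, size=n_down, replace=False))
    for g in thermo_down:
        shifts[g] = thermo_down_delta
    return TruthBundle(
        rng_seed=seed,
        n_genes=n_genes,
        planted_shift_modules=modules,
        module_members=members,
        gene_shifts=shifts,
        planted_on_genes=on,
        planted_off_genes=off,
        planted_low_genes=low,
        planted_blocks=blocks,
        sequence_genes=seq_genes,
        planted_thermosensitive=[str(g) for g in thermo],
        planted_thermo_down=[str(g) for g in thermo_down],
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mu[pos])
        return out
    size = 1.0 / dispersion
    p = size / (size + mu[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def generate_counts(
    truth: TruthBundle,
    n_reps_per_condition: int = 3,
    nb_dispersion: float = 0.1,
    baseline_log2_mean_range: tuple[float, float] = (4.0, 9.0),
    on_mean_range: tuple[float, float] = (30.0, 80.0),
    low_mean_range: tuple[float, float] = (0.5, 2.0),
    filter_threshold: int = 10,
    detect_threshold: int = 10,
) -> CountMatrix:
    """Draw the count matrix implied by a truth bundle.

    Counts are negative-binomial around gene-specific means; shifted
    genes have treated means scaled by 2**delta.  Planted roles are
    forced, not merely probable: on-genes draw exact zeros in control and
    are re-drawn until detected in treated (off-genes mirrored), low
    genes are re-drawn until every count sits below the filter threshold,
    and all other genes until at least one count reaches it — so filter
    and switch recovery are exact by construction.
    """
    if n_reps_per_condition < 1:
        raise ValidationError("need at least one replicate per condition")
    rng = np.random.default_rng(derive_seed(truth.rng_seed, "counts"))
    genes = truth.gene_ids()
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes, reps = len(genes), n_reps_per_condition
    samples = [f"ctrl_{i + 1}" for i in range(reps)] + [f"trt_{i + 1}" for i in range(reps)]
    conditions = {s: (CONTROL if s.startswith("ctrl") else TREATED) for s in samples}
    ctrl = slice(0, reps)
    trt = slice(reps, 2 * reps)

    lo, hi = baseline_log2_mean_range
    base = 2.0 ** rng.uniform(lo, hi, n_genes)
    mu = np.repeat(base[:, None], 2 * reps, axis=1)
    for g, d in truth.gene_shifts.items():
        mu[gene_pos[g], trt] *= 2.0**d
    on_idx = np.array([gene_pos[g] for g in truth.planted_on_genes], dtype=int)
    off_idx = np.array([gene_pos[g] for g in truth.planted_off_genes], dtype=int)
    low_idx = np.array([gene_pos[g] for g in truth.planted_low_genes], dtype=int)
    if on_idx.size:
        mu[on_idx, ctrl] = 0.0
        mu[on_idx, trt] = rng.uniform(*on_mean_range, size=(on_idx.size, reps))
    if off_idx.size:
        mu[off_idx, trt] = 0.0
        mu[off_idx, ctrl] = rng.uniform(*on_mean_range, size=(off_idx.size, reps))
    if low_idx.size:
        mu[low_idx, :] = rng.uniform(*low_mean_range, size=(low_idx.size, 2 * reps))

    counts = _nb_draw(rng, mu, nb_dispersion)

    # forced planted roles: re-draw until the defining condition holds
    def _redraw_until(rows: np.ndarray, cols: slice, ok) -> None:
        pending = rows[~ok(counts[rows, cols])]
        while pending.size:
            counts[pending, cols] = _nb_draw(rng, mu[pending, cols], nb_dispersion)
            pending = pending[~ok(counts[pending, cols])]

    full = slice(0, 2 * reps)
    if low_idx.size:
        _redraw_until(low_idx, full, lambda c: (c < filter_threshold).all(axis=1))
    if on_idx.size:
        _redraw_until(on_idx, trt, lambda c: (c >= detect_threshold).any(axis=1))
    if off_idx.size:
        _redraw_until(off_idx, ctrl, lambda c: (c >= detect_threshold).any(axis=1))
    special = set(truth.planted_low_genes) | set(truth.planted_on_genes) | set(
        truth.planted_off_genes
    )
    normal_idx = np.array([i for g, i in gene_pos.items() if g not in special], dtype=int)
    # detected in BOTH conditions, so no incidental switched-on/off genes
    _redraw_until(normal_idx, ctrl, lambda c: (c >= detect_threshold).any(axis=1))
    _redraw_until(normal_idx, trt, lambda c: (c >= detect_threshold).any(axis=1))

    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    return CountMatrix(df, conditions)


def generate_gene_sets(
    truth: TruthBundle,
    n_sets: int = 100,
    size_range: tuple[int, int] = (10, 50),
) -> GeneSetCollection:
    """Planted shift modules plus uniformly drawn null sets.

    One null set is emitted twice under distinct ids so downstream
    deduplication is exercised; the requested ``n_sets`` counts the
    duplicate, so deduplication shrinks the collection by exactly one.
    Null sets avoid planted low genes so that universe restriction keeps
    their sizes intact.
    """
    rng = np.random.default_rng(derive_seed(truth.rng_seed, "gene_sets"))
    planted = [
        GeneSet(set_id=sid, name=f"planted shift module {sid}", members=tuple(truth.module_members[sid]))
        for sid in sorted(truth.planted_shift_modules)
    ]
    n_null = n_sets - len(planted) - 1
    if n_null < 1:
        raise ValidationError(f"n_sets = {n_sets} leaves no room for null sets")
    low = set(truth.planted_low_genes)
    pool = np.array([g for g in truth.gene_ids() if g not in low])
    if size_range[1] > pool.size:
        raise ValidationError("size_range exceeds the usable universe")
    null_sets = []
    for i in range(n_null):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = tuple(sorted(rng.choice(pool, size=size, replace=False)))
        null_sets.append(GeneSet(set_id=f"NULL_SET_{i:03d}", name=f"null set {i}", members=members))
    duplicate = GeneSet(
        set_id="NULL_SET_DUP", name="duplicate of null set 0", members=null_sets[0].members
    )
    return GeneSetCollection(planted + null_sets + [duplicate])


def generate_interaction_graph(
    truth: TruthBundle,
    p_within: float = 0.9,
    p_between: float = 0.02,
    within_score_range: tuple[float, float] = (0.55, 0.99),
    between_score_range: tuple[float, float] = (0.05, 0.45),
    action_probs: tuple[float, float, float] = DEFAULT_ACTION_PROBS,
    n_bridges: int = 6,
) -> nx.Graph:
    """Stochastic-block interaction graph over the planted block nodes.

    Within-block edges carry confidence scores above 0.5, between-block
    edges below 0.5, and every edge an action label drawn from
    ``action_probs`` over (activation, inhibition, unspecified).  When at
    least two blocks exist, ``n_bridges`` additional block-0/block-1
    edges are planted above confidence 0.9 with neutral-or-inducing
    actions only (never inhibition), emulating the high-confidence
    coupling between DNA-repair drivers and oncogenes.
    """
    for p in (p_within, p_between):
        if not 0.0 <= p <= 1.0:
            raise ValidationError("edge probabilities must lie in [0, 1]")
    rng = np.random.default_rng(derive_seed(truth.rng_seed, "graph"))
    blocks = truth.planted_blocks
    graph = nx.Graph()
    block_of: dict[str, int] = {}
    for bi, block in enumerate(blocks):
        for g in block:
            graph.add_node(g)
            block_of[g] = bi
    nodes = sorted(block_of)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            same = block_of[a] == block_of[b]
            if rng.random() < (p_within if same else p_between):
                score = rng.uniform(*(within_score_range if same else between_score_range))
                action = ACTIONS[rng.choice(len(ACTIONS), p=action_probs)]
                graph.add_edge(a, b, score=float(score), action=action)
    if n_bridges > 0 and len(blocks) >= 2:
        pairs = [(a, b) for a in blocks[0] for b in blocks[1]]
        chosen = rng.choice(len(pairs), size=min(n_bridges, len(pairs)), replace=False)
        for idx in sorted(chosen):
            a, b = pairs[idx]
            action = "activation" if rng.random() < 0.5 else "unspecified"
            graph.add_edge(a, b, score=float(rng.uniform(0.905, 0.99)), action=action)
    return graph


def generate_sequences(
    truth: TruthBundle,
    at_mean_high: float = 0.70,
    at_mean_background: float = 0.50,
    length: int = 2000,
) -> list[SequenceRecord]:
    """Nucleotide sequences with planted AT-content structure.

    Bases are i.i.d. with per-gene AT probability — high for the planted
    thermosensitive genes, background otherwise — so realized AT
    fractions concentrate tightly around their targets at the default
    length and the planted top decile separates cleanly.
    """
    for p in (at_mean_high, at_mean_background):
        if not 0.0 < p < 1.0:
            raise ValidationError("AT means must lie in (0, 1)")
    rng = np.random.default_rng(derive_seed(truth.rng_seed, "sequences"))
    thermo = set(truth.planted_thermosensitive)
    records = []
    bases = np.array(list("ATGC"))
    for g in truth.sequence_genes:
        p_at = at_mean_high if g in thermo else at_mean_background
        probs = [p_at / 2, p_at / 2, (1 - p_at) / 2, (1 - p_at) / 2]
        seq = "".join(bases[rng.choice(4, size=length, p=probs)])
        records.append(SequenceRecord(gene_id=g, sequence=seq))
    return records


def generate_external_folds(
    truth: TruthBundle,
    n_genes: int = 1731,
    stages: tuple[str, ...] = ("stage_I", "stage_II", "stage_III"),
    sd: float = 0.5,
) -> tuple[pd.DataFrame, list[str]]:
    """An external stage-wise fold table independent of this experiment.

    Folds are independent normals, so the expected correlation with the
    generated experiment's folds is zero at every stage.
    """
    rng = np.random.default_rng(derive_seed(truth.rng_seed, "external"))
    low = set(truth.planted_low_genes)
    pool = np.array([g for g in truth.gene_ids() if g not in low])
    if n_genes > pool.size:
        raise ValidationError("external gene list exceeds the usable universe")
    genes = sorted(rng.choice(pool, size=n_genes, replace=False))
    table = pd.DataFrame(
        rng.normal(0.0, sd, size=(n_genes, len(stages))),
        index=pd.Index(genes, name="gene_id"),
        columns=list(stages),
    )
    return table, list(genes)


def _write_obo(path: Path, truth: TruthBundle) -> dict[str, list[str]]:
    """Write a small DNA-repair ontology; return direct gene annotations.

    Members of the first planted module are annotated to the homologous
    recombination leaf and members of the second to excision repair, so
    true-path propagation lifts both onto their ancestors.
    """
    terms = [
        ("T:0001", "DNA repair", []),
        ("T:0002", "double-strand break repair", ["T:0001"]),
        ("T:0003", "homologous recombination", ["T:0002"]),
        ("T:0004", "excision repair", ["T:0001"]),
    ]
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: heatmod-toy\n")
        for term_id, name, parents in terms:
            fh.write(f"\n[Term]\nid: {term_id}\nname: {name}\n")
            for parent in parents:
                fh.write(f"is_a: {parent}\n")
    direct: dict[str, list[str]] = {}
    module_ids = sorted(truth.planted_shift_modules)
    for term, sid in zip(("T:0003", "T:0004"), module_ids):
        for g in truth.module_members[sid]:
            direct.setdefault(g, []).append(term)
    return direct


def generate_bundle(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 10_000,
    n_sets: int = 100,
    n_reps_per_condition: int = 3,
    nb_dispersion: float = 0.1,
    B: int = 20_000,
    **plan_kwargs,
) -> TruthBundle:
    """Write a complete synthetic dataset plus a ready-to-run config.

    Emits counts.tsv / design.tsv, sets.gmt, ontology.obo +
    annotations.tsv, interactions.tsv (STRING-style thousandths scores),
    sequences.fasta, external_folds.tsv + gene_list.txt, the repair and
    oncogene lists (the two planted graph blocks), truth.json and a
    config.yaml whose paths point at the generated files.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = plan_truth(n_genes=n_genes, seed=seed, **plan_kwargs)
    cm = generate_counts(
        truth, n_reps_per_condition=n_reps_per_condition, nb_dispersion=nb_dispersion
    )
    cm.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample": cm.sample_ids, "condition": [cm.conditions[s] for s in cm.sample_ids]}
    ).to_csv(outdir / "design.tsv", sep="\t", index=False)

    gsc = generate_gene_sets(truth, n_sets=n_sets)
    with open(outdir / "sets.gmt", "w") as fh:
        for gs in gsc:
            fh.write("\t".join([gs.set_id, gs.name, *gs.members]) + "\n")

    direct = _write_obo(outdir / "ontology.obo", truth)
    pd.DataFrame(
        [(g, t) for g, ts in sorted(direct.items()) for t in ts],
        columns=["gene_id", "term"],
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    graph = generate_interaction_graph(truth)
    rows = [
        {
            "node1": min(a, b),
            "node2": max(a, b),
            "combined_score": int(round(d["score"] * 1000)),
            "action": d["action"],
        }
        for a, b, d in graph.edges(data=True)
    ]
    rows.sort(key=lambda r: (r["node1"], r["node2"]))
    pd.DataFrame(rows, columns=["node1", "node2", "combined_score", "action"]).to_csv(
        outdir / "interactions.tsv", sep="\t", index=False
    )

    with open(outdir / "sequences.fasta", "w") as fh:
        for rec in generate_sequences(truth):
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i : i + 80] + "\n")

    external, gene_list = generate_external_folds(truth)
    external.to_csv(outdir / "external_folds.tsv", sep="\t")
    (outdir / "gene_list.txt").write_text("\n".join(gene_list) + "\n")

    blocks = truth.planted_blocks
    (outdir / "repair_genes.txt").write_text("\n".join(blocks[0]) + "\n")
    (outdir / "oncogenes.txt").write_text(
        ("\n".join(blocks[1]) + "\n") if len(blocks) > 1 else ""
    )

    truth.to_json(outdir / "truth.json")

    config = {
        "counts": str(outdir / "counts.tsv"),
        "design": str(outdir / "design.tsv"),
        "gmt": str(outdir / "sets.gmt"),
        "obo": str(outdir / "ontology.obo"),
        "annotations": str(outdir / "annotations.tsv"),
        "interactions": str(outdir / "interactions.tsv"),
        "fasta": str(outdir / "sequences.fasta"),
        "external_folds": str(outdir / "external_folds.tsv"),
        "gene_list": str(outdir / "gene_list.txt"),
        "repair_genes": str(outdir / "repair_genes.txt"),
        "oncogenes": str(outdir / "oncogenes.txt"),
        "out_dir": str(outdir / "results"),
        "seeds": blocks[0][:3],
        "rng_seed": seed,
        "B": B,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return truth
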