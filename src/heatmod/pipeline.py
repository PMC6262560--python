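"""Configured end-to-end pipeline over the analysis stages.

Stages run in a fixed order — preprocess, gene sets, module contrast,
switch enrichment, network analysis, thermosensitivity, cross-dataset
comparison — each writing TSV results into the run directory.  A
manifest records the resolved-configuration hash, the master seed and
per-stage row counts; identical configuration and seed reproduce every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from heatmod import __version__, data_io, gene_sets, network_analysis, preprocess
from heatmod import module_contrast, switch_enrichment, thermo_analysis, transform_compare
from heatmod.errors import ValidationError

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "gene_sets", "contrast", "switch", "network", "thermo", "compare")


@dataclass
class PipelineConfig:
    """Resolved configuration for a pipeline run.

    Thresholds default to the study's analysis settings: count filter and
    detection threshold 10, interaction confidence 0.5 (0.9 for the
    bridging tabulation), fold thresholds 2 and 5, B = 20,000 random
    samplings, thermosensitive cut at the top AT-content decile.
    """

    counts: str
    design: str
    gmt: str
    interactions: str
    fasta: str
    external_folds: str
    gene_list: str
    repair_genes: str
    oncogenes: str
    out_dir: str
    obo: str | None = None
    annotations: str | None = None
    seeds: list[str] = field(default_factory=list)
    rng_seed: int = 0
    B: int = 20_000
    filter_threshold: int = 10
    detect_threshold: int = 10
    log_prior: float = 0.5
    min_set_size: int = 5
    confidence_min: float = 0.5
    bridge_confidence: float = 0.9
    fold_threshold: float = 2.0
    highlight_threshold: float = 5.0
    clustering_method: str = "mcl"
    kmeans_k: int = 2
    thermo_quantile: float = 0.9
    score_scale: str = "thousandths"
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValidationError("B must be >= 1")
        if not 0.0 <= self.confidence_min <= 1.0:
            raise ValidationError("confidence_min must lie in [0, 1]")
        if not 0.0 <= self.bridge_confidence <= 1.0:
            raise ValidationError("bridge_confidence must lie in [0, 1]")
        if self.fold_threshold <= 1.0 or self.highlight_threshold <= 1.0:
            raise ValidationError("fold thresholds are linear and must exceed 1")
        if not 0.0 < self.thermo_quantile < 1.0:
            raise ValidationError("thermo_quantile must lie in (0, 1)")
        if self.clustering_method not in ("mcl", "kmeans"):
            raise ValidationError(f"unknown clustering method {self.clustering_method!r}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def check_inputs(self) -> None:
        required = [
            self.counts, self.design, self.gmt, self.interactions, self.fasta,
            self.external_folds, self.gene_list, self.repair_genes, self.oncogenes,
        ]
        optional = [self.obo, self.annotations]
        for p in required + [p for p in optional if p]:
            if not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")


def _read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; return the run directory.

    On stage failure a FAILED marker naming the stage is left in the run
    directory and the exception propagates; outputs of completed stages
    are retained.
    """
    config.check_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
        "stages": {},
    }
    state: dict = {}
    stage_fns = {
        "preprocess": _stage_preprocess,
        "gene_sets": _stage_gene_sets,
        "contrast": _stage_contrast,
        "switch": _stage_switch,
        "network": _stage_network,
        "thermo": _stage_thermo,
        "compare": _stage_compare,
    }
    enabled = [s for s in STAGES if s in config.stages]
    for stage in enabled:
        try:
            counts = stage_fns[stage](config, state, out)
        except Exception as exc:
            (out / "FAILED").write_text(f"{stage}: {exc}\n")
            raise
        manifest["stages"][stage] = counts
        logger.info("stage %s done: %s", stage, counts)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _stage_preprocess(config: PipelineConfig, state: dict, out: Path) -> dict:
    design = data_io.read_design(config.design)
    cm = data_io.read_count_matrix(config.counts, design)
    filtered = preprocess.filter_low_counts(cm, threshold=config.filter_threshold)
    nm = preprocess.quantile_normalize(preprocess.log_cpm(filtered, prior=config.log_prior))
    folds = preprocess.compute_folds(nm, filtered, detect_threshold=config.detect_threshold)
    table = folds.table.reset_index(names="gene_id")
    data_io.write_results_table(table, out / "folds.tsv")
    state["counts"] = filtered
    state["folds"] = folds
    return {"genes_input": len(cm.gene_ids), "genes_expressed": len(folds)}


def _stage_gene_sets(config: PipelineConfig, state: dict, out: Path) -> dict:
    gsc = data_io.read_gmt(config.gmt)
    n_raw = len(gsc)
    if config.obo and config.annotations:
        onto = data_io.read_obo(config.obo)
        direct_df = pd.read_csv(config.annotations, sep="\t", dtype=str)
        direct: dict[str, list[str]] = {}
        for row in direct_df.itertuples(index=False):
            direct.setdefault(row.gene_id, []).append(row.term)
        propagated = gene_sets.propagate_annotations(onto, direct)
        onto_sets = gene_sets.collection_from_annotations(onto, propagated)
        gsc = gene_sets.GeneSetCollection(list(gsc) + list(onto_sets))
    universe = state["folds"].universe
    restricted = gene_sets.restrict_to_universe(gsc, universe, min_size=config.min_set_size)
    deduped = gene_sets.deduplicate_collection(restricted)
    data_io.write_gmt(deduped, out / "modules.gmt")
    state["modules"] = deduped
    return {"sets_input": n_raw, "sets_tested": len(deduped)}


def _stage_contrast(config: PipelineConfig, state: dict, out: Path) -> dict:
    results = module_contrast.run_contrast_analysis(
        state["folds"], state["modules"], B=config.B, rng_seed=config.rng_seed
    )
    data_io.write_results_table(
        results,
        out / "contrast.tsv",
        columns=[f.name for f in dataclasses.fields(module_contrast.ContrastResult)],
    )
    state["contrast"] = results
    return {
        "modules": len(results),
        "q_below_0.01": sum(r.q_value < 0.01 for r in results),
        "q_below_0.001": sum(r.q_value < 0.001 for r in results),
    }


def _stage_switch(config: PipelineConfig, state: dict, out: Path) -> dict:
    folds = state["folds"]
    switches = switch_enrichment.select_switch_genes(folds)
    rows = [
        {"gene_id": g, "direction": d}
        for d, genes in (("on", sorted(switches.on_genes)), ("off", sorted(switches.off_genes)))
        for g in genes
    ]
    data_io.write_results_table(rows, out / "switch_genes.tsv", columns=["gene_id", "direction"])
    results = []
    for direction, selection in (("on", switches.on_genes), ("off", switches.off_genes)):
        results.extend(
            switch_enrichment.hypergeometric_enrichment(
                selection, state["modules"], switches.universe, direction=direction
            )
        )
    data_io.write_results_table(
        results,
        out / "switch_enrichment.tsv",
        columns=[f.name for f in dataclasses.fields(switch_enrichment.EnrichmentResult)],
    )
    state["switches"] = switches
    return {"switched_on": len(switches.on_genes), "switched_off": len(switches.off_genes)}


def _stage_network(config: PipelineConfig, state: dict, out: Path) -> dict:
    graph = data_io.read_interactions(config.interactions, score_scale=config.score_scale)
    state["graph"] = graph
    folds = state["folds"]
    counts: dict = {}
    for direction in (network_analysis.INDUCED, network_analysis.INHIBITED):
        spec = network_analysis.SubnetworkSpec(
            seeds=tuple(config.seeds),
            direction=direction,
            fold_threshold=config.fold_threshold,
            confidence_min=config.confidence_min,
            highlight_threshold=config.highlight_threshold,
        )
        sub = network_analysis.extract_subnetwork(graph, folds, spec)
        if sub.number_of_nodes() == 0:
            counts[direction] = {"nodes": 0, "edges": 0, "clusters": 0}
            continue
        if config.clustering_method == "mcl":
            clusters = network_analysis.mcl_cluster(sub)
        else:
            k = min(config.kmeans_k, sub.number_of_nodes())
            clusters = network_analysis.kmeans_cluster_graph(sub, k, rng_seed=config.rng_seed)
        universe = [g for g in folds.universe]
        cluster_universe = set(universe) | set(sub.nodes)
        annotations = network_analysis.annotate_clusters(
            clusters, state["modules"], cluster_universe
        )
        labels = clusters.labels()
        node_rows = [
            {
                "gene_id": n,
                "log2_fold": data["log2_fold"],
                "large": data["large"],
                "seed": data["seed"],
                "cluster": labels.get(n, -1),
            }
            for n, data in sorted(sub.nodes(data=True))
        ]
        data_io.write_results_table(
            node_rows,
            out / f"network_{direction}_nodes.tsv",
            columns=["gene_id", "log2_fold", "large", "seed", "cluster"],
        )
        edge_rows = [
            {
                "node1": min(a, b),
                "node2": max(a, b),
                "score": d["score"],
                "action": d.get("action", "unspecified"),
            }
            for a, b, d in sub.edges(data=True)
        ]
        edge_rows.sort(key=lambda r: (r["node1"], r["node2"]))
        data_io.write_results_table(
            edge_rows,
            out / f"network_{direction}_edges.tsv",
            columns=["node1", "node2", "score", "action"],
        )
        cluster_rows = [
            {
                "cluster": ann.cluster_index,
                "size": len(ann.nodes),
                "members": ",".join(sorted(ann.nodes)),
                "title": ann.title,
            }
            for ann in annotations
        ]
        data_io.write_results_table(
            cluster_rows,
            out / f"network_{direction}_clusters.tsv",
            columns=["cluster", "size", "members", "title"],
        )
        counts[direction] = {
            "nodes": sub.number_of_nodes(),
            "edges": sub.number_of_edges(),
            "clusters": len(clusters.clusters),
        }
    return counts


def _stage_thermo(config: PipelineConfig, state: dict, out: Path) -> dict:
    records = data_io.read_fasta(config.fasta)
    fractions = {rec.gene_id: thermo_analysis.at_fraction(rec) for rec in records}
    annotations = thermo_analysis.select_thermosensitive(fractions, quantile=config.thermo_quantile)
    folds = state["folds"]
    fold_map = folds.log2_fold
    rows = [
        {
            "gene_id": a.gene_id,
            "at_fraction": a.at_fraction,
            "thermosensitive": a.thermosensitive,
            "log2_fold": float(fold_map.get(a.gene_id, float("nan"))),
        }
        for a in annotations
    ]
    data_io.write_results_table(
        rows, out / "thermo.tsv", columns=["gene_id", "at_fraction", "thermosensitive", "log2_fold"]
    )
    members = [
        a.gene_id
        for a in annotations
        if a.thermosensitive and a.gene_id in fold_map.index and fold_map[a.gene_id] != 0
    ]
    sign = thermo_analysis.direction_sign_test(folds, members)
    data_io.write_results_table([sign], out / "sign_test.tsv")
    graph = state.get("graph")
    if graph is None:
        graph = data_io.read_interactions(config.interactions, score_scale=config.score_scale)
    bridge = thermo_analysis.bridge_tabulation(
        graph,
        _read_gene_list(config.repair_genes),
        _read_gene_list(config.oncogenes),
        confidence_min=config.bridge_confidence,
    )
    data_io.write_results_table(bridge.edges, out / "bridge_edges.tsv")
    return {
        "sequences": len(records),
        "thermosensitive": sum(a.thermosensitive for a in annotations),
        "sign_n": sign.n,
        "sign_n_down": sign.n_down,
        "bridge_edges": int(len(bridge.edges)),
        "bridge_has_inhibiting": bool(bridge.has_inhibiting),
    }


def _stage_compare(config: PipelineConfig, state: dict, out: Path) -> dict:
    external = pd.read_csv(config.external_folds, sep="\t", index_col=0)
    gene_list = _read_gene_list(config.gene_list)
    results = transform_compare.compare_stages(state["folds"], external, gene_list)
    data_io.write_results_table(results, out / "compare.tsv")
    return {"stages": len(results), "n_shared": results[0].n_shared if results else 0}
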