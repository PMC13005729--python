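"""End-to-end pipeline: read -> enrich -> cluster -> pool -> export.

A run reads the condition table and GMT libraries, performs ORA per
condition (optionally split by regulation), retains the top-N significant
terms per stratum, clusters the retained terms on gene overlap, pools
p-values per cluster and writes result tables, graph exports, an LLM
annotation prompt and figures into one run directory, together with a
manifest recording every parameter and input checksum. All randomness is
seeded, and outputs carry no timestamps, so a run is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import clustering, enrich, io, summary, viz
from .exceptions import EnrichClustError, InputError, PipelineError
from .summary import PoolingSpec

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of a full run; mirrors the CLI flags."""

    input_table: str
    libraries: list[str]
    outdir: str
    gene_col: str = "gene"
    condition_col: str = "condition"
    logfc_col: str | None = None
    logfc_threshold: float | None = None  # None: no up/down split
    padj_max: float = 0.05
    min_genes: int = 3
    top_n: int = 5
    ts: float = 0.3
    walk_length: int = 4
    pool_method: str = "cauchy"
    pool_weights: str = "overlap_size"
    p_floor: float = 1e-10
    annotation_file: str | None = None
    make_plots: bool = True
    figure_format: str = "png"
    seed: int = 0

    def __post_init__(self):
        if self.seed < 0:
            raise PipelineError("config", "seed must be a non-negative integer")
        if not 0 < self.padj_max <= 1:
            raise PipelineError("config", "padj_max must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def pooling_spec(self) -> PoolingSpec:
        return PoolingSpec(
            method=self.pool_method, weights=self.pool_weights, floor=self.p_floor
        )


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    table: enrich.EnrichmentTable
    term_gene_map: clustering.TermGeneMap
    graph: "clustering.nx.Graph"
    assignment: clustering.ClusterAssignment
    summary_rows: list[summary.ClusterSummaryRow]
    coherence: summary.CoherenceReport
    outputs: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full workflow; on failure remove partial outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, outdir, written)
    except EnrichClustError:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _stage(name: str):
    """Re-raise non-package exceptions as PipelineError naming the stage."""
    class _Ctx:
        def __enter__(self):
            return self
        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, EnrichClustError):
                raise PipelineError(name, str(exc)) from exc
            if isinstance(exc, EnrichClustError) and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False
    return _Ctx()


def _run(config: PipelineConfig, outdir: Path, written: list[Path]) -> RunResult:
    def track(path: Path) -> Path:
        written.append(path)
        return path

    with _stage("read_input"):
        condition_lists = io.read_condition_table(
            config.input_table,
            gene_col=config.gene_col,
            condition_col=config.condition_col,
            logfc_col=config.logfc_col,
        )
        logger.info("read %d conditions from %s", len(condition_lists), config.input_table)
        libraries = [io.read_gmt(p) for p in config.libraries]
        for lib in libraries:
            logger.info(
                "library %s: %d terms, background %d genes",
                lib.name, len(lib), len(lib.background),
            )

    with _stage("enrich"):
        queries: list[tuple[str, str, frozenset[str]]] = []
        for cgl in condition_lists:
            if config.logfc_threshold is not None:
                up, down = enrich.split_by_regulation(cgl, config.logfc_threshold)
                if up:
                    queries.append((cgl.condition, "up", up.genes))
                if down:
                    queries.append((cgl.condition, "down", down.genes))
            else:
                queries.append((cgl.condition, "all", cgl.genes))
        all_hits: list[enrich.EnrichmentHit] = []
        for condition, regulation, genes in queries:
            for lib in libraries:
                try:
                    hits = enrich.enrich_condition(
                        genes, lib,
                        min_genes=config.min_genes,
                        condition=condition,
                        regulation=regulation,
                    )
                except InputError:
                    logger.warning(
                        "condition %s (%s) has no genes in background of %s; skipped",
                        condition, regulation, lib.name,
                    )
                    continue
                all_hits.extend(hits)
        logger.info("tested %d (condition x regulation x library) strata; %d hits "
                    "passed the size filter", len(queries) * len(libraries), len(all_hits))

    with _stage("filter_and_rank"):
        retained = enrich.filter_and_rank(
            all_hits, padj_max=config.padj_max, top_n=config.top_n
        )
        if not retained:
            raise InputError(
                "no term passed the significance filter in any condition"
            )
        logger.info("retained %d top-ranked hits", len(retained))
        table = enrich.EnrichmentTable(
            hits=retained,
            provenance={
                "padj_max": config.padj_max,
                "min_genes": config.min_genes,
                "top_n": config.top_n,
                "libraries": [lib.name for lib in libraries],
            },
        )

    with _stage("cluster"):
        term_gene_map = clustering.build_term_gene_map(table.hits)
        graph = clustering.build_term_graph(term_gene_map, ts=config.ts)
        assignment = clustering.walktrap_cluster(graph, walk_length=config.walk_length)
        logger.info(
            "clustered %d terms into %d clusters (modularity %.3f)",
            len(term_gene_map), assignment.n_clusters, assignment.modularity_value,
        )

    with _stage("summarize"):
        spec = config.pooling_spec()
        rows = summary.summarize_clusters(table.hits, assignment, spec)
        annotation_map: summary.AnnotationMap | dict = {}
        if config.annotation_file:
            with open(config.annotation_file, encoding="utf-8") as fh:
                annotation_map = summary.parse_annotation_reply(
                    fh.read(), known_ids=sorted(set(assignment.labels.values()))
                )
        rows = summary.apply_annotations(rows, annotation_map)
        coherence = summary.term_coherence(term_gene_map, assignment)

    outputs: dict[str, Path] = {}
    with _stage("export"):
        results_path = track(outdir / "results.tsv")
        annotations = {r.cluster_id: r.annotation for r in rows}
        pooled = {(r.cluster_id, r.condition, r.regulation): r.pooled_p for r in rows}
        result_rows = [
            {
                "cluster_id": assignment.labels[h.term],
                "annotation": annotations.get(assignment.labels[h.term], ""),
                "term": h.term,
                "database": h.database,
                "condition": h.condition,
                "regulation": h.regulation,
                "overlap_genes": h.overlap_genes,
                "p_raw": h.p_raw,
                "p_adj": h.p_adj,
                "pooled_p": pooled[
                    (assignment.labels[h.term], h.condition, h.regulation)
                ],
            }
            for h in sorted(table.hits, key=lambda h: h.key)
        ]
        io.write_results_table(result_rows, results_path)
        outputs["results"] = results_path

        prompt_path = track(outdir / "annotation_prompt.txt")
        prompt_path.write_text(
            summary.build_annotation_prompt(assignment, table.hits), encoding="utf-8"
        )
        outputs["prompt"] = prompt_path

        graphml_path = track(outdir / "term_graph.graphml")
        clustering.write_graphml(graph, graphml_path, assignment)
        outputs["graphml"] = graphml_path
        nodelink_path = track(outdir / "term_graph.json")
        clustering.write_node_link_json(graph, nodelink_path, assignment)
        outputs["node_link"] = nodelink_path

        coherence_path = track(outdir / "coherence.csv")
        coherence.per_term.to_csv(coherence_path, index=False, float_format="%.17g")
        outputs["coherence"] = coherence_path

    if config.make_plots:
        with _stage("plot"):
            fmt = config.figure_format
            heat_path = track(outdir / f"heatmap.{fmt}")
            viz.render(viz.heatmap_bundle(rows), heat_path, fmt)
            track(Path(str(heat_path) + ".csv"))
            bubble_path = track(outdir / f"bubble.{fmt}")
            viz.render(viz.bubble_table(rows), bubble_path, fmt)
            track(Path(str(bubble_path) + ".csv"))
            outputs["heatmap"] = heat_path
            outputs["bubble"] = bubble_path

    with _stage("manifest"):
        manifest = {
            "parameters": asdict(config),
            "library_checksums": {
                str(p): _sha256(Path(p)) for p in config.libraries
            },
            "input_checksum": _sha256(Path(config.input_table)),
            "n_hits_retained": len(table.hits),
            "n_clusters": assignment.n_clusters,
            "modularity": assignment.modularity_value,
            "outputs": {k: str(v) for k, v in outputs.items()},
        }
        manifest_path = track(outdir / "manifest.json")
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        outputs["manifest"] = manifest_path

    return RunResult(
        config=config,
        table=table,
        term_gene_map=term_gene_map,
        graph=graph,
        assignment=assignment,
        summary_rows=rows,
        coherence=coherence,
        outputs=outputs,
    )
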