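"""End-to-end orchestration of the comorbidity age-trend workflow.

Stage order: candidate gene selection (union over allowed diseases from
the gene-disease table) -> per-tissue trend screen -> per-tissue and
combined interaction networks over the significant genes -> network
statistics and the permutation connectivity null -> Markov clustering of
the combined network -> enrichment per tissue and per cluster.  Every
table is written under the output directory with stable names, and a
run manifest records the per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from . import io as atio
from .datamodel import GeneDiseaseTable
from .enrichment import enrich, enrichment_to_frame
from .mcl import MCLParams, cluster_summary, mcl
from .network import (
    DEFAULT_MIN_SCORE,
    connectivity_pvalue,
    induce_network,
    network_stats,
)
from .trend import (
    TrendConfig,
    apply_global_correction,
    heatmap_matrix,
    results_to_frame,
    screen_tissue,
)

log = logging.getLogger("agetrend")

__all__ = ["PipelineConfig", "RunManifest", "select_candidate_genes", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the CLI exit path."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    expression: str
    sample_attributes: str
    subject_phenotypes: str
    gene_disease: str
    interactions: str
    annotations: str
    output_dir: str = "agetrend_out"
    seed: int = 0
    tissues: list[str] = field(default_factory=list)
    diseases: list[str] = field(default_factory=list)
    trend: TrendConfig = field(default_factory=TrendConfig)
    min_score: float = DEFAULT_MIN_SCORE
    score_strict: bool = False
    channel: str | None = "physical"
    n_perm: int = 1000
    mcl: MCLParams = field(default_factory=MCLParams)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key-value YAML config (nested keys use prefixes
        ``trend_*`` and ``mcl_*``)."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        raw.update(overrides)
        trend_kwargs = {k[len("trend_"):]: v for k, v in raw.items() if k.startswith("trend_")}
        mcl_kwargs = {k[len("mcl_"):]: v for k, v in raw.items() if k.startswith("mcl_")}
        plain = {k: v for k, v in raw.items()
                 if not k.startswith(("trend_", "mcl_"))}
        known = set(cls.__dataclass_fields__) - {"trend", "mcl"}
        unknown = set(plain) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(trend=TrendConfig(**trend_kwargs), mcl=MCLParams(**mcl_kwargs), **plain)

    def validate(self) -> None:
        for name in ("expression", "sample_attributes", "subject_phenotypes",
                     "gene_disease", "interactions", "annotations"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"input {name!r}: no such file {p}")


@dataclass
class RunManifest:
    """Reproducibility record: config echo, input checksums, stage counts."""

    config: dict
    input_checksums: dict[str, str]
    n_candidates: int = 0
    n_candidates_expressed: int = 0
    monotone_per_tissue: dict[str, dict[str, int]] = field(default_factory=dict)
    significant_per_tissue: dict[str, int] = field(default_factory=dict)
    n_significant_union: int = 0
    network_nodes: int = 0
    network_edges: int = 0
    network_mean_degree: float = float("nan")
    connectivity_observed_edges: int = 0
    connectivity_p: float = float("nan")
    n_clusters: int = 0
    n_enriched_terms_fdr05: int = 0
    version: str = ""
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def select_candidate_genes(table: GeneDiseaseTable, diseases: Iterable[str] | None = None) -> set[str]:
    """Union of the gene sets of the allowed diseases (all when empty)."""
    if len(table) == 0:
        raise ValueError("gene-disease table is empty")
    return table.gene_union(diseases)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage and write all artifacts under ``config.output_dir``."""
    from . import __version__

    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    import datetime

    manifest = RunManifest(
        config={k: v for k, v in asdict(config).items()},
        input_checksums={
            name: _sha256(getattr(config, name))
            for name in ("expression", "sample_attributes", "subject_phenotypes",
                         "gene_disease", "interactions", "annotations")
        },
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )

    # --- stage: load inputs --------------------------------------------------
    try:
        table = atio.read_gene_disease_table(config.gene_disease)
        matrix = atio.read_gct(config.expression)
        records, _skipped = atio.read_sample_metadata(
            config.sample_attributes, config.subject_phenotypes
        )
        dataset = atio.attach_metadata(matrix, records)
        edges = atio.read_scored_edges(config.interactions)
        annotations = atio.read_gmt(config.annotations)
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    # --- stage: candidate selection ------------------------------------------
    try:
        candidates = select_candidate_genes(table, config.diseases)
    except Exception as exc:
        raise PipelineError("select", str(exc)) from exc
    manifest.n_candidates = len(candidates)
    expressed = {g for g in candidates if g in dataset}
    manifest.n_candidates_expressed = len(expressed)
    log.info("candidates: %d (%d expressed)", len(candidates), len(expressed))

    # --- stage: per-tissue screen ---------------------------------------------
    tissues = config.tissues or dataset.tissues
    unknown = set(tissues) - set(dataset.tissues)
    if unknown:
        raise PipelineError("screen", f"unknown tissues {sorted(unknown)}")
    all_results = []
    try:
        for tissue in tissues:
            results = screen_tissue(dataset, tissue, expressed, config.trend)
            all_results.extend(results)
        if config.trend.correction_scope == "global":
            all_results = apply_global_correction(all_results, config.trend.alpha)
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc

    screen_frame = results_to_frame(all_results)
    _write(screen_frame, outdir / "trend_results.tsv")
    significant_by_tissue: dict[str, set[str]] = {}
    for tissue in tissues:
        tres = [r for r in all_results if r.tissue == tissue]
        manifest.monotone_per_tissue[tissue] = {
            "increasing": sum(1 for r in tres if r.direction == "increasing"),
            "decreasing": sum(1 for r in tres if r.direction == "decreasing"),
        }
        sig = {r.gene for r in tres if r.significant}
        significant_by_tissue[tissue] = sig
        manifest.significant_per_tissue[tissue] = len(sig)
        hm = heatmap_matrix(tres, significant_only=True)
        safe = tissue.replace(" ", "_").replace("/", "_")
        _write(hm, outdir / f"heatmap_{safe}.tsv", index=True)
        log.info("tissue %s: %d significant genes", tissue, len(sig))

    significant_union: set[str] = set().union(*significant_by_tissue.values()) if significant_by_tissue else set()
    manifest.n_significant_union = len(significant_union)

    if not significant_union:
        log.warning("no significant genes; network, clustering and enrichment skipped")
        (outdir / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
        return manifest

    # --- stage: networks -------------------------------------------------------
    try:
        for tissue in tissues:
            sig = significant_by_tissue[tissue]
            if not sig:
                continue
            net_t = induce_network(edges, sig, config.min_score, config.channel,
                                   config.score_strict)
            safe = tissue.replace(" ", "_").replace("/", "_")
            _write(net_t.to_edge_frame(), outdir / f"network_{safe}.tsv")
        net = induce_network(edges, significant_union, config.min_score,
                             config.channel, config.score_strict)
        stats = network_stats(net)
        observed, p_conn = connectivity_pvalue(
            edges, significant_union & edges.nodes, config.min_score,
            n_perm=config.n_perm, seed=config.seed,
            strict=config.score_strict, channel=config.channel,
        )
    except Exception as exc:
        raise PipelineError("network", str(exc)) from exc
    _write(net.to_edge_frame(), outdir / "network_combined.tsv")
    node_frame = net.to_node_frame()
    _write(node_frame, outdir / "network_nodes.tsv")
    stats_frame = stats.to_frame()
    stats_frame["connectivity_observed_edges"] = observed
    stats_frame["connectivity_p"] = p_conn
    _write(stats_frame, outdir / "network_stats.tsv")
    manifest.network_nodes = stats.n_nodes
    manifest.network_edges = stats.n_edges
    manifest.network_mean_degree = stats.mean_degree
    manifest.connectivity_observed_edges = observed
    manifest.connectivity_p = p_conn
    log.info("combined network: %d nodes, %d edges, mean degree %.2f, connectivity p=%.3g",
             stats.n_nodes, stats.n_edges, stats.mean_degree, p_conn)

    # --- stage: clustering ------------------------------------------------------
    try:
        clusters = mcl(net, config.mcl)
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc
    _write(clusters.to_frame(), outdir / "clusters.tsv")
    _write(cluster_summary(clusters, net), outdir / "cluster_summary.tsv")
    manifest.n_clusters = len(clusters)
    log.info("MCL: %d clusters in %d iterations (converged=%s)",
             len(clusters), clusters.n_iter, clusters.converged)

    # --- stage: enrichment -------------------------------------------------------
    try:
        enrich_rows = []
        for tissue in tissues:
            sig = significant_by_tissue[tissue]
            if not sig or not (sig & annotations.universe):
                continue
            for r in enrich(sig, annotations):
                row = enrichment_to_frame([r]).iloc[0].to_dict()
                row["scope"] = f"tissue:{tissue}"
                enrich_rows.append(row)
        for i, cluster in enumerate(clusters.clusters):
            if not (set(cluster) & annotations.universe):
                continue
            for r in enrich(cluster, annotations):
                row = enrichment_to_frame([r]).iloc[0].to_dict()
                row["scope"] = f"cluster:{i}"
                enrich_rows.append(row)
    except Exception as exc:
        raise PipelineError("enrich", str(exc)) from exc
    enrich_frame = pd.DataFrame(enrich_rows)
    _write(enrich_frame, outdir / "enrichment.tsv")
    if not enrich_frame.empty:
        manifest.n_enriched_terms_fdr05 = int(enrich_frame["significant_fdr05"].sum())

    (outdir / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    log.info("pipeline complete; outputs in %s", outdir)
    return manifest
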