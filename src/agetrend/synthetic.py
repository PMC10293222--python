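"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates an age-stratified bulk-expression study: per
tissue, six donor age bins with a fixed number of samples each; gene
expression log-normal around a per-gene baseline; a configurable number
of genes with a planted monotone age trend (a fixed log-fold-change per
age class, in one tissue each); an Erdos-Renyi scored interaction graph
over the gene universe; and annotation sets with one term planted to be
enriched in the trend genes among uniform decoys.  Every draw comes
from one numpy PCG64 generator seeded from the config, so output is
fully reproducible.

Expression model, gene g / tissue t / age bin with index i / sample s:

    e(g, s) = exp(mu_g + d_{g,t} * effect_size * i + eps_s),
    eps_s ~ Normal(0, noise_sigma^2),  mu_g ~ Normal(baseline_log_mean,
    baseline_log_sd^2),  d_{g,t} in {+1, -1, 0} from the truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .datamodel import (
    AGE_GROUPS,
    AnnotationCollection,
    ExpressionDataset,
    GeneDiseaseTable,
    SampleRecord,
    ScoredEdgeList,
    Sex,
)
from . import io as atio

__all__ = ["GeneratorConfig", "TruthTable", "generate_expression",
           "generate_interactions", "generate_annotations", "write_bundle"]

#: Comorbidity labels used for the synthetic gene-disease table.
DISEASES = (
    "atherosclerosis",
    "cardiovascular",
    "diabetic nephropathy",
    "diabetic neuropathy",
    "diabetic retinopathy",
)

PLANTED_TERM_ID = "TERM_PLANTED"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic bundle.

    Defaults are the stochastic-recovery conditions the test-suite
    exercises: 300 genes, 30 planted increasing + 30 decreasing trends
    of 0.4 log-units per age class under log-normal noise of sigma 0.25,
    25 samples per (tissue, age bin).
    """

    n_genes: int = 300
    n_tissues: int = 3
    samples_per_bin: int = 25
    planted_increasing: int = 30
    planted_decreasing: int = 30
    effect_size: float = 0.4
    noise_sigma: float = 0.25
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.0
    edge_prob: float = 0.02
    planted_term_size: int = 40
    planted_term_overlap: int = 30
    n_decoy_terms: int = 50
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_tissues, self.samples_per_bin) < 1:
            raise ValueError("n_genes, n_tissues and samples_per_bin must be >= 1")
        if self.planted_increasing < 0 or self.planted_decreasing < 0:
            raise ValueError("planted counts must be >= 0")
        if self.planted_increasing + self.planted_decreasing > self.n_genes:
            raise ValueError("planted_increasing + planted_decreasing exceeds n_genes")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ValueError("edge_prob must lie in [0, 1]")
        if self.noise_sigma < 0 or self.baseline_log_sd < 0:
            raise ValueError("noise_sigma and baseline_log_sd must be >= 0")
        if not 0 <= self.planted_term_overlap <= self.planted_term_size <= self.n_genes:
            raise ValueError("need 0 <= planted_term_overlap <= planted_term_size <= n_genes")
        if self.n_decoy_terms < 0:
            raise ValueError("n_decoy_terms must be >= 0")


@dataclass
class TruthTable:
    """Ground truth of a generated bundle, for parameter recovery."""

    directions: dict[tuple[str, str], str]
    tissues: list[str]
    genes: list[str]
    planted_term_id: str | None = None

    def direction(self, gene: str, tissue: str) -> str:
        return self.directions.get((gene, tissue), "none")

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        return set(self.directions)

    @property
    def planted_genes(self) -> set[str]:
        return {g for g, _ in self.directions}

    def to_rows(self) -> list[tuple[str, str, str]]:
        return sorted((g, t, d) for (g, t), d in self.directions.items())


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _tissue_names(n: int) -> list[str]:
    return [f"tissue_{i:02d}" for i in range(1, n + 1)]


def generate_expression(config: GeneratorConfig) -> tuple[ExpressionDataset, TruthTable]:
    """Draw one expression bundle (matrix + metadata) and its truth table.

    Trend genes are chosen without replacement; each trends in exactly
    one (uniformly chosen) tissue and is flat elsewhere, mirroring the
    tissue specificity of real age trends.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    tissues = _tissue_names(config.n_tissues)

    n_planted = config.planted_increasing + config.planted_decreasing
    chosen = rng.choice(config.n_genes, size=n_planted, replace=False)
    directions: dict[tuple[str, str], str] = {}
    dir_matrix = np.zeros((config.n_genes, config.n_tissues), dtype=int)
    for rank, gi in enumerate(chosen):
        d = 1 if rank < config.planted_increasing else -1
        ti = int(rng.integers(config.n_tissues))
        dir_matrix[gi, ti] = d
        directions[(genes[gi], tissues[ti])] = "increasing" if d > 0 else "decreasing"
    truth = TruthTable(directions, tissues, genes)

    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes)

    samples: list[SampleRecord] = []
    tissue_of_col: list[int] = []
    age_of_col: list[int] = []
    donor = 0
    for ti, tissue in enumerate(tissues):
        for age in AGE_GROUPS:
            for _ in range(config.samples_per_bin):
                donor += 1
                subject = f"SYN-{donor:05d}"
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                samples.append(
                    SampleRecord(f"{subject}-{ti + 1:04d}", subject, tissue, sex, age)
                )
                tissue_of_col.append(ti)
                age_of_col.append(age.index)

    tissue_of_col = np.asarray(tissue_of_col)
    age_of_col = np.asarray(age_of_col)
    # log-scale mean: baseline + direction * effect * age index
    log_mean = mu[:, None] + dir_matrix[:, tissue_of_col] * config.effect_size * age_of_col[None, :]
    noise = rng.normal(0.0, config.noise_sigma, size=log_mean.shape) if config.noise_sigma > 0 else 0.0
    values = np.exp(log_mean + noise)
    return ExpressionDataset(genes, samples, values), truth


def generate_interactions(genes: Iterable[str], edge_prob: float, seed: int) -> ScoredEdgeList:
    """Erdos-Renyi background graph with Uniform(0, 1) confidence scores."""
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in [0, 1]")
    genes = list(genes)
    rng = np.random.default_rng(seed)
    n = len(genes)
    rows: list[tuple[str, str, float, str]] = []
    if n >= 2 and edge_prob > 0:
        iu, ju = np.triu_indices(n, k=1)
        present = rng.random(iu.size) < edge_prob
        scores = rng.random(iu.size)
        for i, j, s in zip(iu[present], ju[present], scores[present]):
            rows.append((genes[i], genes[j], float(s), "physical"))
    return ScoredEdgeList(rows)


def generate_annotations(
    genes: Iterable[str],
    config: GeneratorConfig,
    planted_genes: Iterable[str] = (),
    seed: int | None = None,
) -> AnnotationCollection:
    """Annotation sets with one term planted in the trend genes.

    The planted term contains exactly ``planted_term_overlap`` genes
    from ``planted_genes`` plus fillers from the rest of the universe;
    decoy terms are drawn uniformly from the whole universe.
    """
    genes = list(genes)
    planted = sorted(set(planted_genes))
    if config.planted_term_overlap > len(planted):
        raise ValueError(
            f"planted_term_overlap={config.planted_term_overlap} exceeds the "
            f"{len(planted)} planted genes available"
        )
    rest = sorted(set(genes) - set(planted))
    n_fill = config.planted_term_size - config.planted_term_overlap
    if n_fill > len(rest):
        raise ValueError("planted_term_size infeasible for this universe")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    in_term = list(rng.choice(planted, size=config.planted_term_overlap, replace=False))
    in_term += list(rng.choice(rest, size=n_fill, replace=False))
    terms: dict[str, tuple[str, frozenset[str]]] = {
        PLANTED_TERM_ID: ("planted enriched term", frozenset(in_term))
    }
    for i in range(1, config.n_decoy_terms + 1):
        size = int(rng.integers(10, max(11, config.planted_term_size + 11)))
        size = min(size, len(genes))
        members = rng.choice(genes, size=size, replace=False)
        terms[f"TERM_{i:04d}"] = (f"decoy term {i}", frozenset(members))
    return AnnotationCollection(terms)


def _gene_disease_rows(genes: list[str], rng: np.random.Generator) -> list[tuple[str, str]]:
    rows = []
    for g in genes:
        k = 1 + int(rng.random() < 0.25)  # ~25% of genes shared by two diseases
        for d in rng.choice(len(DISEASES), size=k, replace=False):
            rows.append((g, DISEASES[int(d)]))
    return rows


def write_bundle(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a full input bundle on disk and return the file paths.

    Files: expression.gct, sample_attributes.tsv, subject_phenotypes.tsv,
    gene_disease.tsv, interactions.tsv, annotations.gmt, truth.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_expression(config)
    edges = generate_interactions(dataset.genes, config.edge_prob, config.seed + 1)
    ann_config = config
    if config.planted_term_overlap > len(truth.planted_genes):
        # fewer trend genes than the requested overlap: clamp, keep term size
        ann_config = replace(config, planted_term_overlap=len(truth.planted_genes))
    annotations = generate_annotations(
        dataset.genes, ann_config, planted_genes=truth.planted_genes, seed=config.seed + 2
    )
    truth.planted_term_id = PLANTED_TERM_ID
    rng = np.random.default_rng(config.seed + 3)
    table = GeneDiseaseTable(_gene_disease_rows(dataset.genes, rng))

    paths = {
        "expression": outdir / "expression.gct",
        "sample_attributes": outdir / "sample_attributes.tsv",
        "subject_phenotypes": outdir / "subject_phenotypes.tsv",
        "gene_disease": outdir / "gene_disease.tsv",
        "interactions": outdir / "interactions.tsv",
        "annotations": outdir / "annotations.gmt",
        "truth": outdir / "truth.tsv",
    }
    atio.write_gct(dataset, paths["expression"])
    atio.write_sample_metadata(dataset.samples, paths["sample_attributes"],
                               paths["subject_phenotypes"])
    atio.write_gene_disease_table(table, paths["gene_disease"])
    atio.write_scored_edges(edges, paths["interactions"])
    atio.write_gmt(annotations, paths["annotations"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("gene\ttissue\ttrue_direction\n")
        for g, t, d in truth.to_rows():
            fh.write(f"{g}\t{t}\t{d}\n")
    return paths
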