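"""Readers and writers for the external formats the pipeline touches.

Formats: GCT v1.2 expression matrices, GTEx-dialect sample-attribute and
subject-phenotype TSVs, STRING-style scored edge lists, GMT annotation
collections and two-column gene-disease TSVs.  All output is UTF-8,
tab-delimited, LF-terminated.  Readers validate eagerly and raise
:class:`ParseError` with the offending 1-based line number.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .datamodel import (
    AgeGroup,
    AnnotationCollection,
    ExpressionDataset,
    GeneDiseaseTable,
    SampleRecord,
    ScoredEdgeList,
    Sex,
)

log = logging.getLogger("agetrend")

__all__ = [
    "ParseError",
    "read_gct",
    "write_gct",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_scored_edges",
    "write_scored_edges",
    "read_gmt",
    "write_gmt",
    "read_gene_disease_table",
    "write_gene_disease_table",
    "attach_metadata",
]


class ParseError(ValueError):
    """Malformed input file; carries the file path and 1-based line number."""

    def __init__(self, path: object, line: int | None, message: str):
        self.path = str(path)
        self.line = line
        where = f"{self.path}:{line}" if line is not None else self.path
        super().__init__(f"{where}: {message}")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8", newline="" if "w" in mode else None)
    return open(path, mode, encoding="utf-8", newline="" if "w" in mode else None)


# ---------------------------------------------------------------------------
# GCT v1.2
# ---------------------------------------------------------------------------

def read_gct(path: str | Path) -> ExpressionDataset:
    """Read a GCT v1.2 matrix into an ExpressionDataset without metadata.

    Gene symbols come from the Description column when non-empty, else
    from Name.  Sample metadata is attached separately; placeholder
    records carry the tissue/age fields as unknown.
    """
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise ParseError(path, 1, "expected GCT version line '#1.2'")
    if len(lines) < 3:
        raise ParseError(path, 2, "truncated GCT file (missing dimensions/header)")
    dims = lines[1].split("\t")
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except (ValueError, IndexError):
        raise ParseError(path, 2, f"malformed dimensions line {lines[1]!r}") from None
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name":
        raise ParseError(path, 3, "header must start with 'Name<TAB>Description'")
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise ParseError(
            path, 3, f"declared {n_samples} samples but header lists {len(sample_ids)}"
        )
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise ParseError(path, 3, f"duplicate sample id {dup!r}")

    data_lines = [ln for ln in lines[3:] if ln.strip()]
    if len(data_lines) != n_genes:
        raise ParseError(
            path, len(lines), f"declared {n_genes} genes but found {len(data_lines)} data rows"
        )
    genes: list[str] = []
    values = np.empty((n_genes, n_samples), dtype=float)
    for i, ln in enumerate(data_lines):
        lineno = i + 4
        fields = ln.split("\t")
        if len(fields) != n_samples + 2:
            raise ParseError(
                path, lineno, f"expected {n_samples + 2} columns, found {len(fields)}"
            )
        name, desc = fields[0], fields[1]
        genes.append(desc if desc.strip() else name)
        try:
            values[i] = [float(x) for x in fields[2:]]
        except ValueError:
            bad = next(x for x in fields[2:] if not _is_float(x))
            raise ParseError(path, lineno, f"non-numeric expression cell {bad!r}") from None
    if len(set(genes)) != len(genes):
        dup = next(g for g in genes if genes.count(g) > 1)
        raise ParseError(path, None, f"duplicate gene symbol {dup!r}")
    samples = [
        SampleRecord(sid, sid, tissue="unknown", sex=Sex.UNKNOWN, age_group=AgeGroup.A20_29)
        for sid in sample_ids
    ]
    # Age placeholder is overwritten by attach_metadata before any analysis.
    return ExpressionDataset(genes, samples, values)


def _is_float(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def write_gct(dataset_or_genes, path: str | Path, sample_ids: list[str] | None = None,
              values: np.ndarray | None = None) -> None:
    """Write a GCT v1.2 file from an ExpressionDataset or (genes, ids, matrix)."""
    if isinstance(dataset_or_genes, ExpressionDataset):
        genes = dataset_or_genes.genes
        sample_ids = [s.sample_id for s in dataset_or_genes.samples]
        values = dataset_or_genes.values
    else:
        genes = list(dataset_or_genes)
        if sample_ids is None or values is None:
            raise ValueError("sample_ids and values are required without a dataset")
    values = np.asarray(values, dtype=float)
    with _open_text(path, "wt") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(genes)}\t{len(sample_ids)}\n")
        fh.write("Name\tDescription\t" + "\t".join(sample_ids) + "\n")
        for g, row in zip(genes, values):
            fh.write(g + "\t" + g + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# Sample attributes + subject phenotypes (GTEx dialect)
# ---------------------------------------------------------------------------

#: Number of leading dash-separated sample-id tokens that form the subject id.
SUBJECT_ID_TOKENS = 2


def subject_from_sample(sample_id: str, n_tokens: int = SUBJECT_ID_TOKENS) -> str:
    return "-".join(sample_id.split("-")[:n_tokens])


@dataclass(frozen=True)
class SkippedSample:
    sample_id: str
    reason: str


def read_sample_metadata(
    attr_path: str | Path,
    pheno_path: str | Path,
    *,
    sample_col: str = "SAMPID",
    tissue_col: str = "SMTSD",
    subject_col: str = "SUBJID",
    sex_col: str = "SEX",
    age_col: str = "AGE",
    subject_id_tokens: int = SUBJECT_ID_TOKENS,
) -> tuple[list[SampleRecord], list[SkippedSample]]:
    """Join a sample-attribute TSV to a subject-phenotype TSV.

    The subject id is derived from the leading dash-separated tokens of
    the sample id.  Samples whose subject is missing from the phenotype
    table, or whose age string is outside the six decade classes, are
    skipped and reported (returned and logged), never fatal.
    """
    attrs = pd.read_csv(attr_path, sep="\t", dtype=str)
    pheno = pd.read_csv(pheno_path, sep="\t", dtype=str)
    for col, frame, p in ((sample_col, attrs, attr_path), (tissue_col, attrs, attr_path),
                          (subject_col, pheno, pheno_path), (sex_col, pheno, pheno_path),
                          (age_col, pheno, pheno_path)):
        if col not in frame.columns:
            raise ParseError(p, 1, f"missing required column {col!r}")
    pheno_by_subject = pheno.set_index(subject_col)
    if pheno_by_subject.index.has_duplicates:
        dup = pheno_by_subject.index[pheno_by_subject.index.duplicated()][0]
        raise ParseError(pheno_path, None, f"duplicate subject id {dup!r}")

    records: list[SampleRecord] = []
    skipped: list[SkippedSample] = []
    for row in attrs.itertuples(index=False):
        sid = getattr(row, sample_col)
        tissue = getattr(row, tissue_col)
        subj = subject_from_sample(sid, subject_id_tokens)
        if subj not in pheno_by_subject.index:
            skipped.append(SkippedSample(sid, f"subject {subj!r} absent from phenotype table"))
            continue
        prow = pheno_by_subject.loc[subj]
        try:
            age = AgeGroup.parse(prow[age_col])
        except ValueError:
            skipped.append(SkippedSample(sid, f"age {prow[age_col]!r} outside the six classes"))
            continue
        records.append(SampleRecord(sid, subj, tissue, Sex.parse(prow[sex_col]), age))
    for s in skipped:
        log.warning("skipped sample %s: %s", s.sample_id, s.reason)
    return records, skipped


def write_sample_metadata(records: Iterable[SampleRecord], attr_path: str | Path,
                          pheno_path: str | Path) -> None:
    """Write the two-table GTEx-dialect metadata for a list of records."""
    records = list(records)
    with _open_text(attr_path, "wt") as fh:
        fh.write("SAMPID\tSMTSD\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.tissue}\n")
    seen: dict[str, SampleRecord] = {}
    for r in records:
        seen.setdefault(r.subject_id, r)
    with _open_text(pheno_path, "wt") as fh:
        fh.write("SUBJID\tSEX\tAGE\n")
        for subj, r in seen.items():
            sex = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: ""}[r.sex]
            fh.write(f"{subj}\t{sex}\t{r.age_group.label}\n")


def attach_metadata(dataset: ExpressionDataset, records: Iterable[SampleRecord],
                    drop_unmatched: bool = True) -> ExpressionDataset:
    """Replace a matrix-only dataset's placeholder samples with real records.

    Columns without a metadata record are dropped (or rejected when
    ``drop_unmatched`` is false).
    """
    by_id = {r.sample_id: r for r in records}
    keep_idx: list[int] = []
    keep_records: list[SampleRecord] = []
    for j, s in enumerate(dataset.samples):
        rec = by_id.get(s.sample_id)
        if rec is None:
            if not drop_unmatched:
                raise ValueError(f"no metadata for sample {s.sample_id!r}")
            continue
        keep_idx.append(j)
        keep_records.append(rec)
    return ExpressionDataset(dataset.genes, keep_records, dataset.values[:, keep_idx])


# ---------------------------------------------------------------------------
# Scored edge lists (STRING dialect)
# ---------------------------------------------------------------------------

_CHANNELS = {"physical", "functional", "unknown"}


def read_scored_edges(path: str | Path) -> ScoredEdgeList:
    """Read a whitespace/tab-delimited protein1 protein2 score[ channel] file.

    STRING distributes confidence as 0..1000 integers; if any parsed
    score exceeds 1 the whole file is divided by 1000, so both raw
    downloads and pre-normalised files parse without a flag.  Edges are
    canonicalised, self-edges dropped, duplicates merged at max score.
    """
    raw: list[tuple[str, str, float, str]] = []
    with _open_text(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            fields = ln.split()
            if (lineno == 1 and len(fields) >= 3 and not _is_float(fields[2])
                    and fields[2].lower() in {"score", "combined_score", "experimental"}):
                continue  # header row
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >=3 fields, found {len(fields)}")
            a, b = fields[0], fields[1]
            try:
                score = float(fields[2])
            except ValueError:
                raise ParseError(path, lineno, f"unparsable score {fields[2]!r}") from None
            if score < 0:
                raise ParseError(path, lineno, f"negative score {score}")
            if score > 1000:
                raise ParseError(path, lineno, f"score {score} exceeds 1000")
            channel = fields[3].lower() if len(fields) >= 4 else "unknown"
            if channel not in _CHANNELS:
                channel = "unknown"
            raw.append((a, b, score, channel))
    if any(s > 1 for _, _, s, _ in raw):
        raw = [(a, b, s / 1000.0, c) for a, b, s, c in raw]
    return ScoredEdgeList(raw)


def write_scored_edges(edges: ScoredEdgeList, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("protein1\tprotein2\tscore\tchannel\n")
        for a, b, score, channel in edges:
            fh.write(f"{a}\t{b}\t{format(score, '.17g')}\t{channel}\n")


# ---------------------------------------------------------------------------
# GMT annotation sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, universe: set[str] | None = None) -> AnnotationCollection:
    """Read a GMT file: one ``term<TAB>description<TAB>gene...`` per line."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with _open_text(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "expected at least 3 tab-separated fields")
            tid, name = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g.strip())
            if not genes:
                raise ParseError(path, lineno, f"term {tid!r} has an empty gene list")
            if tid in terms:
                raise ParseError(path, lineno, f"duplicate term id {tid!r}")
            terms[tid] = (name, genes)
    return AnnotationCollection(terms, universe=universe)


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for tid, (name, genes) in collection.items():
            fh.write(tid + "\t" + name + "\t" + "\t".join(sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Gene-disease tables
# ---------------------------------------------------------------------------

def read_gene_disease_table(path: str | Path) -> GeneDiseaseTable:
    """Read a two-column TSV with header columns ``gene`` and ``disease``."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "disease"):
        if col not in frame.columns:
            raise ParseError(path, 1, f"missing required column {col!r}")
    return GeneDiseaseTable(frame[["gene", "disease"]].itertuples(index=False, name=None))


def write_gene_disease_table(table: GeneDiseaseTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")
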