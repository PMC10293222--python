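"""Canonical in-memory data model shared by every pipeline stage.

The pipeline screens a candidate gene panel for basal-expression trends
across donor age in bulk tissue data.  Donors fall into six decade bins
(20-29 .. 70-79); expression is a dense non-negative genes x samples
matrix (TPM-like units) joined to per-sample tissue / sex / age metadata.
Downstream stages consume gene-disease tables, scored protein-interaction
edge lists and flat annotation gene-set collections.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AgeGroup",
    "Sex",
    "SampleRecord",
    "ExpressionDataset",
    "GeneDiseaseTable",
    "ScoredEdgeList",
    "AnnotationCollection",
    "canonical_edge",
]


class AgeGroup(enum.Enum):
    """The six donor age classes, in chronological order.

    ``index`` is the 0-based chronological position; it doubles as the
    age covariate for planted trends in the synthetic generator.
    """

    A20_29 = ("20-29", 0)
    A30_39 = ("30-39", 1)
    A40_49 = ("40-49", 2)
    A50_59 = ("50-59", 3)
    A60_69 = ("60-69", 4)
    A70_79 = ("70-79", 5)

    def __init__(self, label: str, index: int):
        self.label = label
        self.index = index

    @classmethod
    def parse(cls, text: str) -> "AgeGroup":
        """Parse a decade string like ``"60-69"`` (en-dash tolerated)."""
        key = str(text).strip().replace("–", "-")
        for member in cls:
            if member.label == key:
                return member
        raise ValueError(f"age group {text!r} is not one of the six decade classes")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: Age groups in chronological order (index 0..5).
AGE_GROUPS: tuple[AgeGroup, ...] = tuple(sorted(AgeGroup, key=lambda a: a.index))
N_AGE_GROUPS = len(AGE_GROUPS)


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: object) -> "Sex":
        key = str(text).strip().lower()
        if key in {"male", "m", "1"}:
            return cls.MALE
        if key in {"female", "f", "2"}:
            return cls.FEMALE
        return cls.UNKNOWN


@dataclass(frozen=True)
class SampleRecord:
    """One profiled sample: which donor, which tissue, which age bin."""

    sample_id: str
    subject_id: str
    tissue: str
    sex: Sex
    age_group: AgeGroup


class ExpressionDataset:
    """Dense gene x sample expression matrix with per-sample metadata.

    Invariants enforced at construction: unique gene symbols, unique
    sample ids, matrix shape (n_genes, n_samples), no negative values.
    """

    def __init__(
        self,
        genes: Iterable[str],
        samples: Iterable[SampleRecord],
        values: np.ndarray,
    ):
        self.genes: list[str] = list(genes)
        self.samples: list[SampleRecord] = list(samples)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols are not unique")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids are not unique")
        if self.values.size and np.nanmin(self.values) < 0:
            raise ValueError("expression values must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def tissues(self) -> list[str]:
        """Distinct tissue labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.tissue, None)
        return list(seen)

    def gene_row(self, gene: str) -> np.ndarray:
        return self.values[self._gene_index[gene]]

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def sample_mask(self, tissue: str | None = None, age_group: AgeGroup | None = None) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        if tissue is not None:
            mask &= np.fromiter((s.tissue == tissue for s in self.samples), bool, self.n_samples)
        if age_group is not None:
            mask &= np.fromiter((s.age_group is age_group for s in self.samples), bool, self.n_samples)
        return mask


class GeneDiseaseTable:
    """Curated gene -> disease association table (unique pairs)."""

    def __init__(self, rows: Iterable[tuple[str, str]]):
        seen: dict[tuple[str, str], None] = {}
        for gene, disease in rows:
            seen.setdefault((str(gene), str(disease)), None)
        self.rows: list[tuple[str, str]] = list(seen)
        if not self.rows:
            self._frame = pd.DataFrame(columns=["gene", "disease"])
        else:
            self._frame = pd.DataFrame(self.rows, columns=["gene", "disease"])

    @property
    def diseases(self) -> list[str]:
        return sorted(self._frame["disease"].unique())

    def genes_for(self, disease: str) -> set[str]:
        if disease not in set(self._frame["disease"]):
            raise KeyError(f"unknown disease {disease!r}")
        return set(self._frame.loc[self._frame["disease"] == disease, "gene"])

    def gene_union(self, diseases: Iterable[str] | None = None) -> set[str]:
        """Union of gene sets over ``diseases`` (all diseases when None/empty)."""
        allow = list(diseases) if diseases else []
        if not allow:
            return set(self._frame["gene"])
        out: set[str] = set()
        for d in allow:
            out |= self.genes_for(d)
        return out

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self.rows)


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Undirected edge key: endpoints in lexicographic order."""
    return (a, b) if a <= b else (b, a)


class ScoredEdgeList:
    """Undirected scored interaction edges, canonicalised and de-duplicated.

    Scores live in [0, 1]; duplicate (a, b) rows are merged keeping the
    maximum score; self-edges are dropped (their count is retained in
    ``n_self_edges_dropped``).
    """

    COLUMNS = ("protein_a", "protein_b", "score", "channel")

    def __init__(
        self,
        rows: Iterable[tuple[str, str, float, str]],
        n_self_edges_dropped: int = 0,
    ):
        best: dict[tuple[str, str], tuple[float, str]] = {}
        dropped = n_self_edges_dropped
        order: list[tuple[str, str]] = []
        for a, b, score, channel in rows:
            a, b = str(a), str(b)
            score = float(score)
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"edge score {score} outside [0, 1]")
            if a == b:
                dropped += 1
                continue
            key = canonical_edge(a, b)
            if key not in best:
                order.append(key)
                best[key] = (score, channel)
            elif score > best[key][0]:
                best[key] = (score, channel)
        self._frame = pd.DataFrame(
            [(a, b, best[(a, b)][0], best[(a, b)][1]) for a, b in order],
            columns=list(self.COLUMNS),
        )
        self.n_self_edges_dropped = dropped

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def nodes(self) -> set[str]:
        if self._frame.empty:
            return set()
        return set(self._frame["protein_a"]) | set(self._frame["protein_b"])

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[tuple[str, str, float, str]]:
        return iter(self._frame.itertuples(index=False, name=None))

    def filtered(self, min_score: float, strict: bool = False, channel: str | None = None) -> "ScoredEdgeList":
        """Edges at or above a confidence cutoff (``strict`` -> above only).

        ``channel`` keeps edges of that channel; ``unknown`` edges always
        pass (files without a channel column carry no evidence either way).
        """
        f = self._frame
        keep = f["score"] > min_score if strict else f["score"] >= min_score
        if channel is not None:
            keep &= (f["channel"] == channel) | (f["channel"] == "unknown")
        return ScoredEdgeList(f.loc[keep].itertuples(index=False, name=None))


class AnnotationCollection:
    """Flat annotation gene sets (GO/KEGG-style) keyed by term id."""

    def __init__(
        self,
        terms: Mapping[str, tuple[str, frozenset[str]]],
        universe: set[str] | None = None,
    ):
        self.terms: dict[str, tuple[str, frozenset[str]]] = {
            tid: (name, frozenset(genes)) for tid, (name, genes) in terms.items()
        }
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid!r} has an empty gene set")
            if universe is not None and not genes <= universe:
                raise ValueError(f"term {tid!r} contains genes outside the supplied universe")
        self._explicit_universe = set(universe) if universe is not None else None

    @property
    def universe(self) -> set[str]:
        """Explicit universe if supplied, else the union of all term sets."""
        if self._explicit_universe is not None:
            return set(self._explicit_universe)
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return out

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def items(self):
        return self.terms.items()
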