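"""Age-trend screening: binned median profiles, monotone classification,
Kruskal-Wallis significance and Bonferroni correction.

For each (gene, tissue) the samples are grouped into the six donor age
bins, per-bin medians are computed, and a gene is a candidate trend gene
when its usable bin medians are monotonically increasing or decreasing.
Candidates are then tested with a tie-corrected Kruskal-Wallis test over
the age-bin groups; p-values are Bonferroni-corrected within the tissue
(the correction family is every test performed in that tissue) and
flagged significant below ``alpha`` (default 0.01 after correction).

Medians, not means, summarise each bin: expression is strongly skewed on
the natural scale, and the binned-median profile is also what the
exported heatmap matrices contain.  A mean-based summary is available
via ``TrendConfig.summary``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .datamodel import AGE_GROUPS, N_AGE_GROUPS, ExpressionDataset

__all__ = [
    "AgeProfile",
    "TrendConfig",
    "TrendResult",
    "build_age_profiles",
    "classify_trend",
    "kruskal_wallis",
    "bonferroni",
    "screen_tissue",
    "results_to_frame",
    "heatmap_matrix",
]

Direction = Literal["increasing", "decreasing", "none"]


@dataclass
class AgeProfile:
    """Per-(gene, tissue) expression grouped by age bin, oldest last.

    ``bin_medians[i]`` is NaN when bin i has no samples.
    """

    gene: str
    tissue: str
    bin_values: list[np.ndarray]
    bin_medians: np.ndarray
    bin_counts: np.ndarray

    def reversed(self) -> "AgeProfile":
        """The same profile with the age axis flipped (for symmetry checks)."""
        return AgeProfile(
            self.gene,
            self.tissue,
            self.bin_values[::-1],
            self.bin_medians[::-1].copy(),
            self.bin_counts[::-1].copy(),
        )


@dataclass
class TrendConfig:
    """Knobs of the screening stage.

    alpha: significance level on the corrected p-value.
    min_bin_count: bins with fewer samples are dropped from both the
        monotone sequence and the test groups (a single observation
        makes a degenerate group).
    monotone_rule: 'weak' allows ties between consecutive medians as
        long as at least one step is strict; 'strict' requires every
        step to be strict.
    correction_scope: Bonferroni family — every test in one tissue
        ('per_tissue') or every test in the run ('global', applied by
        the pipeline across tissues).
    summary: per-bin location summary, median (default) or mean.
    """

    alpha: float = 0.01
    min_bin_count: int = 2
    monotone_rule: Literal["strict", "weak"] = "weak"
    correction_scope: Literal["per_tissue", "global"] = "per_tissue"
    summary: Literal["median", "mean"] = "median"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_bin_count < 1:
            raise ValueError("min_bin_count must be >= 1")


@dataclass
class TrendResult:
    gene: str
    tissue: str
    direction: Direction
    H: float
    p_raw: float
    p_adj: float
    n_total: int
    significant: bool
    bin_medians: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    bin_counts: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def build_age_profiles(
    dataset: ExpressionDataset,
    tissue: str,
    genes: Iterable[str],
    summary: Literal["median", "mean"] = "median",
) -> tuple[list[AgeProfile], list[str]]:
    """Group a tissue's samples by age bin for each requested gene.

    Returns the profiles plus the requested genes absent from the matrix
    (skipped, reported).  The per-bin median follows the usual even-count
    convention (mean of the central pair).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("no genes requested")
    if tissue not in dataset.tissues:
        raise KeyError(f"unknown tissue {tissue!r}")
    present = [g for g in genes if g in dataset]
    skipped = [g for g in genes if g not in dataset]
    if not present:
        raise ValueError(f"none of the {len(genes)} requested genes are in the matrix")

    tissue_mask = dataset.sample_mask(tissue=tissue)
    bin_cols = [
        np.flatnonzero(tissue_mask & dataset.sample_mask(age_group=a)) for a in AGE_GROUPS
    ]
    summarise = np.median if summary == "median" else np.mean
    profiles: list[AgeProfile] = []
    for g in present:
        row = dataset.gene_row(g)
        values = [row[cols] for cols in bin_cols]
        medians = np.array([summarise(v) if v.size else np.nan for v in values])
        counts = np.array([v.size for v in values])
        profiles.append(AgeProfile(g, tissue, values, medians, counts))
    return profiles, skipped


def classify_trend(profile: AgeProfile, config: TrendConfig | None = None) -> Direction:
    """Monotone direction of the usable bin medians.

    Bins with undefined medians or fewer than ``min_bin_count`` samples
    are excluded; fewer than two usable bins yields 'none'.  Weak rule:
    increasing iff every consecutive difference >= 0 and at least one
    > 0 (decreasing symmetric); strict rule: every difference strictly
    signed.
    """
    config = config or TrendConfig()
    usable = (profile.bin_counts >= config.min_bin_count) & ~np.isnan(profile.bin_medians)
    seq = profile.bin_medians[usable]
    return classify_sequence(seq, config.monotone_rule)


def classify_sequence(seq: Sequence[float], rule: Literal["strict", "weak"] = "weak") -> Direction:
    """Monotone direction of an ordered value sequence (see classify_trend)."""
    seq = np.asarray(seq, dtype=float)
    if seq.size < 2:
        return "none"
    d = np.diff(seq)
    if rule == "strict":
        if np.all(d > 0):
            return "increasing"
        if np.all(d < 0):
            return "decreasing"
        return "none"
    if np.all(d >= 0) and np.any(d > 0):
        return "increasing"
    if np.all(d <= 0) and np.any(d < 0):
        return "decreasing"
    return "none"


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    H = [12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)] / C with mid-ranks for
    ties and C = 1 - sum(t^3 - t)/(N^3 - N); p is the chi-square upper
    tail with k-1 degrees of freedom.  When every value is identical the
    correction degenerates and (H, p) = (0, 1) is returned.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size == 0:
            raise ValueError("empty group")
    n_total = int(sum(g.size for g in groups))
    if n_total < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = scipy.stats.kruskal(*groups)
    return float(H), float(p)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p -> min(1, p * m), m defaulting to len(p)."""
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValueError(f"family size m={m} smaller than number of p-values {len(ps)}")
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, p * m) for p in ps]


def screen_tissue(
    dataset: ExpressionDataset,
    tissue: str,
    candidate_genes: Iterable[str],
    config: TrendConfig | None = None,
) -> list[TrendResult]:
    """Run the full per-tissue screen over a candidate gene panel.

    Stage order: age-bin profiles -> monotone classification -> KW test
    on every monotone gene's usable bin groups -> Bonferroni with m =
    number of tests performed in the tissue -> significance at alpha.
    Non-monotone genes are carried through with direction 'none' and
    p = 1 (untested).  Results are sorted by adjusted p then gene.
    """
    config = config or TrendConfig()
    candidates = sorted(set(candidate_genes))
    if not candidates:
        return []
    present = [g for g in candidates if g in dataset]
    if not present:
        return []
    profiles, _skipped = build_age_profiles(dataset, tissue, present, summary=config.summary)

    tested: list[tuple[AgeProfile, Direction, float, float, int]] = []
    untested: list[tuple[AgeProfile, Direction]] = []
    for prof in profiles:
        direction = classify_trend(prof, config)
        if direction == "none":
            untested.append((prof, direction))
            continue
        usable = (prof.bin_counts >= config.min_bin_count) & ~np.isnan(prof.bin_medians)
        groups = [prof.bin_values[i] for i in np.flatnonzero(usable)]
        n_total = int(sum(len(g) for g in groups))
        H, p = kruskal_wallis(groups)
        tested.append((prof, direction, H, p, n_total))

    m = len(tested)
    p_adj = bonferroni([t[3] for t in tested], m) if tested else []
    results: list[TrendResult] = []
    for (prof, direction, H, p, n_total), padj in zip(tested, p_adj):
        results.append(
            TrendResult(
                prof.gene, tissue, direction, H, p, padj, n_total,
                significant=bool(padj < config.alpha),
                bin_medians=prof.bin_medians, bin_counts=prof.bin_counts,
            )
        )
    for prof, direction in untested:
        results.append(
            TrendResult(
                prof.gene, tissue, "none", math.nan, 1.0, 1.0,
                int(prof.bin_counts.sum()), significant=False,
                bin_medians=prof.bin_medians, bin_counts=prof.bin_counts,
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.gene))
    return results


def apply_global_correction(results: Iterable[TrendResult], alpha: float) -> list[TrendResult]:
    """Re-correct tested results with a single Bonferroni family across tissues."""
    results = list(results)
    tested = [r for r in results if r.direction != "none"]
    m = len(tested)
    for r in tested:
        r.p_adj = min(1.0, r.p_raw * m)
        r.significant = bool(r.p_adj < alpha)
    return results


def results_to_frame(results: Iterable[TrendResult]) -> pd.DataFrame:
    """Tabular export: one row per (gene, tissue) with medians and counts."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "gene": r.gene,
            "tissue": r.tissue,
            "direction": r.direction,
            "n_total": r.n_total,
        }
        for a, c in zip(AGE_GROUPS, r.bin_counts):
            row[f"n_{a.label}"] = int(c)
        for a, mval in zip(AGE_GROUPS, r.bin_medians):
            row[f"median_{a.label}"] = mval
        row.update(H=r.H, p_raw=r.p_raw, p_adj=r.p_adj, significant=r.significant)
        rows.append(row)
    return pd.DataFrame(rows)


def heatmap_matrix(results: Iterable[TrendResult], significant_only: bool = True) -> pd.DataFrame:
    """Genes x six-age-class median matrix, heatmap-ready."""
    rows = {}
    for r in results:
        if significant_only and not r.significant:
            continue
        rows[r.gene] = {a.label: mval for a, mval in zip(AGE_GROUPS, r.bin_medians)}
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=[a.label for a in AGE_GROUPS])
    frame.index.name = "gene"
    return frame
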