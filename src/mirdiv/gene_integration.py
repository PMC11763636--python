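"""Projecting miRNA directional grades onto target genes.

Each gene inherits a ``mean_div`` — the average div of the distinct miRNAs
that target it (after the experiment-count filter) — and a ``mean_log_fc`` —
its average log2 fold change across cancer types.  Plotting genes in the
(mean_div, mean_log_fc) plane splits them into four quadrants:

    I   mean_div > 0, mean_log_fc > 0   targeting miRNAs net-down, gene up
    II  mean_div < 0, mean_log_fc > 0   targeting miRNAs net-up,  gene up
    III mean_div < 0, mean_log_fc < 0   targeting miRNAs net-up,  gene down
    IV  mean_div > 0, mean_log_fc < 0   targeting miRNAs net-down, gene down

A gene sitting exactly on an axis is labelled ``axis``.  Genes far from the
origin carry the strongest joint signal; distance is the Euclidean norm after
per-axis z-standardization (so the two differently-scaled axes are
commensurable and the ranking is scale-free; a zero-variance axis contributes
zero).  Global concordance between the two axes is tested with a Spearman
rank correlation and a seeded two-sided permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .expression_stats import MirnaDivSummary
from .io_formats import GeneExpressionRecord, TargetLink

__all__ = [
    "GeneSummary",
    "compute_gene_mean_logfc",
    "compute_gene_mean_div",
    "classify_quadrant",
    "build_gene_summaries",
    "rank_genes_by_distance",
    "mirna_gene_concordance",
]

Quadrant = Literal["I", "II", "III", "IV", "axis"]

DEFAULT_TOP_K = 50
DEFAULT_PERMUTATIONS = 999


@dataclass(frozen=True)
class GeneSummary:
    """Per-gene joint summary of miRNA pressure and own expression."""

    gene_id: str
    mean_log_fc: float
    mean_div: float
    n_targeting_mirnas: int
    n_cancers: int
    quadrant: Quadrant
    distance: float = 0.0


def compute_gene_mean_logfc(
    gene_records: Iterable[GeneExpressionRecord],
) -> dict[str, tuple[float, int]]:
    """Unweighted mean log2 fold change per gene across its cancer entries.

    Returns ``gene_id -> (mean_log_fc, n_cancers)``.
    """
    sums: dict[str, list[float]] = {}
    for rec in gene_records:
        acc = sums.setdefault(rec.gene_id, [0.0, 0])
        acc[0] += rec.log_fc
        acc[1] += 1
    return {g: (total / n, n) for g, (total, n) in sums.items()}


def compute_gene_mean_div(
    links: Iterable[TargetLink], summaries: Sequence[MirnaDivSummary]
) -> tuple[dict[str, tuple[float, int]], int]:
    """Mean div over the distinct surviving miRNAs targeting each gene.

    ``summaries`` must already be experiment-filtered.  Genes whose linked
    miRNAs all failed the filter are omitted; the second return value counts
    them.
    """
    div_by_mirna = {s.mirna_id: s.div for s in summaries}
    per_gene: dict[str, set[str]] = {}
    for link in links:
        per_gene.setdefault(link.gene_id, set()).add(link.mirna_id)
    result: dict[str, tuple[float, int]] = {}
    n_omitted = 0
    for gene_id, mirnas in per_gene.items():
        divs = [div_by_mirna[m] for m in mirnas if m in div_by_mirna]
        if not divs:
            n_omitted += 1
            continue
        result[gene_id] = (sum(divs) / len(divs), len(divs))
    return result, n_omitted


def classify_quadrant(mean_div: float, mean_log_fc: float) -> Quadrant:
    """Canonical sign-based quadrant; exact zero on either axis -> ``axis``."""
    if mean_div == 0 or mean_log_fc == 0:
        return "axis"
    if mean_div > 0:
        return "I" if mean_log_fc > 0 else "IV"
    return "II" if mean_log_fc > 0 else "III"


def build_gene_summaries(
    links: Iterable[TargetLink],
    mirna_summaries: Sequence[MirnaDivSummary],
    gene_records: Iterable[GeneExpressionRecord],
    positive_div_only: bool = False,
) -> tuple[list[GeneSummary], int]:
    """Join the miRNA and gene layers into per-gene summaries.

    Only genes present in both layers (>= 1 surviving targeting miRNA and
    >= 1 expression entry) are summarized.  ``positive_div_only`` restricts
    the output to genes with mean_div > 0 — the genes whose targeting miRNAs
    are net down-regulated and therefore the actionable side of the plane.
    Returns the summaries (gene_id-sorted) and the count of genes omitted
    because all their miRNAs failed the experiment filter.
    """
    mean_logfc = compute_gene_mean_logfc(gene_records)
    mean_div, n_omitted = compute_gene_mean_div(links, mirna_summaries)
    out: list[GeneSummary] = []
    for gene_id in sorted(mean_div.keys() & mean_logfc.keys()):
        div_val, n_mirnas = mean_div[gene_id]
        logfc_val, n_cancers = mean_logfc[gene_id]
        if positive_div_only and div_val <= 0:
            continue
        out.append(
            GeneSummary(
                gene_id=gene_id,
                mean_log_fc=logfc_val,
                mean_div=div_val,
                n_targeting_mirnas=n_mirnas,
                n_cancers=n_cancers,
                quadrant=classify_quadrant(div_val, logfc_val),
            )
        )
    return out, n_omitted


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def rank_genes_by_distance(
    gene_summaries: Sequence[GeneSummary], k: int = DEFAULT_TOP_K
) -> list[GeneSummary]:
    """Top-k genes by distance from the origin of the standardized plane.

    Each axis is z-scored over all input genes (population SD; a
    zero-variance axis maps to all zeros) before taking the Euclidean norm,
    so the ranking does not depend on the axes' units or on their order.
    Ties are broken by gene_id.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not gene_summaries:
        raise ValueError("no gene summaries to rank")
    div_z = _standardize(np.array([g.mean_div for g in gene_summaries], dtype=float))
    fc_z = _standardize(np.array([g.mean_log_fc for g in gene_summaries], dtype=float))
    dist = np.hypot(div_z, fc_z)
    ranked = [replace(g, distance=float(d)) for g, d in zip(gene_summaries, dist)]
    ranked.sort(key=lambda g: (-g.distance, g.gene_id))
    return ranked[: min(k, len(ranked))]


def mirna_gene_concordance(
    gene_summaries: Sequence[GeneSummary],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation between mean_div and mean_log_fc across genes,
    with a two-sided permutation p-value.

    The p-value is p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_permutations)
    over seeded shuffles of the mean_log_fc vector, exact under
    exchangeability of genes.  Requires >= 3 genes, >= 99 permutations and
    non-constant axes.
    """
    if len(gene_summaries) < 3:
        raise ValueError("need at least 3 genes for a concordance test")
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    x = np.array([g.mean_div for g in gene_summaries], dtype=float)
    y = np.array([g.mean_log_fc for g in gene_summaries], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: constant axis")
    r_obs = float(stats.spearmanr(x, y).statistic)

    # Permutation r values reduce to dot products of centered, unit-norm ranks.
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / np.linalg.norm(rx - rx.mean())
    ry = (ry - ry.mean()) / np.linalg.norm(ry - ry.mean())
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ry, (n_permutations, 1)), axis=1)
    r_perm = perms @ rx
    n_extreme = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    p_value = (1 + n_extreme) / (1 + n_permutations)
    return r_obs, p_value
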