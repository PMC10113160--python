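"""Distance-stratified association between regulatory elements and gene
expression.

Genes are filtered by a minimal expression threshold, log2 fold changes
between two conditions are computed from condition means (with a
pseudocount), and genes are grouped by their distance to the nearest
element of a target interval set (e.g. H3K27ac-marked TE copies).  Group
differences are tested with one-way ANOVA plus Tukey post-hoc contrasts
against the open ">last-edge" reference bin, or with rank-sum tests plus
Benjamini-Hochberg correction in two-group mode.  Also provides
TE-promoter transcript detection (multi-exonic transcripts whose TSS lies
inside an active element) and nearest-peak target-gene assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, GeneModel, IntervalSet

__all__ = [
    "ExpressionMatrix",
    "DistanceGroupTable",
    "DEFAULT_BIN_EDGES",
    "compute_log2fc",
    "gene_distances",
    "stratify_by_distance",
    "te_promoter_transcripts",
    "nearest_peak_targets",
    "family_target_fc",
]

# [0 (overlap), <=10 kb, 10-50 kb, 50-100 kb, >100 kb]
DEFAULT_BIN_EDGES = (10_000, 50_000, 100_000)


@dataclass
class ExpressionMatrix:
    """Gene-level abundances (genes x samples) with condition labels.

    ``values`` are on a linear normalized scale (e.g. RPKM-like); the unit
    is recorded in ``unit``.  Gene ids must be unique and all samples share
    the gene universe (enforced by the DataFrame shape).
    """

    values: pd.DataFrame
    conditions: dict[str, str]
    unit: str = "normalized abundance (linear)"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        missing = [s for s in self.values.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]

    def condition_mean(self, condition: str) -> pd.Series:
        samples = self.samples_for(condition)
        if not samples:
            raise ValueError(f"condition {condition!r} has zero samples")
        return self.values[samples].mean(axis=1)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id",
                           float_format="%.10g")


def compute_log2fc(
    expr: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    min_expr: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2 fold change between two conditions.

    Genes whose mean abundance is below ``min_expr`` in BOTH conditions are
    dropped; for the rest, log2fc = log2((mean_a + pseudocount) /
    (mean_b + pseudocount)).  Swapping the conditions negates every value.
    """
    mean_a = expr.condition_mean(cond_a)
    mean_b = expr.condition_mean(cond_b)
    keep = (mean_a >= min_expr) | (mean_b >= min_expr)
    lfc = np.log2((mean_a[keep] + pseudocount) / (mean_b[keep] + pseudocount))
    lfc.name = "log2fc"
    return lfc


def gene_distances(
    genes: Sequence[GeneModel],
    targets: IntervalSet,
    anchor: str = "span",
) -> pd.Series:
    """Distance (bp) from each gene to the nearest target interval.

    ``anchor`` "span" measures from the gene body; "tss" from the single
    TSS position.  0 means overlap; inf means no target on the chromosome.
    """
    if anchor == "span":
        queries = IntervalSet(g.span for g in genes)
    elif anchor == "tss":
        queries = IntervalSet(
            GenomicInterval(g.span.chrom, g.tss, g.tss + 1) for g in genes
        )
    else:
        raise ValueError("anchor must be 'span' or 'tss'")
    return pd.Series(
        targets.nearest_distances(queries),
        index=[g.gene_id for g in genes],
        name="distance_bp",
    )


def _bin_labels(edges: Sequence[int]) -> list[str]:
    def kb(x: int) -> str:
        return f"{x // 1000}kb" if x % 1000 == 0 else f"{x}bp"

    labels = ["overlap", f"0-{kb(edges[0])}"]
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"{kb(lo)}-{kb(hi)}")
    labels.append(f">{kb(edges[-1])}")
    return labels


def _assign_bins(distances: np.ndarray, edges: Sequence[int]) -> np.ndarray:
    """0 = overlap; i = (edges[i-2], edges[i-1]]; last = open bin."""
    edges_arr = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges_arr, distances, side="left") + 1
    idx[distances == 0] = 0
    return idx


@dataclass
class DistanceGroupTable:
    """Per-gene distances/bins plus group summaries and test results."""

    per_gene: pd.DataFrame
    bin_edges: tuple[int, ...]
    bin_labels: list[str] = field(default_factory=list)
    group_summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    tests: pd.DataFrame = field(default_factory=pd.DataFrame)
    reference_bin: str = ""


def stratify_by_distance(
    log2fc: pd.Series,
    genes: Sequence[GeneModel],
    targets: IntervalSet,
    bins: Sequence[int] = DEFAULT_BIN_EDGES,
    anchor: str = "span",
    method: str = "anova",
) -> DistanceGroupTable:
    """Bin genes by distance to the nearest target and test group effects.

    ``bins`` are strictly increasing edges in bp; a final open bin
    (>last edge) is implied and serves as the reference group.  ``method``
    "anova" runs one-way ANOVA plus Tukey post-hoc contrasts against the
    reference; "wilcoxon" runs a rank-sum test of each bin against the
    reference with Benjamini-Hochberg correction.  Bins with fewer than two
    genes are excluded from testing with a warning.
    """
    edges = tuple(int(b) for b in bins)
    if any(b >= a for b, a in zip(edges, edges[1:])) or edges[0] <= 0:
        raise ValueError("bin edges must be positive and strictly increasing")
    labels = _bin_labels(edges)
    reference = labels[-1]

    dist = gene_distances(genes, targets, anchor=anchor)
    common = log2fc.index.intersection(dist.index)
    per_gene = pd.DataFrame(
        {"log2fc": log2fc.loc[common], "distance_bp": dist.loc[common]}
    )
    bin_idx = _assign_bins(per_gene["distance_bp"].to_numpy(), edges)
    per_gene["bin"] = [labels[i] for i in bin_idx]
    per_gene.index.name = "gene_id"

    groups = {
        lbl: per_gene.loc[per_gene["bin"] == lbl, "log2fc"].to_numpy()
        for lbl in labels
    }
    summary = pd.DataFrame(
        {
            "bin": labels,
            "n_genes": [len(groups[l]) for l in labels],
            "mean_log2fc": [
                float(np.mean(groups[l])) if len(groups[l]) else np.nan
                for l in labels
            ],
            "median_log2fc": [
                float(np.median(groups[l])) if len(groups[l]) else np.nan
                for l in labels
            ],
        }
    )

    testable = [l for l in labels if len(groups[l]) >= 2]
    dropped = [l for l in labels if l not in testable]
    if dropped:
        warnings.warn(f"bins with <2 genes excluded from testing: {dropped}")

    rows = []
    if reference not in testable or len(testable) < 2:
        warnings.warn("reference bin too small or too few groups; tests skipped")
    elif method == "anova":
        arrays = [groups[l] for l in testable]
        f_stat, p_anova = stats.f_oneway(*arrays)
        rows.append(
            {"test": "anova", "contrast": "all bins", "statistic": float(f_stat),
             "p": float(p_anova), "p_adj": np.nan}
        )
        tukey = stats.tukey_hsd(*arrays)
        ref_i = testable.index(reference)
        for i, lbl in enumerate(testable):
            if lbl == reference:
                continue
            rows.append(
                {
                    "test": "tukey",
                    "contrast": f"{lbl} vs {reference}",
                    "statistic": float(np.mean(groups[lbl]) - np.mean(groups[reference])),
                    "p": float(tukey.pvalue[i, ref_i]),
                    "p_adj": float(tukey.pvalue[i, ref_i]),
                }
            )
    elif method == "wilcoxon":
        ps = []
        for lbl in testable:
            if lbl == reference:
                continue
            u, p = stats.mannwhitneyu(
                groups[lbl], groups[reference], alternative="two-sided"
            )
            rows.append(
                {"test": "ranksum", "contrast": f"{lbl} vs {reference}",
                 "statistic": float(u), "p": float(p), "p_adj": np.nan}
            )
            ps.append(p)
        if ps:
            adj = multipletests(ps, method="fdr_bh")[1]
            k = 0
            for row in rows:
                if row["test"] == "ranksum":
                    row["p_adj"] = float(adj[k])
                    k += 1
    else:
        raise ValueError("method must be 'anova' or 'wilcoxon'")

    return DistanceGroupTable(
        per_gene=per_gene,
        bin_edges=edges,
        bin_labels=labels,
        group_summary=summary,
        tests=pd.DataFrame(rows, columns=["test", "contrast", "statistic", "p", "p_adj"]),
        reference_bin=reference,
    )


def te_promoter_transcripts(
    genes: Sequence[GeneModel], active_tes: IntervalSet
) -> pd.DataFrame:
    """Multi-exonic transcripts whose TSS lies within an active TE element.

    The TSS is a single position; containment is point-in-interval under
    half-open semantics.  Single-exon transcripts are excluded.
    """
    rows = []
    points = []
    meta = []
    for g in genes:
        for t in g.multi_exonic_transcripts():
            points.append(GenomicInterval(g.span.chrom, t.tss, t.tss + 1))
            meta.append((g.gene_id, t.transcript_id, t.tss, t.exon_count))
    if points:
        flags = active_tes.overlap_flags(IntervalSet(points))
        rows = [m for m, f in zip(meta, flags) if f]
    return pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "tss", "exon_count"]
    )


def nearest_peak_targets(
    genes: Sequence[GeneModel], peaks: IntervalSet, max_dist: float
) -> pd.DataFrame:
    """Genes whose nearest peak lies within ``max_dist`` bp, with distances."""
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    dist = gene_distances(genes, peaks)
    hit = dist[dist <= max_dist]
    return pd.DataFrame(
        {"gene_id": hit.index, "distance_bp": hit.to_numpy()}
    ).reset_index(drop=True)


def family_target_fc(
    family_marked: Mapping[str, IntervalSet],
    log2fc: pd.Series,
    genes: Sequence[GeneModel],
    max_dist: float = 100_000,
) -> pd.DataFrame:
    """Per-family distribution of target-gene log2 fold changes.

    For each family, targets are the genes within ``max_dist`` bp of any of
    the family's (H3K27ac-marked) copies; their log2fc distribution is
    tested against 0 with the Wilcoxon signed-rank test, BH-corrected
    across families.  Families with no targets are recorded as empty.
    """
    rows = []
    for fam in sorted(family_marked):
        targets = nearest_peak_targets(genes, family_marked[fam], max_dist)
        values = log2fc.reindex(targets["gene_id"]).dropna().to_numpy()
        if len(values) == 0:
            rows.append(
                {"family": fam, "n_targets": 0, "median_log2fc": np.nan,
                 "statistic": np.nan, "p": np.nan}
            )
            continue
        nonzero = values[values != 0]
        if len(nonzero) == 0:
            stat, p = np.nan, 1.0
        else:
            stat, p = stats.wilcoxon(values, alternative="two-sided")
        rows.append(
            {"family": fam, "n_targets": len(values),
             "median_log2fc": float(np.median(values)),
             "statistic": float(stat) if stat == stat else np.nan,
             "p": float(p)}
        )
    df = pd.DataFrame(rows)
    tested = df["p"].notna()
    df["q_bh"] = np.nan
    if tested.any():
        df.loc[tested, "q_bh"] = multipletests(
            df.loc[tested, "p"], method="fdr_bh"
        )[1]
    return df
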