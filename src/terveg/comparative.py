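"""Cross-species ortholog mapping of TE copies and stratified expression
comparison.

A CoordinateMap is a list of aligned block pairs between two genomes
(equal-length source and target spans, non-overlapping on each side) — the
abstraction of a liftOver chain.  An interval lifts if at least ``min_frac``
of its length maps into one contiguously-merged region on a single target
chromosome.  A TE copy has a reciprocal ortholog when its lifted interval
lifts back onto a span overlapping the original element (>=1 bp).

One-to-one orthologous genes are then compared across species: the
log2 expression ratio (after per-matrix median scaling) is stratified by
whether the marked TEs near each gene are conserved, with a rank-sum test
between groups (ortholog-presence mode, 100-kb window) or ANOVA plus Tukey
contrasts across species-activity groups (50-kb window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, GeneModel, IntervalSet, TEAnnotation
from .expression import ExpressionMatrix, gene_distances

__all__ = [
    "CoordinateMap",
    "read_block_map",
    "write_block_map",
    "lift_interval",
    "reciprocal_ortholog_map",
    "family_ortholog_fraction",
    "cross_species_stratified_fc",
    "species_activity_group_fc",
]

BLOCK_COLUMNS = [
    "src_chrom", "src_start", "src_end",
    "dst_chrom", "dst_start", "dst_end", "dst_strand",
]


class CoordinateMap:
    """Directed collection of aligned block pairs between genome A and B."""

    def __init__(self, blocks: pd.DataFrame):
        blocks = blocks[BLOCK_COLUMNS].copy()
        src_len = blocks["src_end"] - blocks["src_start"]
        dst_len = blocks["dst_end"] - blocks["dst_start"]
        if (src_len != dst_len).any():
            raise ValueError("source and target block lengths must be equal")
        if (src_len <= 0).any():
            raise ValueError("blocks must have positive length")
        self.blocks = blocks.sort_values(
            ["src_chrom", "src_start"], kind="stable"
        ).reset_index(drop=True)
        self._by_chrom: dict[str, pd.DataFrame] = {}
        for chrom, grp in self.blocks.groupby("src_chrom", sort=False):
            starts = grp["src_start"].to_numpy()
            ends = grp["src_end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"source blocks overlap on {chrom}")
            self._by_chrom[chrom] = grp.reset_index(drop=True)

    def mapped_pieces(
        self, iv: GenomicInterval
    ) -> list[tuple[str, int, int]]:
        """Target-side pieces (chrom, start, end) of the portions of ``iv``
        covered by blocks."""
        grp = self._by_chrom.get(iv.chrom)
        if grp is None:
            return []
        starts = grp["src_start"].to_numpy()
        ends = grp["src_end"].to_numpy()
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        pieces = []
        for j in range(lo, hi):
            row = grp.iloc[j]
            a = max(iv.start, int(row["src_start"]))
            b = min(iv.end, int(row["src_end"]))
            if b <= a:
                continue
            off_a = a - int(row["src_start"])
            off_b = b - int(row["src_start"])
            if row["dst_strand"] == "-":
                ds = int(row["dst_end"]) - off_b
                de = int(row["dst_end"]) - off_a
            else:
                ds = int(row["dst_start"]) + off_a
                de = int(row["dst_start"]) + off_b
            pieces.append((str(row["dst_chrom"]), ds, de))
        return pieces


def read_block_map(path) -> CoordinateMap:
    df = pd.read_csv(path, sep="\t")
    return CoordinateMap(df)


def write_block_map(cmap: CoordinateMap, path) -> None:
    cmap.blocks.to_csv(path, sep="\t", index=False)


def lift_interval(
    iv: GenomicInterval, cmap: CoordinateMap, min_frac: float = 0.5
) -> GenomicInterval | None:
    """Map an interval through aligned blocks.

    The mapped pieces are merged (overlapping or touching) per target
    chromosome; the merged region carrying the most mapped bases is
    returned as a span iff those bases cover at least ``min_frac`` of the
    input length.  Returns None otherwise.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    pieces = cmap.mapped_pieces(iv)
    if not pieces:
        return None
    best: tuple[int, str, int, int] | None = None
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in pieces:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, spans in by_chrom.items():
        spans.sort()
        cur_s, cur_e, mapped = spans[0][0], spans[0][1], spans[0][1] - spans[0][0]
        regions = []
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
                mapped += e - s
            else:
                regions.append((mapped, cur_s, cur_e))
                cur_s, cur_e, mapped = s, e, e - s
        regions.append((mapped, cur_s, cur_e))
        for mapped, s, e in regions:
            if best is None or mapped > best[0]:
                best = (mapped, chrom, s, e)
    assert best is not None
    if best[0] >= min_frac * iv.length:
        return GenomicInterval(best[1], best[2], best[3], iv.strand, iv.name)
    return None


def reciprocal_ortholog_map(
    elements: TEAnnotation,
    map_ab: CoordinateMap,
    map_ba: CoordinateMap,
    min_frac: float = 0.5,
    annotation_b: TEAnnotation | None = None,
) -> pd.DataFrame:
    """Reciprocal-lift orthology calls for every TE copy of species A.

    ``reciprocal_ok``: the element lifts A->B, the lifted interval lifts
    back B->A, and the back-lifted span overlaps the original element.
    ``has_ortholog`` additionally requires (when ``annotation_b`` is given)
    that the lifted interval overlaps an annotated element of the same
    family in species B.
    """
    fam_b: dict[str, IntervalSet] = {}
    if annotation_b is not None:
        fam_b = {f: annotation_b.family_intervals(f) for f in annotation_b.families}
    rows = []
    for i, el in enumerate(elements.elements):
        iv = el.interval
        lifted = lift_interval(iv, map_ab, min_frac)
        reciprocal_ok = False
        if lifted is not None:
            back = lift_interval(lifted, map_ba, min_frac)
            reciprocal_ok = back is not None and back.overlaps(iv)
        has_ortholog = reciprocal_ok
        if reciprocal_ok and annotation_b is not None:
            fam_set = fam_b.get(el.family)
            has_ortholog = bool(
                fam_set is not None
                and lifted is not None
                and fam_set.overlap_flags(IntervalSet([lifted]))[0]
            )
        rows.append(
            {
                "element_id": i,
                "family": el.family,
                "lifted_chrom": lifted.chrom if lifted else None,
                "lifted_start": lifted.start if lifted else -1,
                "lifted_end": lifted.end if lifted else -1,
                "reciprocal_ok": reciprocal_ok,
                "has_ortholog": has_ortholog,
            }
        )
    return pd.DataFrame(rows)


def family_ortholog_fraction(records: pd.DataFrame) -> pd.Series:
    """Per-family fraction of copies with an ortholog in the target species."""
    if len(records) == 0:
        raise ValueError("orthology records cover no family")
    return records.groupby("family")["has_ortholog"].mean()


def _scaled_means(
    expr_a: ExpressionMatrix, expr_b: ExpressionMatrix
) -> tuple[pd.Series, pd.Series]:
    """Per-gene mean abundances, median-scaled to a common level.

    Each matrix keeps its own normalized units; before taking cross-species
    ratios both are rescaled so their matrix-wide medians coincide (at the
    geometric mean of the two medians, preserving the natural abundance
    scale so the pseudocount stays small relative to typical values).
    """
    mean_a = expr_a.values.mean(axis=1)
    mean_b = expr_b.values.mean(axis=1)
    med_a, med_b = float(mean_a.median()), float(mean_b.median())
    if med_a <= 0 or med_b <= 0:
        raise ValueError("per-matrix medians must be positive for scaling")
    target = float(np.sqrt(med_a * med_b))
    return mean_a * (target / med_a), mean_b * (target / med_b)


@dataclass
class StratifiedFCResult:
    per_gene: pd.DataFrame
    group_summary: pd.DataFrame
    test: dict


def _ortholog_ratio(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    orth_genes: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    scaled_a, scaled_b = _scaled_means(expr_a, expr_b)
    pairs = orth_genes[
        orth_genes["gene_a"].isin(scaled_a.index)
        & orth_genes["gene_b"].isin(scaled_b.index)
    ].copy()
    a = scaled_a.loc[pairs["gene_a"]].to_numpy()
    b = scaled_b.loc[pairs["gene_b"]].to_numpy()
    pairs["log2_ratio"] = np.log2((a + pseudocount) / (b + pseudocount))
    return pairs


def cross_species_stratified_fc(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    orth_genes: pd.DataFrame,
    genes_a: list[GeneModel],
    marked_tes_a: IntervalSet,
    ortholog_flags: np.ndarray,
    window: float = 100_000,
    pseudocount: float = 1.0,
) -> StratifiedFCResult:
    """Expression ratio between species, split by TE conservation.

    One-to-one orthologous genes within ``window`` bp of a marked TE
    (species A coordinates) are grouped by the conservation of those TEs: a
    gene is "non_orthologous" if ANY marked TE within the window lacks an
    ortholog, "orthologous" only when every nearby marked TE is conserved.
    Groups are compared with a two-sided rank-sum test.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    flags = np.asarray(ortholog_flags, dtype=bool)
    if len(flags) != len(marked_tes_a):
        raise ValueError("ortholog_flags must align with marked_tes_a")
    tes = list(marked_tes_a)
    with_orth = IntervalSet(iv for iv, f in zip(tes, flags) if f)
    without_orth = IntervalSet(iv for iv, f in zip(tes, flags) if not f)

    pairs = _ortholog_ratio(expr_a, expr_b, orth_genes, pseudocount)
    models = {g.gene_id: g for g in genes_a}
    kept = pairs[pairs["gene_a"].isin(models)].copy()
    gene_list = [models[g] for g in kept["gene_a"]]
    d_any = gene_distances(gene_list, marked_tes_a).to_numpy()
    d_non = (
        gene_distances(gene_list, without_orth).to_numpy()
        if len(without_orth)
        else np.full(len(gene_list), np.inf)
    )
    kept["distance_bp"] = d_any
    near = d_any <= window
    group = np.where(d_non <= window, "non_orthologous", "orthologous")
    kept["group"] = np.where(near, group, "not_near")
    per_gene = kept[kept["group"] != "not_near"].reset_index(drop=True)

    groups = {
        g: per_gene.loc[per_gene["group"] == g, "log2_ratio"].to_numpy()
        for g in ("orthologous", "non_orthologous")
    }
    summary = pd.DataFrame(
        {
            "group": list(groups),
            "n_genes": [len(v) for v in groups.values()],
            "mean_log2_ratio": [
                float(np.mean(v)) if len(v) else np.nan for v in groups.values()
            ],
            "median_log2_ratio": [
                float(np.median(v)) if len(v) else np.nan for v in groups.values()
            ],
        }
    )
    if all(len(v) >= 2 for v in groups.values()):
        u, p = stats.mannwhitneyu(
            groups["non_orthologous"], groups["orthologous"],
            alternative="two-sided",
        )
        test = {"test": "ranksum", "statistic": float(u), "p": float(p)}
    else:
        warnings.warn("a conservation group is empty; between-group test skipped")
        test = {"test": "ranksum", "statistic": np.nan, "p": np.nan}
    return StratifiedFCResult(per_gene, summary, test)


def species_activity_group_fc(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    orth_genes: pd.DataFrame,
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    marked_a: IntervalSet,
    marked_b: IntervalSet,
    window: float = 50_000,
    pseudocount: float = 1.0,
) -> StratifiedFCResult:
    """Three-group comparison: marked TE near the gene in species A only,
    species B only, or neither (genes near marked TEs in both species are
    set aside).  ANOVA plus Tukey contrasts across the three groups."""
    pairs = _ortholog_ratio(expr_a, expr_b, orth_genes, pseudocount)
    models_a = {g.gene_id: g for g in genes_a}
    models_b = {g.gene_id: g for g in genes_b}
    kept = pairs[
        pairs["gene_a"].isin(models_a) & pairs["gene_b"].isin(models_b)
    ].copy()
    da = gene_distances([models_a[g] for g in kept["gene_a"]], marked_a).to_numpy()
    db = gene_distances([models_b[g] for g in kept["gene_b"]], marked_b).to_numpy()
    near_a, near_b = da <= window, db <= window
    group = np.full(len(kept), "neither", dtype=object)
    group[near_a & ~near_b] = "A_only"
    group[near_b & ~near_a] = "B_only"
    group[near_a & near_b] = "both"
    kept["group"] = group
    per_gene = kept[kept["group"] != "both"].reset_index(drop=True)

    order = ["A_only", "B_only", "neither"]
    groups = {
        g: per_gene.loc[per_gene["group"] == g, "log2_ratio"].to_numpy()
        for g in order
    }
    summary = pd.DataFrame(
        {
            "group": order,
            "n_genes": [len(groups[g]) for g in order],
            "mean_log2_ratio": [
                float(np.mean(groups[g])) if len(groups[g]) else np.nan
                for g in order
            ],
        }
    )
    testable = [g for g in order if len(groups[g]) >= 2]
    if len(testable) < 2:
        warnings.warn("too few populated groups; ANOVA skipped")
        return StratifiedFCResult(per_gene, summary, {"test": "anova", "p": np.nan})
    f_stat, p = stats.f_oneway(*[groups[g] for g in testable])
    tukey = stats.tukey_hsd(*[groups[g] for g in testable])
    contrasts = {}
    for i, gi in enumerate(testable):
        for j, gj in enumerate(testable):
            if i < j:
                contrasts[f"{gi} vs {gj}"] = float(tukey.pvalue[i, j])
    test = {
        "test": "anova+tukey",
        "statistic": float(f_stat),
        "p": float(p),
        "tukey_p": contrasts,
    }
    return StratifiedFCResult(per_gene, summary, test)
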