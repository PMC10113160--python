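"""End-to-end pipeline on synthetic data: simulate, enrich, select,
chromatin-state, expression association, cross-species comparison.

One seed drives the whole run; every output file is written with fixed
column order and number formatting, so repeated runs from the same config
produce byte-identical output trees.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .intervals import IntervalSet
from . import io
from .enrichment import family_enrichment, write_enrichment_tsv
from .selection import select_candidate_families
from .chromstate import classify_elements, family_state_proportions
from .expression import (
    compute_log2fc,
    stratify_by_distance,
    te_promoter_transcripts,
    family_target_fc,
)
from .comparative import (
    reciprocal_ortholog_map,
    family_ortholog_fraction,
    cross_species_stratified_fc,
    write_block_map,
)
from .simulate import (
    SimulationConfig,
    simulate_genome,
    simulate_peaks,
    simulate_expression,
    simulate_two_species,
)

__all__ = ["run_pipeline", "DNASE_DATASETS"]

# synthetic DNase panel layout: dataset_id -> (tissue, planted?)
DNASE_DATASETS = [
    ("placenta_1", "placenta", True),
    ("placenta_2", "placenta", True),
    ("placenta_3", "placenta", True),
    ("kidney_1", "kidney", False),
    ("kidney_2", "kidney", False),
    ("liver_1", "liver", False),
    ("liver_2", "liver", False),
    ("lung_1", "lung", False),
    ("lung_2", "lung", False),
]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: SimulationConfig, outdir) -> dict:
    """Run every stage on one simulated study and write all outputs.

    Returns the in-memory results keyed by stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # --- simulate -----------------------------------------------------------
    genome = simulate_genome(config)
    io.write_chrom_sizes(genome.chrom_sizes, outdir / "chrom.sizes")
    io.write_te_bed(genome.annotation, outdir / "te_annotation.bed")
    io.write_bed(genome.mask, outdir / "unmappable_mask.bed")
    io.write_gtf(genome.genes, outdir / "genes.gtf")
    space = genome.mappable_space()
    results["genome"] = genome

    # --- enrichment in two cell contexts ------------------------------------
    peaks = {}
    for stream, context in ((0, "context_a"), (1, "context_b")):
        pk, truth = simulate_peaks(config, genome, stream=stream)
        peaks[context] = pk
        io.write_bed(pk, outdir / f"peaks_{context}.bed")
        _write_tsv(truth, outdir / f"peaks_{context}.truth.tsv")
    enr = {}
    for i, context in enumerate(("context_a", "context_b")):
        enr[context] = family_enrichment(
            peaks[context], genome.annotation, space,
            n_perm=config.n_perm, seed=config.seed * 1000 + i,
        )
        write_enrichment_tsv(enr[context], outdir / f"enrichment_{context}.tsv")
    results["enrichment"] = enr

    # --- DNase tissue panels -------------------------------------------------
    panel_rows = []
    for j, (dataset_id, tissue, with_planting) in enumerate(DNASE_DATASETS):
        planted = config.peaks.planted if with_planting else {}
        pk, _ = simulate_peaks(config, genome, planted=planted,
                               stream=100 + j)
        rec = family_enrichment(
            pk, genome.annotation, space, n_perm=config.n_perm,
            seed=config.seed * 1000 + 100 + j,
        )
        for _, row in rec.iterrows():
            panel_rows.append(
                {"family": row["family"], "dataset_id": dataset_id,
                 "tissue": tissue, "fold": row["fold"]}
            )
    panels = pd.DataFrame(panel_rows)
    _write_tsv(panels, outdir / "dnase_panels.tsv")
    candidates = select_candidate_families(
        enr["context_a"], enr["context_b"], panels
    )
    _write_tsv(candidates, outdir / "candidate_families.tsv")
    results["candidates"] = candidates

    # --- chromatin-state combinations ---------------------------------------
    planted = config.peaks.planted
    mark_streams = {
        "H3K27ac": (200, planted),
        "H3K4me1": (201, planted),
        "H3K4me3": (202, {f: frac * 0.2 for f, frac in planted.items()}),
        "H3K9me3": (203, {}),
    }
    mark_peaks = {}
    for mark, (stream, mark_planted) in mark_streams.items():
        pk, _ = simulate_peaks(config, genome, planted=mark_planted,
                               stream=stream)
        mark_peaks[mark] = pk
        io.write_bed(pk, outdir / f"peaks_{mark}.bed")
    calls = classify_elements(genome.annotation, mark_peaks)
    calls_out = calls.copy()
    _write_tsv(calls_out, outdir / "chromstate_calls.tsv")
    proportions = family_state_proportions(calls, genome.annotation, "all")
    proportions.reset_index(names="family").to_csv(
        outdir / "chromstate_proportions.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    results["chromstate"] = {"calls": calls, "proportions": proportions}

    # --- expression association ----------------------------------------------
    k27 = mark_peaks["H3K27ac"].merged()
    te_flags = k27.overlap_flags(genome.annotation.all_intervals())
    marked_tes = IntervalSet(
        el.interval for el, f in zip(genome.annotation.elements, te_flags) if f
    )
    io.write_bed(marked_tes, outdir / "marked_tes.bed")
    expr, expr_truth = simulate_expression(config, genome, marked_tes)
    expr.to_tsv(outdir / "expression.tsv")
    _write_tsv(expr_truth, outdir / "expression.truth.tsv")
    lfc = compute_log2fc(
        expr, "A", "B",
        min_expr=config.expression.min_expr,
        pseudocount=config.expression.pseudocount,
    )
    table = stratify_by_distance(lfc, genome.genes, marked_tes)
    table.per_gene.reset_index().to_csv(
        outdir / "assoc_per_gene.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    _write_tsv(table.group_summary, outdir / "assoc_groups.tsv")
    _write_tsv(table.tests, outdir / "assoc_tests.tsv")
    promoters = te_promoter_transcripts(genome.genes, marked_tes)
    _write_tsv(promoters, outdir / "te_promoter_transcripts.tsv")
    fam_marked = {
        fam: IntervalSet(
            el.interval
            for el, f in zip(genome.annotation.elements, te_flags)
            if f and el.family == fam
        )
        for fam in sorted(planted)
    }
    fam_fc = family_target_fc(fam_marked, lfc, genome.genes)
    _write_tsv(fam_fc, outdir / "family_target_fc.tsv")
    results["assoc"] = {"log2fc": lfc, "table": table,
                        "promoters": promoters, "family_fc": fam_fc}

    # --- cross-species comparison ---------------------------------------------
    two = simulate_two_species(config, genome)
    write_block_map(two.map_ab, outdir / "map_a_to_b.tsv")
    write_block_map(two.map_ba, outdir / "map_b_to_a.tsv")
    _write_tsv(two.ortholog_genes, outdir / "ortholog_genes.tsv")
    orth = reciprocal_ortholog_map(
        genome.annotation, two.map_ab, two.map_ba,
        annotation_b=two.annotation_b,
    )
    _write_tsv(orth, outdir / "orthology.tsv")
    fractions = family_ortholog_fraction(orth)
    fractions.rename("ortholog_fraction").reset_index().to_csv(
        outdir / "family_ortholog_fraction.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    marked_all = genome.annotation.all_intervals()
    flags = orth["has_ortholog"].to_numpy(bool)
    strat = cross_species_stratified_fc(
        two.expr_a, two.expr_b, two.ortholog_genes, genome.genes,
        marked_all, flags, window=config.species_b.window_bp,
    )
    _write_tsv(strat.per_gene, outdir / "cross_species_per_gene.tsv")
    _write_tsv(strat.group_summary, outdir / "cross_species_groups.tsv")
    pd.DataFrame([strat.test]).to_csv(
        outdir / "cross_species_test.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    results["comparative"] = {"orthology": orth, "fractions": fractions,
                              "stratified": strat, "fixture": two}
    return results
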