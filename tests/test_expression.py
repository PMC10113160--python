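"""Expression filtering, log2 fold changes, distance stratification,
TE-promoter detection and nearest-peak targets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from terveg.expression import (
    ExpressionMatrix,
    compute_log2fc,
    family_target_fc,
    gene_distances,
    nearest_peak_targets,
    stratify_by_distance,
    te_promoter_transcripts,
)
from terveg.intervals import (
    GenomicInterval,
    GeneModel,
    IntervalSet,
    TranscriptModel,
)
from conftest import brute_nearest


def _expr(values: dict, n_rep=2) -> ExpressionMatrix:
    """values: gene -> (mean_a, mean_b); replicates exactly at the mean."""
    data = {}
    conditions = {}
    for r in range(n_rep):
        data[f"A{r}"] = [v[0] for v in values.values()]
        data[f"B{r}"] = [v[1] for v in values.values()]
        conditions[f"A{r}"] = "A"
        conditions[f"B{r}"] = "B"
    return ExpressionMatrix(
        pd.DataFrame(data, index=list(values)), conditions
    )


class TestComputeLog2fc:
    def test_identical_means_give_zero(self):
        expr = _expr({"g1": (8, 8), "g2": (3, 3)})
        lfc = compute_log2fc(expr, "A", "B", min_expr=1, pseudocount=1)
        assert (lfc == 0).all()

    def test_gene_below_threshold_in_both_dropped(self):
        expr = _expr({"g1": (8, 2), "g2": (0.5, 0.2)})
        lfc = compute_log2fc(expr, "A", "B", min_expr=1, pseudocount=1)
        assert list(lfc.index) == ["g1"]

    def test_hand_computed_value(self):
        expr = _expr({"g1": (8, 2)})
        lfc = compute_log2fc(expr, "A", "B", min_expr=1, pseudocount=1)
        assert lfc["g1"] == pytest.approx(np.log2(9 / 3))

    def test_missing_condition_fails(self):
        expr = _expr({"g1": (8, 2)})
        with pytest.raises(ValueError, match="zero samples"):
            compute_log2fc(expr, "A", "C")

    def test_duplicate_gene_ids_rejected(self):
        df = pd.DataFrame({"A0": [1, 2]}, index=["g", "g"])
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(df, {"A0": "A"})

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        means=st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)),
            min_size=1, max_size=20,
        ),
        pseudocount=st.floats(0.1, 5),
    )
    def test_antisymmetry(self, means, pseudocount):
        expr = _expr({f"g{i}": m for i, m in enumerate(means)})
        fwd = compute_log2fc(expr, "A", "B", min_expr=0, pseudocount=pseudocount)
        rev = compute_log2fc(expr, "B", "A", min_expr=0, pseudocount=pseudocount)
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy(), atol=1e-12)


def _gene(gid, chrom, start, end, strand="+", exons=(2,)):
    tss = start if strand == "+" else end - 1
    return GeneModel(
        gid, GenomicInterval(chrom, start, end, strand, gid), tss,
        [TranscriptModel(f"{gid}.t{k}", tss, n) for k, n in enumerate(exons)],
    )


class TestStratifyByDistance:
    def _setup(self, rng, n_genes=300, effect=0.0):
        targets = IntervalSet(
            [GenomicInterval("chr1", p, p + 500)
             for p in range(100_000, 4_000_000, 400_000)]
        )
        genes = [
            _gene(f"g{i}", "chr1", int(s := rng.integers(0, 3_990_000)), s + 2000)
            for i in range(n_genes)
        ]
        dist = gene_distances(genes, targets)
        noise = rng.normal(0, 0.3, size=n_genes)
        lfc = pd.Series(
            noise + np.where(dist.to_numpy() <= 50_000, effect, 0.0),
            index=dist.index,
        )
        return lfc, genes, targets

    def test_bins_partition_retained_genes(self, rng):
        lfc, genes, targets = self._setup(rng)
        table = stratify_by_distance(lfc, genes, targets)
        assert table.group_summary["n_genes"].sum() == len(table.per_gene)
        assert set(table.per_gene["bin"]) <= set(table.bin_labels)

    def test_null_case_not_significant(self, rng):
        lfc, genes, targets = self._setup(rng, effect=0.0)
        table = stratify_by_distance(lfc, genes, targets)
        anova = table.tests[table.tests["test"] == "anova"]
        assert anova["p"].iloc[0] > 0.01

    def test_planted_effect_detected_near_reference_null(self, rng):
        lfc, genes, targets = self._setup(rng, n_genes=600, effect=1.0)
        table = stratify_by_distance(lfc, genes, targets)
        summary = table.group_summary.set_index("bin")
        assert summary.loc["0-10kb", "mean_log2fc"] == pytest.approx(1.0, abs=0.2)
        assert summary.loc[">100kb", "mean_log2fc"] == pytest.approx(0.0, abs=0.1)
        tukey = table.tests[
            table.tests["contrast"] == "0-10kb vs >100kb"
        ]
        assert tukey["p"].iloc[0] < 0.05

    def test_wilcoxon_mode_reports_bh_adjusted(self, rng):
        lfc, genes, targets = self._setup(rng, n_genes=600, effect=1.0)
        table = stratify_by_distance(lfc, genes, targets, method="wilcoxon")
        ranksum = table.tests[table.tests["test"] == "ranksum"]
        assert (ranksum["p_adj"] >= ranksum["p"] - 1e-12).all()
        near = ranksum[ranksum["contrast"] == "0-10kb vs >100kb"]
        assert near["p_adj"].iloc[0] < 0.05

    def test_reference_is_open_bin(self, rng):
        lfc, genes, targets = self._setup(rng)
        table = stratify_by_distance(lfc, genes, targets)
        assert table.reference_bin == ">100kb"

    def test_invalid_bins_rejected(self, rng):
        lfc, genes, targets = self._setup(rng, n_genes=20)
        with pytest.raises(ValueError):
            stratify_by_distance(lfc, genes, targets, bins=[50_000, 10_000])


class TestTePromoterTranscripts:
    def test_built_fixture_exactly_two_pass(self):
        te = IntervalSet([GenomicInterval("chr1", 1000, 1500)])
        genes = [
            _gene("hit1", "chr1", 1200, 3000, "+", exons=(3,)),   # TSS in TE
            _gene("hit2", "chr1", 200, 1400, "-", exons=(2,)),    # TSS=1399 in TE
            _gene("single", "chr1", 1100, 2500, "+", exons=(1,)),  # single-exon
            _gene("outside", "chr1", 5000, 7000, "+", exons=(4,)),
            _gene("edge", "chr1", 1500, 2500, "+", exons=(2,)),    # TSS=1500, half-open
        ]
        out = te_promoter_transcripts(genes, te)
        assert sorted(out["gene_id"]) == ["hit1", "hit2"]

    def test_multi_transcript_gene_counts_each_tss(self):
        te = IntervalSet([GenomicInterval("chr1", 1000, 1500)])
        g = _gene("g", "chr1", 1200, 3000, "+", exons=(3, 1, 2))
        out = te_promoter_transcripts([g], te)
        assert sorted(out["transcript_id"]) == ["g.t0", "g.t2"]


class TestNearestPeakTargets:
    def test_overlap_gives_distance_zero(self):
        peaks = IntervalSet([GenomicInterval("chr1", 1000, 2000)])
        genes = [_gene("g", "chr1", 1500, 3000)]
        out = nearest_peak_targets(genes, peaks, max_dist=0)
        assert list(out["gene_id"]) == ["g"]
        assert out["distance_bp"].iloc[0] == 0

    def test_window_boundary(self):
        peaks = IntervalSet([GenomicInterval("chr1", 200_001, 201_000)])
        near = [_gene("near", "chr1", 99_000, 100_000)]   # gap 100,001
        out = nearest_peak_targets(near, peaks, max_dist=100_000)
        assert len(out) == 0
        out = nearest_peak_targets(near, peaks, max_dist=100_001)
        assert len(out) == 1

    def test_membership_matches_brute_force(self, rng):
        peaks = IntervalSet(
            GenomicInterval("chr1", int(s := rng.integers(0, 900_000)),
                            int(s + rng.integers(100, 2000)))
            for _ in range(50)
        )
        genes = [
            _gene(f"g{i}", "chr1", int(s := rng.integers(0, 995_000)), s + 2000)
            for i in range(100)
        ]
        out = set(nearest_peak_targets(genes, peaks, max_dist=5_000)["gene_id"])
        expected = {
            g.gene_id for g in genes if brute_nearest(g.span, peaks) <= 5_000
        }
        assert out == expected


class TestFamilyTargetFc:
    def test_null_family_not_flagged_planted_family_flagged(self, rng):
        # family A on chr1, family B on chr2: disjoint 100-kb neighborhoods
        fam_a = IntervalSet(
            [GenomicInterval("chr1", p, p + 500)
             for p in range(200_000, 9_800_000, 600_000)]
        )
        fam_b = IntervalSet(
            [GenomicInterval("chr2", p, p + 500)
             for p in range(200_000, 9_800_000, 600_000)]
        )
        genes = [
            _gene(f"a{i}", "chr1", int(s := rng.integers(0, 9_990_000)), s + 2000)
            for i in range(300)
        ] + [
            _gene(f"b{i}", "chr2", int(s := rng.integers(0, 9_990_000)), s + 2000)
            for i in range(300)
        ]
        d_a = gene_distances(genes, fam_a)
        lfc = pd.Series(
            rng.normal(0, 0.3, len(genes))
            + np.where(d_a.to_numpy() <= 100_000, 1.0, 0.0),
            index=d_a.index,
        )
        out = family_target_fc({"A": fam_a, "B": fam_b}, lfc, genes).set_index(
            "family"
        )
        assert out.loc["A", "n_targets"] >= 50
        assert out.loc["A", "q_bh"] < 0.05
        assert out.loc["B", "q_bh"] > 0.05
        assert out.loc["A", "median_log2fc"] == pytest.approx(1.0, abs=0.2)

    def test_all_zero_targets_non_significant(self):
        fam = IntervalSet([GenomicInterval("chr1", 1000, 2000)])
        genes = [_gene("g1", "chr1", 1500, 3000), _gene("g2", "chr1", 4000, 6000)]
        lfc = pd.Series([0.0, 0.0], index=["g1", "g2"])
        out = family_target_fc({"F": fam}, lfc, genes)
        assert out["median_log2fc"].iloc[0] == 0
        assert out["p"].iloc[0] == 1.0

    def test_family_without_targets_recorded_empty(self):
        fam = IntervalSet([GenomicInterval("chr9", 0, 100)])
        genes = [_gene("g", "chr1", 0, 2000)]
        lfc = pd.Series([1.0], index=["g"])
        out = family_target_fc({"F": fam}, lfc, genes)
        assert out["n_targets"].iloc[0] == 0
        assert np.isnan(out["p"].iloc[0])
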