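"""Coordinate-map lifting, reciprocal orthology and cross-species
stratified expression comparison."""

import numpy as np
import pandas as pd
import pytest

from terveg.comparative import (
    CoordinateMap,
    cross_species_stratified_fc,
    family_ortholog_fraction,
    lift_interval,
    read_block_map,
    reciprocal_ortholog_map,
    species_activity_group_fc,
    write_block_map,
)
from terveg.intervals import (
    GenomicInterval,
    GeneModel,
    IntervalSet,
    TEAnnotation,
    TEElement,
    TranscriptModel,
)
from terveg.expression import ExpressionMatrix
from conftest import brute_lift


def _map(rows):
    return CoordinateMap(
        pd.DataFrame(
            rows,
            columns=["src_chrom", "src_start", "src_end", "dst_chrom",
                     "dst_start", "dst_end", "dst_strand"],
        )
    )


IDENTITY = _map([("chrA", 0, 1_000_000, "chrA", 0, 1_000_000, "+")])


class TestCoordinateMap:
    def test_unequal_block_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            _map([("chrA", 0, 100, "chrB", 0, 99, "+")])

    def test_overlapping_source_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            _map([("chrA", 0, 100, "chrB", 0, 100, "+"),
                  ("chrA", 50, 150, "chrB", 200, 300, "+")])

    def test_tsv_round_trip(self, tmp_path):
        m = _map([("chrA", 0, 100, "chrB", 50, 150, "+"),
                  ("chrA", 200, 300, "chrB", 300, 400, "-")])
        p = tmp_path / "map.tsv"
        write_block_map(m, p)
        back = read_block_map(p)
        pd.testing.assert_frame_equal(m.blocks, back.blocks)


class TestLiftInterval:
    def test_identity_map_returns_interval(self):
        iv = GenomicInterval("chrA", 1000, 2000)
        for frac in (0.1, 0.5, 1.0):
            out = lift_interval(iv, IDENTITY, min_frac=frac)
            assert (out.chrom, out.start, out.end) == ("chrA", 1000, 2000)

    def test_outside_all_blocks_gives_none(self):
        m = _map([("chrA", 0, 100, "chrB", 0, 100, "+")])
        assert lift_interval(GenomicInterval("chrA", 500, 600), m) is None
        assert lift_interval(GenomicInterval("chrZ", 0, 50), m) is None

    def test_partial_coverage_against_min_frac(self):
        # 100-bp interval with 60 bp inside one block
        m = _map([("chrA", 0, 160, "chrB", 1000, 1160, "+")])
        iv = GenomicInterval("chrA", 100, 200)
        out = lift_interval(iv, m, min_frac=0.5)
        assert (out.chrom, out.start, out.end) == ("chrB", 1100, 1160)
        assert lift_interval(iv, m, min_frac=0.7) is None

    def test_minus_strand_block(self):
        m = _map([("chrA", 100, 200, "chrB", 500, 600, "-")])
        out = lift_interval(GenomicInterval("chrA", 120, 140), m, min_frac=1.0)
        # offset 20..40 from block start maps to 560..580 reversed
        assert (out.chrom, out.start, out.end) == ("chrB", 560, 580)

    def test_invalid_min_frac(self):
        with pytest.raises(ValueError):
            lift_interval(GenomicInterval("chrA", 0, 10), IDENTITY, min_frac=0)

    def test_matches_per_base_oracle_on_random_fixtures(self, rng):
        for _ in range(30):
            # random non-overlapping source blocks
            starts = np.sort(rng.choice(np.arange(0, 9000, 150), 12,
                                        replace=False))
            rows = []
            dst_pos = int(rng.integers(0, 5000))
            for s in starts:
                length = int(rng.integers(20, 140))
                strand = "+" if rng.random() < 0.7 else "-"
                rows.append(("chrA", int(s), int(s) + length, "chrB",
                             dst_pos, dst_pos + length, strand))
                dst_pos += length + int(rng.integers(0, 80))
            m = _map(rows)
            for _ in range(5):
                start = int(rng.integers(0, 8500))
                iv = GenomicInterval("chrA", start,
                                     start + int(rng.integers(1, 600)))
                frac = float(rng.choice([0.3, 0.5, 0.8]))
                fast = lift_interval(iv, m, min_frac=frac)
                slow = brute_lift(iv, m.blocks, frac)
                if slow is None:
                    assert fast is None
                else:
                    assert fast is not None
                    assert (fast.chrom, fast.start, fast.end) == (
                        slow.chrom, slow.start, slow.end)


def _elements(spans, family="F"):
    return TEAnnotation(
        TEElement(GenomicInterval("chrA", s, e), family) for s, e in spans
    )


class TestReciprocalOrthologMap:
    def test_identity_maps_every_element_ok(self):
        ann = _elements([(100, 200), (300, 450), (600, 900)])
        rec = reciprocal_ortholog_map(ann, IDENTITY, IDENTITY)
        assert rec["reciprocal_ok"].all()
        assert rec["has_ortholog"].all()

    def test_reverse_maps_to_other_chromosome_fails(self):
        fwd = _map([("chrA", 0, 1000, "chrB", 0, 1000, "+")])
        rev = _map([("chrB", 0, 1000, "chrC", 0, 1000, "+")])
        rec = reciprocal_ortholog_map(_elements([(100, 200)]), fwd, rev)
        assert not rec["reciprocal_ok"].any()

    def test_no_forward_mapping_means_no_ortholog(self):
        fwd = _map([("chrA", 5000, 6000, "chrB", 0, 1000, "+")])
        rec = reciprocal_ortholog_map(_elements([(100, 200)]), fwd, IDENTITY)
        assert not rec["has_ortholog"].any()
        assert rec["lifted_chrom"].isna().all()

    def test_same_family_annotation_b_requirement(self):
        ann_a = _elements([(100, 200)], family="F")
        ann_b_same = _elements([(100, 200)], family="F")
        ann_b_other = _elements([(100, 200)], family="G")
        ok = reciprocal_ortholog_map(ann_a, IDENTITY, IDENTITY,
                                     annotation_b=ann_b_same)
        bad = reciprocal_ortholog_map(ann_a, IDENTITY, IDENTITY,
                                      annotation_b=ann_b_other)
        assert ok["has_ortholog"].all()
        assert bad["reciprocal_ok"].all() and not bad["has_ortholog"].any()


class TestFamilyOrthologFraction:
    def test_all_orthologous(self):
        rec = pd.DataFrame({"family": ["F"] * 5, "has_ortholog": [True] * 5})
        assert family_ortholog_fraction(rec)["F"] == 1.0

    def test_hand_fraction(self):
        rec = pd.DataFrame(
            {"family": ["F"] * 12, "has_ortholog": [True] * 3 + [False] * 9}
        )
        assert family_ortholog_fraction(rec)["F"] == pytest.approx(0.25)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            family_ortholog_fraction(pd.DataFrame(columns=["family",
                                                           "has_ortholog"]))


def _species_expr(gene_ids, log2_means, prefix, rng, n=3, noise=0.0):
    data = {
        f"{prefix}{i}": np.power(
            2.0, log2_means + rng.normal(0, noise, len(gene_ids))
        )
        for i in range(n)
    }
    return ExpressionMatrix(
        pd.DataFrame(data, index=gene_ids),
        {f"{prefix}{i}": prefix for i in range(n)},
    )


def _gene(gid, chrom, start, end):
    return GeneModel(gid, GenomicInterval(chrom, start, end, "+", gid), start,
                     [TranscriptModel(f"{gid}.t", start, 2)])


class TestCrossSpeciesStratifiedFc:
    def _fixture(self, rng, effect=0.8):
        # TEs: 10 conserved on chrA left arm, 10 A-specific on right arm
        tes = [GenomicInterval("chrA", 100_000 + 300_000 * i,
                               100_500 + 300_000 * i) for i in range(10)]
        tes += [GenomicInterval("chrA", 20_000_000 + 300_000 * i,
                                20_000_500 + 300_000 * i) for i in range(10)]
        flags = np.array([True] * 10 + [False] * 10)
        marked = IntervalSet(tes)
        genes, base = [], []
        k = 0
        for te, f in zip(tes, flags):
            for _ in range(20):
                start = int(te.start + rng.integers(-80_000, 80_000))
                genes.append(_gene(f"g{k}", "chrA", max(start, 0),
                                   max(start, 0) + 2000))
                base.append(f)
                k += 1
        gene_ids = [g.gene_id for g in genes]
        baseline = rng.normal(6, 1, len(genes))
        shift = np.where(np.array(base), 0.0, effect)  # A-specific: higher in A
        expr_a = _species_expr(gene_ids, baseline + shift, "hs", rng, noise=0.3)
        expr_b = _species_expr(gene_ids, baseline, "mac", rng, noise=0.3)
        orth = pd.DataFrame({"gene_a": gene_ids, "gene_b": gene_ids})
        return expr_a, expr_b, orth, genes, marked, flags

    def test_recovers_planted_group_difference(self, rng):
        expr_a, expr_b, orth, genes, marked, flags = self._fixture(rng)
        res = cross_species_stratified_fc(
            expr_a, expr_b, orth, genes, marked, flags, window=100_000
        )
        gs = res.group_summary.set_index("group")["mean_log2_ratio"]
        assert gs["non_orthologous"] - gs["orthologous"] == pytest.approx(
            0.8, abs=0.2)
        assert res.test["p"] < 1e-6

    def test_all_tes_orthologous_single_group_test_skipped(self, rng):
        expr_a, expr_b, orth, genes, marked, flags = self._fixture(rng, effect=0)
        with pytest.warns(UserWarning, match="empty"):
            res = cross_species_stratified_fc(
                expr_a, expr_b, orth, genes, marked,
                np.ones(len(flags), dtype=bool), window=100_000,
            )
        assert np.isnan(res.test["p"])

    def test_species_label_swap_preserves_magnitude(self, rng):
        expr_a, expr_b, orth, genes, marked, flags = self._fixture(rng)
        fwd = cross_species_stratified_fc(
            expr_a, expr_b, orth, genes, marked, flags, window=100_000)
        swapped = cross_species_stratified_fc(
            expr_b, expr_a,
            orth.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"}),
            genes, marked, flags, window=100_000)
        d1 = fwd.group_summary.set_index("group")["mean_log2_ratio"]
        d2 = swapped.group_summary.set_index("group")["mean_log2_ratio"]
        assert abs(
            (d1["non_orthologous"] - d1["orthologous"])
            + (d2["non_orthologous"] - d2["orthologous"])
        ) < 1e-9


class TestSpeciesActivityGroups:
    def test_three_group_recovery(self, rng):
        # A-active TEs on chrA left, B-active on chrA right, none in middle
        marked_a = IntervalSet(
            [GenomicInterval("chrA", 100_000 + 200_000 * i,
                             100_500 + 200_000 * i) for i in range(8)]
        )
        marked_b = IntervalSet(
            [GenomicInterval("chrA", 30_000_000 + 200_000 * i,
                             30_000_500 + 200_000 * i) for i in range(8)]
        )
        genes, group = [], []
        k = 0
        for base, lbl in [(100_000, "A_only"), (30_000_000, "B_only"),
                          (15_000_000, "neither")]:
            for i in range(60):
                start = base + 25_000 * i
                genes.append(_gene(f"g{k}", "chrA", start, start + 2000))
                group.append(lbl)
                k += 1
        gene_ids = [g.gene_id for g in genes]
        baseline = rng.normal(6, 1, len(genes))
        shift_a = np.where(np.array(group) == "A_only", 0.8, 0.0)
        shift_b = np.where(np.array(group) == "B_only", 0.8, 0.0)
        expr_a = _species_expr(gene_ids, baseline + shift_a, "hs", rng, noise=0.3)
        expr_b = _species_expr(gene_ids, baseline + shift_b, "ms", rng, noise=0.3)
        orth = pd.DataFrame({"gene_a": gene_ids, "gene_b": gene_ids})
        res = species_activity_group_fc(
            expr_a, expr_b, orth, genes, genes, marked_a, marked_b,
            window=50_000,
        )
        gs = res.group_summary.set_index("group")["mean_log2_ratio"]
        assert gs["A_only"] > gs["neither"] > gs["B_only"]
        assert res.test["p"] < 1e-6
        assert res.test["tukey_p"]["A_only vs B_only"] < 0.01
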