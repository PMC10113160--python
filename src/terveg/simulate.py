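"""Seeded synthetic-data generators with planted, parameterized structure.

Every pipeline stage gets a ground-truth test bed: a genome with
multi-family TE annotations (variable copy number and length), unmappable
masked regions, peak sets with a planted fraction of peaks overlapping
chosen families, two-condition expression with a distance-dependent planted
effect, and a two-species setup in which a recorded subset of TE copies is
deleted from species B (coordinate maps reflect the deletions as unmapped
gaps).

All generators are pure functions of the configuration: a single root seed
drives the run and each stage draws from its own spawned stream, so outputs
are bit-identical across runs for a fixed config.  Truth records accompany
every stochastic output and are sufficient to score downstream calls
without re-deriving ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    GenomicInterval,
    GeneModel,
    IntervalSet,
    TEAnnotation,
    TEElement,
    TranscriptModel,
)
from .enrichment import MappableSpace, build_mappable_space
from .expression import ExpressionMatrix, gene_distances

__all__ = [
    "FamilyConfig",
    "PeakConfig",
    "EffectConfig",
    "ExpressionConfig",
    "SpeciesBConfig",
    "SimulationConfig",
    "Genome",
    "TwoSpeciesFixture",
    "simulate_genome",
    "simulate_peaks",
    "simulate_expression",
    "simulate_two_species",
    "config_from_yaml",
    "config_to_yaml",
]

# stage tags for spawned RNG streams
_STAGE_GENOME, _STAGE_PEAKS, _STAGE_EXPR, _STAGE_SPECIES = 1, 2, 3, 4


@dataclass
class FamilyConfig:
    name: str
    copy_number: int = 60
    length_mean: float = 500.0
    length_sd: float = 100.0


@dataclass
class PeakConfig:
    count: int = 500
    length_mean: float = 300.0
    length_sd: float = 50.0
    # family name -> fraction of peaks placed to overlap a copy of it
    planted: dict[str, float] = field(default_factory=dict)


@dataclass
class EffectConfig:
    window_bp: int = 50_000
    log2fc: float = 1.0


@dataclass
class ExpressionConfig:
    n_genes: int = 1000
    gene_length: int = 2000
    n_samples_per_condition: int = 3
    baseline_mean: float = 6.0   # log2 scale
    baseline_sd: float = 1.0
    noise_sd: float = 0.5        # log2 scale, per sample
    min_expr: float = 1.0
    pseudocount: float = 1.0
    effect: EffectConfig = field(default_factory=EffectConfig)


@dataclass
class SpeciesBConfig:
    # family name -> fraction of copies shared with species B
    shared_fraction: dict[str, float] = field(default_factory=dict)
    default_shared_fraction: float = 0.5
    effect_log2fc: float = 0.8   # planted species effect near A-specific TEs
    window_bp: int = 100_000


def _default_families() -> list[FamilyConfig]:
    # heterogeneous copy numbers and lengths, LTR-like scale
    return [
        FamilyConfig(f"ERVsim{i + 1}", copy_number=cn, length_mean=lm, length_sd=lm / 5)
        for i, (cn, lm) in enumerate(
            [(80, 400), (60, 600), (40, 900), (100, 350), (50, 500),
             (30, 1200), (70, 450), (45, 700), (90, 300), (55, 800)]
        )
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 12_000_000, "chrS2": 8_000_000}
    )
    families: list[FamilyConfig] = field(default_factory=_default_families)
    mask_fraction: float = 0.05
    mask_segment_bp: int = 50_000
    peaks: PeakConfig = field(
        default_factory=lambda: PeakConfig(
            planted={"ERVsim1": 0.25, "ERVsim2": 0.15}
        )
    )
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    species_b: SpeciesBConfig = field(default_factory=SpeciesBConfig)
    n_perm: int = 1000

    def __post_init__(self) -> None:
        if not (0 <= self.mask_fraction <= 1):
            raise ValueError("mask_fraction must be in [0, 1]")
        planted = self.peaks.planted
        if any(f < 0 or f > 1 for f in planted.values()):
            raise ValueError("planted fractions must be in [0, 1]")
        if sum(planted.values()) > 1 + 1e-12:
            raise ValueError("planted fractions must sum to <= 1")
        known = {f.name for f in self.families}
        unknown = set(planted) - known
        if unknown:
            raise ValueError(f"planted families not in config: {sorted(unknown)}")
        for fam, frac in self.species_b.shared_fraction.items():
            if not (0 <= frac <= 1):
                raise ValueError(f"shared_fraction for {fam} must be in [0, 1]")
        if self.peaks.count < 0 or self.expression.n_genes < 0:
            raise ValueError("counts must be >= 0")

    def shared_fraction_for(self, family: str) -> float:
        return self.species_b.shared_fraction.get(
            family, self.species_b.default_shared_fraction
        )


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _config_from_dict(raw)


def _config_from_dict(raw: dict) -> SimulationConfig:
    kwargs = dict(raw)
    if "families" in kwargs:
        kwargs["families"] = [FamilyConfig(**f) for f in kwargs["families"]]
    if "peaks" in kwargs:
        kwargs["peaks"] = PeakConfig(**kwargs["peaks"])
    if "expression" in kwargs:
        expr = dict(kwargs["expression"])
        if "effect" in expr:
            expr["effect"] = EffectConfig(**expr["effect"])
        kwargs["expression"] = ExpressionConfig(**expr)
    if "species_b" in kwargs:
        kwargs["species_b"] = SpeciesBConfig(**kwargs["species_b"])
    return SimulationConfig(**kwargs)


def config_to_yaml(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


class _FreeSpace:
    """Non-overlapping placement bookkeeping: uniform placement over all
    positions where an interval fits inside a single free segment."""

    def __init__(self, chrom_sizes: Mapping[str, int]):
        self.chrom_names = sorted(chrom_sizes)
        cap = max(16, 4 * len(self.chrom_names))
        self._chrom = np.empty(cap, dtype=np.int64)
        self._start = np.empty(cap, dtype=np.int64)
        self._end = np.empty(cap, dtype=np.int64)
        self._n = 0
        for i, name in enumerate(self.chrom_names):
            self._append(i, 0, chrom_sizes[name])

    def _append(self, chrom: int, start: int, end: int) -> None:
        if end <= start:
            return
        if self._n == len(self._chrom):
            for name in ("_chrom", "_start", "_end"):
                arr = getattr(self, name)
                grown = np.empty(2 * len(arr), dtype=np.int64)
                grown[: self._n] = arr[: self._n]
                setattr(self, name, grown)
        self._chrom[self._n] = chrom
        self._start[self._n] = start
        self._end[self._n] = end
        self._n += 1

    def place(self, length: int, rng: np.random.Generator,
              what: str = "interval") -> tuple[str, int]:
        n = self._n
        valid = self._end[:n] - self._start[:n] - length + 1
        np.clip(valid, 0, None, out=valid)
        total = int(valid.sum())
        if total == 0:
            raise ValueError(
                f"cannot place {what} of length {length}: requested content "
                "exceeds remaining genome capacity"
            )
        r = int(rng.integers(0, total))
        cum = np.cumsum(valid)
        seg = int(np.searchsorted(cum, r, side="right"))
        prev = int(cum[seg - 1]) if seg > 0 else 0
        start = int(self._start[seg]) + (r - prev)
        chrom = self.chrom_names[int(self._chrom[seg])]
        seg_start, seg_end = int(self._start[seg]), int(self._end[seg])
        # split the segment around the placement
        self._end[seg] = start  # left remnant (may be empty; harmless)
        if start == seg_start:
            # left remnant empty: overwrite with right remnant instead
            self._start[seg] = start + length
            self._end[seg] = seg_end
            if self._start[seg] >= self._end[seg]:
                # segment fully consumed: drop by swapping in the last one
                self._n -= 1
                if seg != self._n:
                    self._chrom[seg] = self._chrom[self._n]
                    self._start[seg] = self._start[self._n]
                    self._end[seg] = self._end[self._n]
        else:
            self._append(int(self._chrom[seg]), start + length, seg_end)
        return chrom, start


@dataclass
class Genome:
    chrom_sizes: dict[str, int]
    annotation: TEAnnotation
    mask: IntervalSet
    genes: list[GeneModel]

    def mappable_space(self) -> MappableSpace:
        return build_mappable_space(self.chrom_sizes, self.mask)


def _lengths(rng: np.random.Generator, n: int, mean: float, sd: float,
             minimum: int = 20) -> np.ndarray:
    return np.maximum(
        np.round(rng.normal(mean, sd, size=n)).astype(np.int64), minimum
    )


def simulate_genome(config: SimulationConfig) -> Genome:
    """Generate chromosome sizes, a masked-region set, a TE annotation and
    gene models.  TE copies are placed uniformly without overlapping each
    other or the mask; genes are placed uniformly with recorded TSS."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _STAGE_GENOME])
    )
    sizes = dict(config.chromosomes)
    free = _FreeSpace(sizes)

    # unmappable mask
    mask_ivs = []
    target = int(round(config.mask_fraction * sum(sizes.values())))
    placed = 0
    while placed < target:
        seg = int(min(config.mask_segment_bp, target - placed))
        chrom, start = free.place(seg, rng, what="mask segment")
        mask_ivs.append(GenomicInterval(chrom, start, start + seg))
        placed += seg
    mask = IntervalSet(
        sorted(mask_ivs, key=lambda iv: (iv.chrom, iv.start))
    )

    # TE copies, non-overlapping, outside the mask
    elements = []
    for fam in config.families:
        lens = _lengths(rng, fam.copy_number, fam.length_mean, fam.length_sd, 50)
        strands = rng.choice(["+", "-"], size=fam.copy_number)
        for k in range(fam.copy_number):
            chrom, start = free.place(
                int(lens[k]), rng, what=f"TE copy of {fam.name}"
            )
            elements.append(
                TEElement(
                    GenomicInterval(chrom, start, start + int(lens[k]),
                                    str(strands[k])),
                    fam.name,
                    "LTR/ERV-sim",
                )
            )
    annotation = TEAnnotation(elements)

    # genes: uniform, overlaps permitted, strand-aware TSS
    chrom_names = sorted(sizes)
    weights = np.asarray([sizes[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    genes = []
    glen = config.expression.gene_length
    for g in range(config.expression.n_genes):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
        start = int(rng.integers(0, sizes[chrom] - glen))
        strand = str(rng.choice(["+", "-"]))
        gid = f"gene{g + 1:05d}"
        span = GenomicInterval(chrom, start, start + glen, strand, gid)
        tss = start if strand == "+" else start + glen - 1
        exon_count = int(rng.integers(1, 6))
        genes.append(
            GeneModel(gid, span, tss,
                      [TranscriptModel(f"{gid}.t1", tss, exon_count)])
        )
    return Genome(sizes, annotation, mask, genes)


def _place_background(
    lengths: np.ndarray, space: MappableSpace, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Uniform placement over the whole mappable space (across chromosomes),
    each interval inside a single mappable segment."""
    seg_chrom: list[str] = []
    seg_s_parts, seg_e_parts = [], []
    for chrom in sorted(space.chrom_sizes):
        s, e = space.segments(chrom)
        seg_chrom.extend([chrom] * len(s))
        seg_s_parts.append(s)
        seg_e_parts.append(e)
    seg_s = np.concatenate(seg_s_parts) if seg_s_parts else np.empty(0, np.int64)
    seg_e = np.concatenate(seg_e_parts) if seg_e_parts else np.empty(0, np.int64)
    seg_len = seg_e - seg_s
    chroms, starts = [], np.empty(len(lengths), dtype=np.int64)
    for i, L in enumerate(lengths):
        valid = np.clip(seg_len - L + 1, 0, None)
        total = int(valid.sum())
        if total == 0:
            raise ValueError(
                f"background interval of length {L} fits in no mappable segment"
            )
        r = int(rng.integers(0, total))
        cum = np.cumsum(valid)
        j = int(np.searchsorted(cum, r, side="right"))
        prev = int(cum[j - 1]) if j > 0 else 0
        chroms.append(seg_chrom[j])
        starts[i] = seg_s[j] + (r - prev)
    return chroms, starts


def simulate_peaks(
    config: SimulationConfig,
    genome: Genome,
    planted: Mapping[str, float] | None = None,
    count: int | None = None,
    stream: int = 0,
) -> tuple[IntervalSet, pd.DataFrame]:
    """Generate a peak set with a planted fraction of peaks inside chosen
    TE families, plus a per-peak provenance truth record.

    Planted peaks overlap a uniformly chosen copy of the target family by
    at least 1 bp; background peaks are uniform over mappable space.
    ``stream`` distinguishes independent peak sets under one seed.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _STAGE_PEAKS, stream])
    )
    planted = dict(config.peaks.planted if planted is None else planted)
    count = config.peaks.count if count is None else count
    for fam in planted:
        if fam not in genome.annotation.family_index:
            raise ValueError(f"planted family {fam} not in the annotation")

    n_planted = {fam: int(round(frac * count)) for fam, frac in planted.items()}
    if sum(n_planted.values()) > count:
        raise ValueError("planted counts exceed total peak count")
    n_background = count - sum(n_planted.values())

    lengths = _lengths(rng, count, config.peaks.length_mean,
                       config.peaks.length_sd, 50)
    intervals: list[GenomicInterval] = []
    provenance: list[str] = []
    k = 0
    for fam in sorted(n_planted):
        copies = genome.annotation.family_elements(fam)
        for _ in range(n_planted[fam]):
            el = copies[int(rng.integers(0, len(copies)))]
            iv = el.interval
            L = int(lengths[k])
            size = genome.chrom_sizes[iv.chrom]
            lo = max(0, iv.start - L + 1)
            hi = min(iv.end - 1, size - L)
            if hi < lo:
                raise ValueError(
                    f"cannot overlap a {fam} copy with a peak of length {L}"
                )
            start = int(rng.integers(lo, hi + 1))
            intervals.append(
                GenomicInterval(iv.chrom, start, start + L, ".", f"pk{k + 1:05d}")
            )
            provenance.append(f"planted:{fam}")
            k += 1
    if n_background:
        space = genome.mappable_space()
        chroms, starts = _place_background(lengths[k:], space, rng)
        for j, (chrom, start) in enumerate(zip(chroms, starts)):
            L = int(lengths[k + j])
            intervals.append(
                GenomicInterval(chrom, int(start), int(start) + L, ".",
                                f"pk{k + j + 1:05d}")
            )
            provenance.append("background")
    peaks = IntervalSet(intervals)
    truth = pd.DataFrame(
        {
            "peak_id": [iv.name for iv in intervals],
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "provenance": provenance,
        }
    )
    return peaks, truth


def simulate_expression(
    config: SimulationConfig,
    genome: Genome,
    marked_tes: IntervalSet,
    stream: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-condition expression with a distance-dependent planted effect.

    Per-gene baselines are log-normal (normal on the log2 scale); condition
    A gains ``effect.log2fc`` iff the gene lies within ``effect.window_bp``
    of a marked TE; per-sample noise is normal on the log2 scale.  Values
    are emitted on the linear scale.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _STAGE_EXPR, stream])
    )
    ec = config.expression
    gene_ids = [g.gene_id for g in genome.genes]
    dist = gene_distances(genome.genes, marked_tes)
    effect = np.where(
        dist.to_numpy() <= ec.effect.window_bp, ec.effect.log2fc, 0.0
    )
    baseline = rng.normal(ec.baseline_mean, ec.baseline_sd, size=len(gene_ids))
    n = ec.n_samples_per_condition
    columns, conditions = [], {}
    data = {}
    for cond, shift in (("A", effect), ("B", 0.0)):
        for s in range(n):
            name = f"{cond}{s + 1}"
            noise = rng.normal(0.0, ec.noise_sd, size=len(gene_ids))
            data[name] = np.power(2.0, baseline + shift + noise)
            conditions[name] = cond
            columns.append(name)
    values = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "distance_bp": dist.to_numpy(),
            "planted_log2fc": effect,
        }
    )
    return ExpressionMatrix(values, conditions), truth


def _cumulative_deleted_before(
    positions: np.ndarray, del_starts: np.ndarray, del_ends: np.ndarray
) -> np.ndarray:
    """Deleted bases strictly before each position (positions outside
    deletions)."""
    if len(del_starts) == 0:
        return np.zeros(len(positions), dtype=np.int64)
    del_len = np.concatenate([[0], np.cumsum(del_ends - del_starts)])
    idx = np.searchsorted(del_ends, positions, side="right")
    return del_len[idx]


@dataclass
class TwoSpeciesFixture:
    chrom_sizes_b: dict[str, int]
    annotation_b: TEAnnotation
    genes_b: list[GeneModel]
    map_ab: "object"
    map_ba: "object"
    ortholog_genes: pd.DataFrame
    expr_a: ExpressionMatrix
    expr_b: ExpressionMatrix
    element_truth: pd.DataFrame   # element_id, family, shared
    gene_truth: pd.DataFrame      # gene_id, group, planted_log2_ratio


def simulate_two_species(
    config: SimulationConfig,
    genome_a: Genome,
    marked_families: Sequence[str] | None = None,
    stream: int = 0,
) -> TwoSpeciesFixture:
    """Derive species B from species A by deleting a recorded subset of TE
    copies per family; emit coordinate maps in both directions, one-to-one
    gene orthologs, and expression for both species.

    Species-B expression lacks the TE-linked effect for genes that have an
    A-specific marked copy within the window (a single species-specific
    element is taken to dominate), so the planted cross-species log2 ratio
    equals ``species_b.effect_log2fc`` exactly for those genes and 0 for
    genes whose nearby marked copies are all shared.
    """
    from .comparative import CoordinateMap  # local import: avoid cycle

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _STAGE_SPECIES, stream])
    )
    ann = genome_a.annotation
    marked_families = (
        list(marked_families) if marked_families is not None else ann.families
    )

    # choose shared vs species-A-specific copies per family
    shared = np.zeros(len(ann), dtype=bool)
    for fam in ann.families:
        ids = np.asarray(ann.family_index[fam])
        n_shared = int(round(config.shared_fraction_for(fam) * len(ids)))
        chosen = rng.choice(ids, size=n_shared, replace=False)
        shared[chosen] = True
    element_truth = pd.DataFrame(
        {
            "element_id": np.arange(len(ann)),
            "family": [el.family for el in ann.elements],
            "shared": shared,
        }
    )

    # deletions in A coordinates = spans of the A-specific copies
    deletions: dict[str, list[tuple[int, int]]] = {}
    for i, el in enumerate(ann.elements):
        if not shared[i]:
            deletions.setdefault(el.interval.chrom, []).append(
                (el.interval.start, el.interval.end)
            )
    del_arrays = {
        c: (
            np.asarray(sorted(s for s, _ in spans), dtype=np.int64),
            np.asarray(sorted(e for _, e in spans), dtype=np.int64),
        )
        for c, spans in deletions.items()
    }

    def shift(chrom: str, pos: np.ndarray) -> np.ndarray:
        ds, de = del_arrays.get(chrom, (np.empty(0, np.int64),) * 2)
        return pos - _cumulative_deleted_before(pos, ds, de)

    sizes_b = {
        c: int(size - sum(e - s for s, e in deletions.get(c, [])))
        for c, size in genome_a.chrom_sizes.items()
    }

    # aligned blocks: the retained segments between deletions
    blocks = []
    for chrom, size in sorted(genome_a.chrom_sizes.items()):
        ds, de = del_arrays.get(chrom, (np.empty(0, np.int64),) * 2)
        prev, deleted = 0, 0
        for s, e in zip(ds, de):
            if s > prev:
                blocks.append(
                    {"src_chrom": chrom, "src_start": prev, "src_end": int(s),
                     "dst_chrom": chrom, "dst_start": prev - deleted,
                     "dst_end": int(s) - deleted, "dst_strand": "+"}
                )
            deleted += int(e - s)
            prev = int(e)
        if size > prev:
            blocks.append(
                {"src_chrom": chrom, "src_start": prev, "src_end": size,
                 "dst_chrom": chrom, "dst_start": prev - deleted,
                 "dst_end": size - deleted, "dst_strand": "+"}
            )
    blocks_df = pd.DataFrame(blocks)
    map_ab = CoordinateMap(blocks_df)
    inverse = blocks_df.rename(
        columns={
            "src_chrom": "dst_chrom", "src_start": "dst_start",
            "src_end": "dst_end", "dst_chrom": "src_chrom",
            "dst_start": "src_start", "dst_end": "src_end",
        }
    )
    inverse["dst_strand"] = "+"
    map_ba = CoordinateMap(inverse)

    # species-B annotation: shared copies at shifted coordinates
    elements_b = []
    for i, el in enumerate(ann.elements):
        if shared[i]:
            iv = el.interval
            s = int(shift(iv.chrom, np.asarray([iv.start]))[0])
            elements_b.append(
                TEElement(
                    GenomicInterval(iv.chrom, s, s + iv.length, iv.strand),
                    el.family, el.class_label,
                )
            )
    annotation_b = TEAnnotation(elements_b)

    # species-B gene models: spans shrink by any deleted bases they contain
    genes_b = []
    for g in genome_a.genes:
        chrom = g.span.chrom
        se = shift(chrom, np.asarray([g.span.start, g.span.end]))
        b_start, b_end = int(se[0]), int(se[1])
        if b_end <= b_start:  # gene fully deleted (cannot happen: genes > TEs)
            continue
        strand = g.span.strand
        tss = b_start if strand == "+" else b_end - 1
        genes_b.append(
            GeneModel(
                g.gene_id,
                GenomicInterval(chrom, b_start, b_end, strand, g.gene_id),
                tss,
                [TranscriptModel(t.transcript_id, tss, t.exon_count)
                 for t in g.transcripts],
            )
        )
    ortholog_genes = pd.DataFrame(
        {
            "gene_a": [g.gene_id for g in genes_b],
            "gene_b": [g.gene_id for g in genes_b],
        }
    )

    # expression: planted species effect near A-specific marked copies
    marked_ids = [
        i for i, el in enumerate(ann.elements) if el.family in marked_families
    ]
    marked_all = IntervalSet(ann.elements[i].interval for i in marked_ids)
    marked_specific = IntervalSet(
        ann.elements[i].interval for i in marked_ids if not shared[i]
    )
    window = config.species_b.window_bp
    d_any = gene_distances(genome_a.genes, marked_all).to_numpy()
    d_spec = (
        gene_distances(genome_a.genes, marked_specific).to_numpy()
        if len(marked_specific)
        else np.full(len(genome_a.genes), np.inf)
    )
    near_any = d_any <= window
    near_spec = d_spec <= window
    e = config.species_b.effect_log2fc
    effect_a = np.where(near_any, e, 0.0)
    effect_b = np.where(near_any & ~near_spec, e, 0.0)

    ec = config.expression
    gene_ids = [g.gene_id for g in genome_a.genes]
    baseline = rng.normal(ec.baseline_mean, ec.baseline_sd, size=len(gene_ids))
    n = ec.n_samples_per_condition

    def matrix(effect: np.ndarray, prefix: str) -> ExpressionMatrix:
        data, conditions = {}, {}
        for s in range(n):
            name = f"{prefix}{s + 1}"
            noise = rng.normal(0.0, ec.noise_sd, size=len(gene_ids))
            data[name] = np.power(2.0, baseline + effect + noise)
            conditions[name] = prefix
        return ExpressionMatrix(
            pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id")),
            conditions,
        )

    expr_a = matrix(effect_a, "spA")
    expr_b = matrix(effect_b, "spB")
    group = np.where(
        near_any, np.where(near_spec, "non_orthologous", "orthologous"),
        "not_near",
    )
    gene_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "group": group,
            "planted_log2_ratio": effect_a - effect_b,
        }
    )
    return TwoSpeciesFixture(
        sizes_b, annotation_b, genes_b, map_ab, map_ba, ortholog_genes,
        expr_a, expr_b, element_truth, gene_truth,
    )
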