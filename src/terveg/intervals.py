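"""Genomic-interval data model and overlap/nearest algebra.

All coordinates are 0-based half-open ``[start, end)``; readers for 1-based
formats (GTF, RepeatMasker) convert at the boundary.  Overlap requires at
least one shared base pair: intervals that merely share a boundary point do
not overlap.  Distances are unsigned edge-to-edge gaps (0 for overlapping or
bookended intervals); strand is carried but ignored by overlap and distance
queries.  Chromosome names are matched by exact string equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "TEElement",
    "TEAnnotation",
    "TranscriptModel",
    "GeneModel",
    "count_overlaps",
    "nearest_distance",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A located span on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> float:
        """Unsigned edge-to-edge gap; 0 if overlapping; inf across chromosomes."""
        if self.chrom != other.chrom:
            return math.inf
        return float(max(0, other.start - self.end, self.start - other.end))


class _ChromIndex:
    """Per-chromosome sorted/merged arrays supporting hit and nearest queries."""

    __slots__ = ("starts", "ends", "merged_starts", "merged_ends")

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        order = np.argsort(starts, kind="stable")
        self.starts = starts[order]
        self.ends = ends[order]
        # merge overlapping-or-bookended intervals for run-based queries
        ms, me = [], []
        cur_s = cur_e = None
        for s, e in zip(self.starts, self.ends):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                ms.append(cur_s)
                me.append(cur_e)
                cur_s, cur_e = s, e
        if cur_s is not None:
            ms.append(cur_s)
            me.append(cur_e)
        self.merged_starts = np.asarray(ms, dtype=np.int64)
        self.merged_ends = np.asarray(me, dtype=np.int64)

    def hits(self, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        """Boolean array: does query i overlap (>=1 bp) any interval here."""
        lo = np.searchsorted(self.merged_ends, qs, side="right")
        hi = np.searchsorted(self.merged_starts, qe, side="left")
        return hi > lo

    def nearest(self, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        """Unsigned gap from each query to its nearest interval here."""
        ms, me = self.merged_starts, self.merged_ends
        lo = np.searchsorted(me, qs, side="right")
        hi = np.searchsorted(ms, qe, side="left")
        dist = np.zeros(len(qs), dtype=float)
        miss = hi <= lo  # no overlap
        if miss.any():
            left = np.full(miss.sum(), np.inf)
            right = np.full(miss.sum(), np.inf)
            lo_m = lo[miss]
            has_left = lo_m > 0
            left[has_left] = qs[miss][has_left] - me[lo_m[has_left] - 1]
            has_right = lo_m < len(ms)
            right[has_right] = ms[lo_m[has_right]] - qe[miss][has_right]
            dist[miss] = np.minimum(left, right)
        return dist


class IntervalSet:
    """An order-independent, duplicate-tolerant collection of intervals
    with per-chromosome indexes for overlap and nearest queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._intervals: list[GenomicInterval] = list(intervals)
        self._index: dict[str, _ChromIndex] | None = None

    @classmethod
    def from_arrays(
        cls,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        strands: Sequence[str] | None = None,
        names: Sequence[str | None] | None = None,
    ) -> "IntervalSet":
        n = len(chroms)
        strands = strands if strands is not None else ["."] * n
        names = names if names is not None else [None] * n
        return cls(
            GenomicInterval(c, int(s), int(e), st, nm)
            for c, s, e, st, nm in zip(chroms, starts, ends, strands, names)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IntervalSet":
        return cls.from_arrays(
            df["chrom"].tolist(),
            df["start"].tolist(),
            df["end"].tolist(),
            df["strand"].tolist() if "strand" in df else None,
            df["name"].tolist() if "name" in df else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self._intervals],
                "start": [iv.start for iv in self._intervals],
                "end": [iv.end for iv in self._intervals],
                "strand": [iv.strand for iv in self._intervals],
                "name": [iv.name for iv in self._intervals],
            }
        )

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    @property
    def chromosomes(self) -> list[str]:
        return sorted({iv.chrom for iv in self._intervals})

    def total_length(self) -> int:
        return sum(iv.length for iv in self._intervals)

    def _chrom_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        by: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self._intervals:
            s, e = by.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in by.items()
        }

    def _get_index(self) -> dict[str, _ChromIndex]:
        if self._index is None:
            self._index = {
                c: _ChromIndex(s, e) for c, (s, e) in self._chrom_arrays().items()
            }
        return self._index

    # ---- queries ----------------------------------------------------------

    def overlap_flags(self, queries: "IntervalSet") -> np.ndarray:
        """Per query interval: overlaps (>=1 bp) any interval of this set."""
        index = self._get_index()
        out = np.zeros(len(queries), dtype=bool)
        by: dict[str, list[int]] = {}
        for i, iv in enumerate(queries):
            by.setdefault(iv.chrom, []).append(i)
        for chrom, idxs in by.items():
            ci = index.get(chrom)
            if ci is None:
                continue
            qs = np.asarray([queries[i].start for i in idxs], dtype=np.int64)
            qe = np.asarray([queries[i].end for i in idxs], dtype=np.int64)
            out[np.asarray(idxs)] = ci.hits(qs, qe)
        return out

    def nearest_distances(self, queries: "IntervalSet") -> np.ndarray:
        """Per query: unsigned gap to nearest member (0 if overlapping,
        inf if this set has nothing on the query's chromosome)."""
        index = self._get_index()
        out = np.full(len(queries), np.inf)
        by: dict[str, list[int]] = {}
        for i, iv in enumerate(queries):
            by.setdefault(iv.chrom, []).append(i)
        for chrom, idxs in by.items():
            ci = index.get(chrom)
            if ci is None:
                continue
            qs = np.asarray([queries[i].start for i in idxs], dtype=np.int64)
            qe = np.asarray([queries[i].end for i in idxs], dtype=np.int64)
            out[np.asarray(idxs)] = ci.nearest(qs, qe)
        return out

    def merged(self) -> "IntervalSet":
        """Union of members: overlapping or bookended intervals coalesced."""
        index = self._get_index()
        out = []
        for chrom in sorted(index):
            ci = index[chrom]
            for s, e in zip(ci.merged_starts, ci.merged_ends):
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return IntervalSet(out)

    def complement(self, chrom_sizes: Mapping[str, int]) -> "IntervalSet":
        """Per-chromosome complement within [0, size)."""
        index = self._get_index()
        out = []
        for chrom in sorted(chrom_sizes):
            size = chrom_sizes[chrom]
            pos = 0
            ci = index.get(chrom)
            if ci is not None:
                for s, e in zip(ci.merged_starts, ci.merged_ends):
                    if e > size or s < 0:
                        raise ValueError(
                            f"interval {chrom}:{s}-{e} outside chromosome "
                            f"bounds [0, {size})"
                        )
                    if s > pos:
                        out.append(GenomicInterval(chrom, pos, int(s)))
                    pos = max(pos, int(e))
            if pos < size:
                out.append(GenomicInterval(chrom, pos, size))
        return IntervalSet(out)


@dataclass(frozen=True)
class TEElement:
    """One annotated transposable-element copy, assigned to a repeat family."""

    interval: GenomicInterval
    family: str
    class_label: str | None = None

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("family must be non-empty")


class TEAnnotation:
    """TE copies grouped into repeat families — the unit of enrichment testing."""

    def __init__(self, elements: Iterable[TEElement] = ()):
        self.elements: list[TEElement] = list(elements)
        self.family_index: dict[str, list[int]] = {}
        for i, el in enumerate(self.elements):
            self.family_index.setdefault(el.family, []).append(i)
        self._family_sets: dict[str, IntervalSet] = {}

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def families(self) -> list[str]:
        return sorted(self.family_index)

    def copy_number(self, family: str) -> int:
        return len(self.family_index[family])

    def family_elements(self, family: str) -> list[TEElement]:
        return [self.elements[i] for i in self.family_index[family]]

    def family_intervals(self, family: str) -> IntervalSet:
        if family not in self._family_sets:
            self._family_sets[family] = IntervalSet(
                el.interval for el in self.family_elements(family)
            )
        return self._family_sets[family]

    def all_intervals(self) -> IntervalSet:
        return IntervalSet(el.interval for el in self.elements)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [el.interval.chrom for el in self.elements],
                "start": [el.interval.start for el in self.elements],
                "end": [el.interval.end for el in self.elements],
                "strand": [el.interval.strand for el in self.elements],
                "family": [el.family for el in self.elements],
                "class_label": [el.class_label for el in self.elements],
            }
        )


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    tss: int
    exon_count: int


@dataclass
class GeneModel:
    """A gene span with a strand-aware TSS and its transcript structures.

    TSS is ``span.start`` on the + strand and ``span.end - 1`` on the -
    strand (the first transcribed base in 0-based coordinates).
    """

    gene_id: str
    span: GenomicInterval
    tss: int
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.span.start <= self.tss < self.span.end):
            raise ValueError(
                f"TSS {self.tss} outside span of gene {self.gene_id}"
            )

    def multi_exonic_transcripts(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.exon_count >= 2]


def count_overlaps(peaks: IntervalSet, targets: IntervalSet) -> dict[str, int]:
    """Count peaks overlapping >=1 target and targets overlapped by >=1 peak.

    Overlap means at least one shared base under half-open semantics; each
    interval is counted at most once regardless of multiplicity.
    """
    if len(peaks) == 0 or len(targets) == 0:
        return {"n_query_hit": 0, "n_target_hit": 0}
    return {
        "n_query_hit": int(targets.overlap_flags(peaks).sum()),
        "n_target_hit": int(peaks.overlap_flags(targets).sum()),
    }


def nearest_distance(anchor: GenomicInterval, targets: IntervalSet) -> float:
    """Gap in bp from anchor to the nearest target (0 if overlapping;
    inf if no target lies on the anchor's chromosome)."""
    return float(targets.nearest_distances(IntervalSet([anchor]))[0])
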