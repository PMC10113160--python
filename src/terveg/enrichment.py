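"""Per-family peak enrichment against a shuffled-peak null.

The statistic: for each repeat family, the number of peaks overlapping any
of its copies is compared with the same count over ``n_perm`` random
controls, in which every peak is re-placed uniformly at random on its own
chromosome, with its exact length, entirely inside a single mappable
segment (the complement of an unmappable-region mask).  The empirical
p-value uses the add-one estimator ``(1 + r) / (n_perm + 1)`` where ``r``
counts null overlap counts at least as large as the observed one, so the
smallest attainable p is exactly ``1/(n_perm + 1)`` and p is never 0.
Fold enrichment is observed / mean(null), with the null mean floored at
``1/n_perm`` so families never hit under the null get a finite fold.

Benjamini-Hochberg q-values are computed and reported across families; the
significance call itself uses the raw empirical p (p < 0.05, fold > 2, and
at least ten family copies overlapped by peaks; the p and fold cutoffs are
strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IntervalSet, TEAnnotation
from .io import read_chrom_sizes

__all__ = [
    "MappableSpace",
    "build_mappable_space",
    "shuffle_intervals",
    "family_enrichment",
    "call_significant",
    "ENRICHMENT_COLUMNS",
    "write_enrichment_tsv",
    "read_enrichment_tsv",
]

ENRICHMENT_COLUMNS = [
    "family",
    "n_copies",
    "n_obs_peaks",
    "n_elements_hit",
    "null_mean",
    "null_sd",
    "fold",
    "p_emp",
    "q_bh",
    "significant",
]


@dataclass
class MappableSpace:
    """Chromosome sizes plus the merged allowed placement regions."""

    chrom_sizes: dict[str, int]
    mappable: IntervalSet
    _segments: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        by: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.mappable:
            if iv.chrom not in self.chrom_sizes:
                raise ValueError(f"mappable interval on unknown chromosome {iv.chrom}")
            if iv.end > self.chrom_sizes[iv.chrom]:
                raise ValueError(
                    f"mappable interval {iv.chrom}:{iv.start}-{iv.end} beyond "
                    f"chromosome end {self.chrom_sizes[iv.chrom]}"
                )
            s, e = by.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
        self._segments = {}
        for chrom, (s, e) in by.items():
            order = np.argsort(s)
            self._segments[chrom] = (
                np.asarray(s, dtype=np.int64)[order],
                np.asarray(e, dtype=np.int64)[order],
            )
        if self.total_mappable_length() <= 0:
            raise ValueError("total mappable length must be > 0")

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self._segments.get(chrom, (empty, empty))

    def total_mappable_length(self) -> int:
        return sum(
            int((e - s).sum()) for s, e in self._segments.values()
        )


def build_mappable_space(
    chrom_sizes: Mapping[str, int] | str,
    exclusion_mask: IntervalSet | None = None,
) -> MappableSpace:
    """Complement the (merged) exclusion mask per chromosome.

    ``chrom_sizes`` may be a mapping or the path of a two-column TSV.  With
    no mask the whole genome is mappable.  A mask interval beyond its
    chromosome end is an error.
    """
    if isinstance(chrom_sizes, (str, bytes)) or hasattr(chrom_sizes, "__fspath__"):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    sizes = dict(chrom_sizes)
    mask = exclusion_mask if exclusion_mask is not None else IntervalSet()
    for iv in mask:
        if iv.chrom in sizes and iv.end > sizes[iv.chrom]:
            raise ValueError(
                f"mask interval {iv.chrom}:{iv.start}-{iv.end} beyond "
                f"chromosome end {sizes[iv.chrom]}"
            )
    return MappableSpace(sizes, mask.complement(sizes))


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _uniform_starts(
    lengths: np.ndarray,
    seg_starts: np.ndarray,
    seg_ends: np.ndarray,
    rng: np.random.Generator,
    labels: list[str],
) -> np.ndarray:
    """Uniform start positions over all placements where each interval fits
    entirely inside a single mappable segment."""
    seg_len = seg_ends - seg_starts
    valid = np.clip(seg_len[None, :] - lengths[:, None] + 1, 0, None)
    totals = valid.sum(axis=1)
    if (totals == 0).any():
        bad = int(np.argmax(totals == 0))
        raise ValueError(
            f"peak {labels[bad]} (length {lengths[bad]}) is longer than every "
            "mappable segment on its chromosome"
        )
    r = rng.integers(0, totals)
    cum = np.cumsum(valid, axis=1)
    seg_idx = (r[:, None] >= cum).sum(axis=1)
    prev = np.where(seg_idx > 0, np.take_along_axis(
        cum, np.maximum(seg_idx - 1, 0)[:, None], axis=1).ravel(), 0)
    return seg_starts[seg_idx] + (r - prev)


def shuffle_intervals(peaks: IntervalSet, space: MappableSpace, seed) -> IntervalSet:
    """Length-preserving per-chromosome shuffle avoiding masked regions.

    Each peak keeps its chromosome, length, name and strand; placement is
    uniform over valid start positions.  Deterministic for a fixed seed
    (``seed`` may be an int, SeedSequence or Generator).
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(_as_seed_sequence(seed))
    out: list[GenomicInterval | None] = [None] * len(peaks)
    by: dict[str, list[int]] = {}
    for i, iv in enumerate(peaks):
        by.setdefault(iv.chrom, []).append(i)
    for chrom in sorted(by):
        idxs = by[chrom]
        lengths = np.asarray([peaks[i].length for i in idxs], dtype=np.int64)
        seg_s, seg_e = space.segments(chrom)
        labels = [peaks[i].name or f"#{i}({chrom})" for i in idxs]
        starts = _uniform_starts(lengths, seg_s, seg_e, rng, labels)
        for k, i in enumerate(idxs):
            iv = peaks[i]
            out[i] = GenomicInterval(
                chrom, int(starts[k]), int(starts[k] + lengths[k]), iv.strand, iv.name
            )
    return IntervalSet(out)  # type: ignore[arg-type]


def _global_element_arrays(annotation: TEAnnotation, families: list[str]):
    """Per-chromosome sorted (starts, ends, family codes) for all elements,
    plus whether elements are globally non-overlapping (enables the fast
    join-based counting path)."""
    fam_code = {f: i for i, f in enumerate(families)}
    by: dict[str, list[tuple[int, int, int]]] = {}
    for el in annotation.elements:
        by.setdefault(el.interval.chrom, []).append(
            (el.interval.start, el.interval.end, fam_code[el.family])
        )
    arrays = {}
    disjoint = True
    for chrom, triples in by.items():
        triples.sort()
        s = np.asarray([t[0] for t in triples], dtype=np.int64)
        e = np.asarray([t[1] for t in triples], dtype=np.int64)
        c = np.asarray([t[2] for t in triples], dtype=np.int64)
        if len(s) > 1 and (s[1:] < e[:-1]).any():
            disjoint = False
        arrays[chrom] = (s, e, c)
    return arrays, disjoint


def _joined_family_counts(
    qs: np.ndarray,
    qe: np.ndarray,
    rows: np.ndarray,
    elem: tuple[np.ndarray, np.ndarray, np.ndarray],
    n_fam: int,
    n_rows: int,
) -> np.ndarray:
    """Count, per (family, row), queries overlapping >=1 element — for
    non-overlapping elements, where each query's overlapping elements form
    one contiguous run in start order."""
    es, ee, ec = elem
    lo = np.searchsorted(ee, qs, side="right")
    hi = np.searchsorted(es, qe, side="left")
    off = hi - lo
    total = int(off.sum())
    out = np.zeros(n_fam * n_rows, dtype=np.int64)
    if total == 0:
        return out.reshape(n_fam, n_rows)
    cum = np.cumsum(off)
    start_pos = cum - off
    rep = np.repeat(np.arange(len(qs), dtype=np.int64), off)
    elem_idx = (np.arange(total, dtype=np.int64)
                - np.repeat(start_pos, off)) + np.repeat(lo, off)
    # one count per distinct (query, family) pair
    key = rep * n_fam + ec[elem_idx]
    ukey = np.unique(key)
    fam_u = ukey % n_fam
    row_u = rows[ukey // n_fam]
    np.add.at(out, fam_u * n_rows + row_u, 1)
    return out.reshape(n_fam, n_rows)


def family_enrichment(
    peaks: IntervalSet,
    annotation: TEAnnotation,
    space: MappableSpace,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation peak enrichment per repeat family.

    Returns one row per family (sorted by name) with the columns in
    ``ENRICHMENT_COLUMNS``.  A single root seed drives the run; permutation
    ``i`` uses the i-th spawned sub-seed, so results are reproducible and
    independent of permutation evaluation order.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    families = annotation.families
    if not families:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    n_fam = len(families)
    elem_arrays, disjoint = _global_element_arrays(annotation, families)

    # observed statistics
    obs = np.zeros(n_fam, dtype=np.int64)
    elements_hit = np.zeros(n_fam, dtype=np.int64)
    merged_peaks = peaks.merged()
    for fi, fam in enumerate(families):
        fam_ivs = annotation.family_intervals(fam)
        if len(peaks):
            obs[fi] = int(fam_ivs.overlap_flags(peaks).sum())
            elements_hit[fi] = int(merged_peaks.overlap_flags(fam_ivs).sum())

    # null: all shuffled placements first, then vectorized counting
    by: dict[str, list[int]] = {}
    for i, iv in enumerate(peaks):
        by.setdefault(iv.chrom, []).append(i)
    chrom_lengths = {
        c: np.asarray([peaks[i].length for i in idxs], dtype=np.int64)
        for c, idxs in by.items()
    }
    root = _as_seed_sequence(seed)
    children = root.spawn(n_perm)
    null_qs: dict[str, np.ndarray] = {}
    null_qe: dict[str, np.ndarray] = {}
    if len(peaks):
        starts_by_chrom = {
            c: np.empty((n_perm, len(idxs)), dtype=np.int64)
            for c, idxs in by.items()
        }
        for p, child in enumerate(children):
            rng = np.random.default_rng(child)
            for chrom in sorted(by):
                idxs = by[chrom]
                seg_s, seg_e = space.segments(chrom)
                labels = [peaks[i].name or f"#{i}({chrom})" for i in idxs]
                starts_by_chrom[chrom][p, :] = _uniform_starts(
                    chrom_lengths[chrom], seg_s, seg_e, rng, labels
                )
        for chrom, starts in starts_by_chrom.items():
            null_qs[chrom] = starts.ravel()
            null_qe[chrom] = (starts + chrom_lengths[chrom][None, :]).ravel()

    null_counts = np.zeros((n_fam, n_perm), dtype=np.int64)
    if disjoint:
        for chrom in null_qs:
            if chrom not in elem_arrays:
                continue
            n_peaks_c = len(by[chrom])
            rows = np.repeat(
                np.arange(n_perm, dtype=np.int64), n_peaks_c
            )
            null_counts += _joined_family_counts(
                null_qs[chrom], null_qe[chrom], rows,
                elem_arrays[chrom], n_fam, n_perm,
            )
    else:
        for fi, fam in enumerate(families):
            fam_index = annotation.family_intervals(fam)._get_index()
            for chrom, ci in fam_index.items():
                if chrom not in null_qs:
                    continue
                lo = np.searchsorted(ci.merged_ends, null_qs[chrom],
                                     side="right")
                hi = np.searchsorted(ci.merged_starts, null_qe[chrom],
                                     side="left")
                hits = (hi > lo).reshape(n_perm, -1)
                null_counts[fi] += hits.sum(axis=1)

    null_mean = null_counts.mean(axis=1)
    null_sd = null_counts.std(axis=1)
    r = (null_counts >= obs[:, None]).sum(axis=1)
    p_emp = (1.0 + r) / (n_perm + 1.0)
    eps = 1.0 / n_perm
    fold = np.where(obs == 0, 0.0, obs / np.maximum(null_mean, eps))
    q_bh = multipletests(p_emp, method="fdr_bh")[1]

    df = pd.DataFrame(
        {
            "family": families,
            "n_copies": [annotation.copy_number(f) for f in families],
            "n_obs_peaks": obs,
            "n_elements_hit": elements_hit,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "fold": fold,
            "p_emp": p_emp,
            "q_bh": q_bh,
        }
    )
    return call_significant(df)


def call_significant(
    records: pd.DataFrame,
    p_max: float = 0.05,
    fold_min: float = 2.0,
    min_copies_hit: int = 10,
) -> pd.DataFrame:
    """Apply the significance rule: p < p_max (strict), fold > fold_min
    (strict) and at least ``min_copies_hit`` family copies overlapped."""
    out = records.copy()
    out["significant"] = (
        (out["p_emp"] < p_max)
        & (out["fold"] > fold_min)
        & (out["n_elements_hit"] >= min_copies_hit)
    )
    return out[ENRICHMENT_COLUMNS] if set(ENRICHMENT_COLUMNS) <= set(out.columns) else out


def write_enrichment_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_enrichment_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
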