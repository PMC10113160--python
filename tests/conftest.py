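"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (O(n*m) double loops, per-base
coordinate mapping, hand-rolled BH step-up) and never share code with the
implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from terveg.intervals import GenomicInterval, IntervalSet


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_count_overlaps(peaks: IntervalSet, targets: IntervalSet) -> dict:
    """All-pairs double-loop overlap counting."""
    n_query_hit = sum(
        1 for p in peaks if any(p.overlaps(t) for t in targets)
    )
    n_target_hit = sum(
        1 for t in targets if any(p.overlaps(t) for p in peaks)
    )
    return {"n_query_hit": n_query_hit, "n_target_hit": n_target_hit}


def brute_nearest(anchor: GenomicInterval, targets: IntervalSet) -> float:
    """Exhaustive per-target edge-gap minimum."""
    dists = [anchor.distance_to(t) for t in targets if t.chrom == anchor.chrom]
    return min(dists) if dists else float("inf")


def brute_lift(iv: GenomicInterval, blocks, min_frac: float):
    """Per-base mapping oracle: map every base through the block list,
    merge mapped bases per target chromosome into contiguous regions and
    apply the acceptance rule.  ``blocks`` is the CoordinateMap.blocks
    DataFrame."""
    rows = list(blocks.itertuples(index=False))
    mapped: dict[str, set[int]] = {}
    for pos in range(iv.start, iv.end):
        for b in rows:
            if b.src_chrom == iv.chrom and b.src_start <= pos < b.src_end:
                off = pos - b.src_start
                if b.dst_strand == "-":
                    dst = b.dst_end - 1 - off
                else:
                    dst = b.dst_start + off
                mapped.setdefault(str(b.dst_chrom), set()).add(int(dst))
                break
    best = None
    for chrom, bases in mapped.items():
        ordered = sorted(bases)
        run_start = ordered[0]
        prev = ordered[0]
        runs = []
        for p in ordered[1:]:
            if p == prev + 1:
                prev = p
            else:
                runs.append((run_start, prev + 1))
                run_start = prev = p
        runs.append((run_start, prev + 1))
        for s, e in runs:
            n_mapped = sum(1 for p in bases if s <= p < e)
            if best is None or n_mapped > best[0]:
                best = (n_mapped, chrom, s, e)
    if best is not None and best[0] >= min_frac * iv.length:
        return GenomicInterval(best[1], best[2], best[3])
    return None


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Independent Benjamini-Hochberg step-up implementation."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def random_interval_set(
    rng: np.random.Generator,
    n: int,
    chroms=("chrR1", "chrR2"),
    span: int = 1_000_000,
    max_len: int = 5_000,
) -> IntervalSet:
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs)


@pytest.fixture
def rng():
    return np.random.default_rng(20230403)
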