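"""Readers and writers for the standard interval formats.

BED is consumed verbatim (already 0-based half-open).  RepeatMasker ``.out``
and GTF use 1-based inclusive coordinates and are converted at the boundary.
A fallback "BED + family name in column 4" dialect is supported for TE
annotations.  Chromosome sizes are a two-column TSV (name, length).
"""

from __future__ import annotations

import warnings
from typing import Mapping

from .intervals import (
    GenomicInterval,
    GeneModel,
    IntervalSet,
    TEAnnotation,
    TEElement,
    TranscriptModel,
)

__all__ = [
    "read_bed",
    "write_bed",
    "read_repeatmasker_out",
    "read_te_bed",
    "write_te_bed",
    "read_gtf_genes",
    "write_gtf",
    "read_chrom_sizes",
    "write_chrom_sizes",
]


def read_bed(path) -> IntervalSet:
    """Read a BED3+ file into an IntervalSet.

    Track/browser/comment lines are skipped; malformed lines raise with
    their line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, name))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path) -> None:
    """Write BED6; write-then-read round-trips coordinates bit-exactly."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_repeatmasker_out(path) -> TEAnnotation:
    """Read a RepeatMasker ``.out`` annotation.

    Layout: 3 header lines, whitespace-separated columns, 1-based inclusive
    begin/end (converted here to 0-based half-open); strand 'C' maps to '-';
    the repeat-name column supplies the family.
    """
    elements = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=11 whitespace-"
                    f"separated columns, got {len(fields)}"
                )
            try:
                chrom = fields[4]
                begin, end = int(fields[5]), int(fields[6])
                strand = "-" if fields[8] == "C" else "+"
                family = fields[9]
                class_label = fields[10]
                iv = GenomicInterval(chrom, begin - 1, end, strand)
                elements.append(TEElement(iv, family, class_label))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return TEAnnotation(elements)


def read_te_bed(path) -> TEAnnotation:
    """Read the fallback TE dialect: BED with the family name in column 4."""
    elements = []
    for iv in read_bed(path):
        if iv.name is None:
            raise ValueError(f"{path}: TE BED requires a family name in column 4")
        elements.append(TEElement(iv, iv.name))
    return TEAnnotation(elements)


def write_te_bed(annotation: TEAnnotation, path) -> None:
    with open(path, "w") as fh:
        for el in annotation.elements:
            iv = el.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{el.family}\t0\t{iv.strand}\n")


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf_genes(path) -> list[GeneModel]:
    """Read gene models from a GTF (1-based inclusive coordinates).

    Builds one GeneModel per gene with a strand-aware TSS; exon_count per
    transcript counts exon records.  Transcripts without exons get
    exon_count 0 with a warning (they are excluded from multi-exonic
    queries downstream).
    """
    genes: dict[str, dict] = {}
    tx_meta: dict[str, dict] = {}
    exon_counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attr = fields[:9]
            start0, end0 = int(start) - 1, int(end)
            attrs = _parse_gtf_attributes(attr)
            if feature == "gene":
                gid = attrs["gene_id"]
                genes[gid] = {"chrom": chrom, "start": start0, "end": end0,
                              "strand": strand}
            elif feature == "transcript":
                tid = attrs["transcript_id"]
                tx_meta[tid] = {
                    "gene_id": attrs["gene_id"],
                    "tss": start0 if strand == "+" else end0 - 1,
                }
            elif feature == "exon":
                tid = attrs["transcript_id"]
                exon_counts[tid] = exon_counts.get(tid, 0) + 1

    models = []
    tx_by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, meta in tx_meta.items():
        n_exons = exon_counts.get(tid, 0)
        if n_exons == 0:
            warnings.warn(f"transcript {tid} has no exon records; exon_count 0")
        tx_by_gene.setdefault(meta["gene_id"], []).append(
            TranscriptModel(tid, meta["tss"], n_exons)
        )
    for gid in sorted(genes):
        g = genes[gid]
        span = GenomicInterval(g["chrom"], g["start"], g["end"], g["strand"], gid)
        tss = g["start"] if g["strand"] == "+" else g["end"] - 1
        models.append(
            GeneModel(gid, span, tss, sorted(tx_by_gene.get(gid, []),
                                             key=lambda t: t.transcript_id))
        )
    return models


def write_gtf(genes: list[GeneModel], path, source: str = "terveg") -> None:
    """Write gene/transcript/exon records (transcripts as single exons
    unless exon structure is synthesized by the caller)."""
    with open(path, "w") as fh:
        for g in genes:
            s1, e1 = g.span.start + 1, g.span.end
            strand = g.span.strand if g.span.strand in "+-" else "+"
            fh.write(
                f"{g.span.chrom}\t{source}\tgene\t{s1}\t{e1}\t.\t{strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.span.chrom}\t{source}\ttranscript\t{s1}\t{e1}\t.\t"
                    f'{strand}\t.\tgene_id "{g.gene_id}"; '
                    f'transcript_id "{t.transcript_id}";\n'
                )
                # evenly split the span into exon_count exon records
                n = max(t.exon_count, 1)
                length = g.span.end - g.span.start
                bounds = [g.span.start + (length * k) // n for k in range(n + 1)]
                for k in range(t.exon_count):
                    fh.write(
                        f"{g.span.chrom}\t{source}\texon\t{bounds[k] + 1}\t"
                        f'{bounds[k + 1]}\t.\t{strand}\t.\t'
                        f'gene_id "{g.gene_id}"; '
                        f'transcript_id "{t.transcript_id}";\n'
                    )


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected name and length")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sizes):
            fh.write(f"{name}\t{sizes[name]}\n")
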