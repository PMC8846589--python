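"""Coordinate conventions, interval arithmetic, and strand-aware promoter
and gene-territory construction.

All internal coordinates are 1-based inclusive: an interval ``[start, end]``
contains ``end - start + 1`` bases.  BED-family inputs (0-based half-open)
are converted on read by their respective readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "PromoterRule",
    "interval_length",
    "promoter_window",
    "gene_territory",
    "overlaps",
    "merge_intervals",
    "read_gff3_genes",
    "read_fasta_lengths",
    "read_fasta_sequences",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval on one scaffold, 1-based inclusive."""

    seqid: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end ({self.end}) < start ({self.start}) on {self.seqid}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene span; the TSS is the 5' boundary of the span."""

    gene_id: str
    span: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def seqid(self) -> str:
        return self.span.seqid

    @property
    def tss(self) -> int:
        """Transcription start site: span start on '+', span end on '-'."""
        return self.span.start if self.strand == "+" else self.span.end


@dataclass(frozen=True)
class PromoterRule:
    """Strand-aware promoter window sizes around the TSS (in bp)."""

    upstream_bp: int = 350
    downstream_bp: int = 100

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("promoter window extents must be non-negative")


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp under the 1-based inclusive convention (end - start + 1)."""
    return len(iv)


def promoter_window(
    gene: GeneModel, rule: PromoterRule | None = None, seq_length: int | None = None
) -> GenomicInterval:
    """Promoter window around the TSS, strand-aware, clipped to the scaffold.

    On '+' the window is ``[TSS - upstream, TSS + downstream]``; on '-' the
    roles of upstream/downstream mirror.  The window always contains the TSS
    base itself, so its unclipped length is ``upstream + downstream + 1``.
    """
    rule = rule or PromoterRule()
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = tss - rule.upstream_bp, tss + rule.downstream_bp
    else:
        lo, hi = tss - rule.downstream_bp, tss + rule.upstream_bp
    lo = max(1, lo)
    if seq_length is not None:
        hi = min(hi, seq_length)
    return GenomicInterval(gene.seqid, lo, hi)


def gene_territory(
    gene: GeneModel, rule: PromoterRule | None = None, seq_length: int | None = None
) -> GenomicInterval:
    """Union of the promoter window and the gene body.

    Because the promoter window contains the TSS (a gene-span boundary), the
    union is always a single contiguous interval.
    """
    win = promoter_window(gene, rule, seq_length)
    return GenomicInterval(
        gene.seqid, min(win.start, gene.span.start), max(win.end, gene.span.end)
    )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base (same seqid)."""
    return a.seqid == b.seqid and a.start <= b.end and b.start <= a.end


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge touching/overlapping intervals per seqid, sorted output."""
    out: list[GenomicInterval] = []
    for iv in sorted(ivs):
        if out and out[-1].seqid == iv.seqid and iv.start <= out[-1].end + 1:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.seqid, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


# ---------------------------------------------------------------------------
# readers

def read_gff3_genes(
    path: str | Path, feature_type: str = "gene"
) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    Only features of ``feature_type`` are kept; the ``ID`` attribute is the
    gene id.  Score and phase columns may be '.'.  GFF3 is already 1-based
    inclusive, so coordinates pass through unchanged.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != feature_type:
                continue
            attr_map = _parse_gff3_attributes(attrs)
            gene_id = attr_map.get("ID")
            if gene_id is None:
                raise ValueError(f"{path}: line {lineno}: {feature_type} feature lacks ID attribute")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    span=GenomicInterval(seqid, int(start), int(end)),
                    strand=strand,
                )
            )
    return genes


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            continue
        key, _, val = part.partition("=")
        out[key] = val
    return out


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    """Scaffold id -> length, from a FASTA file."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Scaffold id -> uppercase sequence string, from a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
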