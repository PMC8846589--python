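"""Assign consensus peaks to genes: a gene is a direct target iff at least
one consensus peak overlaps its territory (promoter window plus gene body)
by >= 1 bp.  A peak overlapping several territories supports all of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from regulonkit.genome_intervals import (
    GeneModel,
    GenomicInterval,
    PromoterRule,
    gene_territory,
    overlaps,
)
from regulonkit.peak_consensus import ConsensusPeak

__all__ = ["TargetCall", "assign_targets", "write_targets_tsv", "read_targets_tsv"]


@dataclass(frozen=True)
class TargetCall:
    """A gene called as a direct target, with its supporting peak indices."""

    gene_id: str
    supporting_peaks: tuple[int, ...]  # indices into the input consensus list
    territory: GenomicInterval

    def __post_init__(self) -> None:
        if len(self.supporting_peaks) < 1:
            raise ValueError("a target call requires >= 1 supporting peak")


def assign_targets(
    peaks: Sequence[ConsensusPeak],
    genes: Sequence[GeneModel],
    rule: PromoterRule | None = None,
    seq_lengths: dict[str, int] | None = None,
    min_overlap_bp: int = 1,
) -> list[TargetCall]:
    """One TargetCall per gene whose territory a peak overlaps.

    Output is sorted by gene_id.  Duplicate gene ids are rejected.
    """
    rule = rule or PromoterRule()
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene id: {g.gene_id}")
        seen.add(g.gene_id)

    peaks_by_seqid: dict[str, list[tuple[int, ConsensusPeak]]] = {}
    for i, cp in enumerate(peaks):
        peaks_by_seqid.setdefault(cp.interval.seqid, []).append((i, cp))

    calls: list[TargetCall] = []
    for gene in genes:
        seq_len = seq_lengths.get(gene.seqid) if seq_lengths else None
        territory = gene_territory(gene, rule, seq_len)
        support = [
            i
            for i, cp in peaks_by_seqid.get(gene.seqid, [])
            if overlaps(cp.interval, territory)
            and _overlap_bp(cp.interval, territory) >= min_overlap_bp
        ]
        if support:
            calls.append(
                TargetCall(
                    gene_id=gene.gene_id,
                    supporting_peaks=tuple(sorted(support)),
                    territory=territory,
                )
            )
    calls.sort(key=lambda c: c.gene_id)
    return calls


def _overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def read_targets_tsv(path: str | Path) -> list[TargetCall]:
    """Round-trip reader for the table written by :func:`write_targets_tsv`."""
    calls: list[TargetCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "n_supporting_peaks"]:
            raise ValueError(f"{path}: unexpected targets table header")
        for line in fh:
            gene_id, _n, peak_ids, loc = line.rstrip("\n").split("\t")
            seqid, _, span = loc.partition(":")
            start, _, end = span.partition("-")
            calls.append(
                TargetCall(
                    gene_id=gene_id,
                    supporting_peaks=tuple(
                        int(p.rsplit("_", 1)[1]) - 1 for p in peak_ids.split(",") if p
                    ),
                    territory=GenomicInterval(seqid, int(start), int(end)),
                )
            )
    return calls


def write_targets_tsv(calls: Sequence[TargetCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn_supporting_peaks\tpeak_ids\tterritory\n")
        for c in calls:
            peak_ids = ",".join(f"consensus_{i + 1}" for i in c.supporting_peaks)
            t = c.territory
            fh.write(
                f"{c.gene_id}\t{len(c.supporting_peaks)}\t{peak_ids}\t"
                f"{t.seqid}:{t.start}-{t.end}\n"
            )
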