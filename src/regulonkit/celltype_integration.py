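"""Per-cell-type (metacell) regulon composition.

A gene is "represented" in a metacell when its footprint value is strictly
above a threshold (default 0, i.e. any nonzero footprint).  Summaries count
activated/repressed targets per metacell, the repression proportion as a
percentage, and exclusive markers (represented in exactly one metacell).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from regulonkit.regulon_classify import TargetClass

__all__ = [
    "MetacellMatrix",
    "RegulonSummary",
    "read_metacell_tsv",
    "represented_targets",
    "repression_proportion",
    "exclusive_markers",
    "summarize_regulons",
    "write_summary_tsv",
]


@dataclass
class MetacellMatrix:
    """Gene x metacell footprint matrix with a representation threshold."""

    footprint: pd.DataFrame  # index: gene ids, columns: metacell ids
    represented_threshold: float = 0.0

    def __post_init__(self) -> None:
        if (self.footprint.values < 0).any():
            raise ValueError("footprint values must be non-negative")
        if self.footprint.index.has_duplicates:
            raise ValueError("duplicate gene ids in metacell matrix")
        if self.footprint.columns.has_duplicates:
            raise ValueError("duplicate metacell ids in metacell matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.footprint.index)

    @property
    def metacells(self) -> list[str]:
        return list(self.footprint.columns)

    def is_represented(self, gene_id: str, metacell_id: str) -> bool:
        if gene_id not in self.footprint.index:
            return False
        return float(self.footprint.at[gene_id, metacell_id]) > self.represented_threshold

    def represented_genes(self, metacell_id: str) -> set[str]:
        col = self.footprint[metacell_id]
        return set(col.index[col > self.represented_threshold])


@dataclass(frozen=True)
class RegulonSummary:
    """Regulon composition of one metacell."""

    metacell_id: str
    n_activated: int
    n_repressed: int
    repression_pct: float | None
    exclusive_genes: tuple[str, ...] = ()

    @property
    def n_total(self) -> int:
        return self.n_activated + self.n_repressed


def read_metacell_tsv(path: str | Path, represented_threshold: float = 0.0) -> MetacellMatrix:
    """Read a metacell footprint TSV (first column gene_id, one column per
    metacell, non-negative values)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return MetacellMatrix(footprint=df, represented_threshold=represented_threshold)


def represented_targets(
    M: MetacellMatrix, classes: Sequence[TargetClass]
) -> dict[str, tuple[set[str], set[str]]]:
    """Per metacell: (activated gene set, repressed gene set) represented
    there.  Genes absent from the matrix count as not represented."""
    activated = {c.gene_id for c in classes if c.label == "activated"}
    repressed = {c.gene_id for c in classes if c.label == "repressed"}
    out: dict[str, tuple[set[str], set[str]]] = {}
    for mc in M.metacells:
        rep = M.represented_genes(mc)
        out[mc] = (activated & rep, repressed & rep)
    return out


def repression_proportion(
    n_activated: int, n_repressed: int, decimals: int = 2
) -> float | None:
    """100 * repressed / (activated + repressed), rounded half-up.

    With zero total targets the proportion is undefined and None is
    returned (reported as missing, never as 0).
    """
    total = n_activated + n_repressed
    if total == 0:
        return None
    pct = Decimal(100) * Decimal(n_repressed) / Decimal(total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def exclusive_markers(
    M: MetacellMatrix, gene_set: set[str], metacell_id: str
) -> set[str]:
    """Genes of ``gene_set`` represented in ``metacell_id`` and nowhere else."""
    if metacell_id not in M.footprint.columns:
        raise ValueError(f"unknown metacell id: {metacell_id}")
    here = M.represented_genes(metacell_id) & gene_set
    for other in M.metacells:
        if other == metacell_id:
            continue
        here -= M.represented_genes(other)
        if not here:
            break
    return here


def summarize_regulons(
    M: MetacellMatrix, classes: Sequence[TargetClass], decimals: int = 2
) -> list[RegulonSummary]:
    """One RegulonSummary per metacell with >= 1 represented target,
    sorted by metacell id."""
    per_mc = represented_targets(M, classes)
    summaries: list[RegulonSummary] = []
    for mc in sorted(per_mc):
        act, rep = per_mc[mc]
        if not act and not rep:
            continue
        summaries.append(
            RegulonSummary(
                metacell_id=mc,
                n_activated=len(act),
                n_repressed=len(rep),
                repression_pct=repression_proportion(len(act), len(rep), decimals),
                exclusive_genes=tuple(sorted(exclusive_markers(M, act | rep, mc))),
            )
        )
    return summaries


def write_summary_tsv(summaries: Sequence[RegulonSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "metacell_id\tn_activated\tn_repressed\tn_total\trepression_pct\texclusive_genes\n"
        )
        for s in summaries:
            pct = "NA" if s.repression_pct is None else f"{s.repression_pct:g}"
            fh.write(
                f"{s.metacell_id}\t{s.n_activated}\t{s.n_repressed}\t{s.n_total}\t"
                f"{pct}\t{','.join(s.exclusive_genes)}\n"
            )
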