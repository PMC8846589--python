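"""Intersect direct targets with differential expression to label genes as
directly activated, directly repressed, or target-only.

Sign convention: log2 fold change is mutant relative to sibling control, so
a gene DOWN in the mutant (log2fc < 0) is ACTIVATED by the factor, and a
gene UP in the mutant is REPRESSED by it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from regulonkit.target_assignment import TargetCall

__all__ = [
    "DERecord",
    "TargetClass",
    "read_de_table",
    "classify_de",
    "split_targets",
    "detect_autoregulation",
    "write_classification_tsv",
    "read_classification_tsv",
]

LABELS = ("activated", "repressed", "target_only")


@dataclass(frozen=True)
class DERecord:
    """Per-gene differential expression: log2fc (mutant vs sibling), BH padj."""

    gene_id: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.padj <= 1.0) and not math.isnan(self.padj):
            raise ValueError(f"padj must be in [0, 1], got {self.padj}")


@dataclass(frozen=True)
class TargetClass:
    gene_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a DE TSV with required header gene_id, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s): {sorted(missing)}")
    return [
        DERecord(gene_id=str(r.gene_id), log2fc=float(r.log2fc), padj=float(r.padj))
        for r in df.itertuples(index=False)
    ]


def classify_de(
    de: Iterable[DERecord], alpha: float = 0.01
) -> tuple[set[str], set[str]]:
    """Split DE records into (down_set, up_set) at strict padj < alpha.

    Genes with log2fc == 0 land in neither set; records with missing padj
    are excluded with a warning.
    """
    seen: set[str] = set()
    down: set[str] = set()
    up: set[str] = set()
    for rec in de:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene id in DE table: {rec.gene_id}")
        seen.add(rec.gene_id)
        if math.isnan(rec.padj):
            warnings.warn(f"gene {rec.gene_id}: missing padj, excluded", stacklevel=2)
            continue
        if rec.padj < alpha:
            if rec.log2fc < 0:
                down.add(rec.gene_id)
            elif rec.log2fc > 0:
                up.add(rec.gene_id)
    return down, up


def split_targets(
    targets: Sequence[TargetCall], down_set: set[str], up_set: set[str]
) -> list[TargetClass]:
    """Label each target: in down_set -> activated, in up_set -> repressed,
    otherwise target_only.  The three labels partition the target set."""
    if down_set & up_set:
        raise ValueError("down and up sets must be disjoint")
    out: list[TargetClass] = []
    for t in targets:
        if t.gene_id in down_set:
            label = "activated"
        elif t.gene_id in up_set:
            label = "repressed"
        else:
            label = "target_only"
        out.append(TargetClass(gene_id=t.gene_id, label=label))
    return out


def detect_autoregulation(tf_gene_id: str, classes: Sequence[TargetClass]) -> str:
    """Report how the factor regulates its own locus.

    Returns 'activates_self', 'represses_self', or 'none' (the factor is not
    among the classified targets, or is target-only).
    """
    for c in classes:
        if c.gene_id == tf_gene_id:
            if c.label == "activated":
                return "activates_self"
            if c.label == "repressed":
                return "represses_self"
            return "none"
    return "none"


def read_classification_tsv(path: str | Path) -> list[TargetClass]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "label" not in df.columns or "gene_id" not in df.columns:
        raise ValueError(f"{path}: expected gene_id and label columns")
    return [TargetClass(gene_id=r.gene_id, label=r.label) for r in df.itertuples(index=False)]


def write_classification_tsv(
    classes: Sequence[TargetClass],
    targets: Sequence[TargetCall],
    de: Sequence[DERecord],
    path: str | Path,
) -> None:
    de_by_id = {r.gene_id: r for r in de}
    support = {t.gene_id: len(t.supporting_peaks) for t in targets}
    with open(path, "w") as fh:
        fh.write("gene_id\tlabel\tlog2fc\tpadj\tn_supporting_peaks\n")
        for c in sorted(classes, key=lambda c: c.gene_id):
            rec = de_by_id.get(c.gene_id)
            l2fc = f"{rec.log2fc:.6g}" if rec else "NA"
            padj = f"{rec.padj:.6g}" if rec else "NA"
            fh.write(f"{c.gene_id}\t{c.label}\t{l2fc}\t{padj}\t{support.get(c.gene_id, 0)}\n")
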