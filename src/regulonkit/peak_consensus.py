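"""Replicate peak sets -> consensus peaks.

Reads ENCODE narrowPeak files (one per replicate) and confirms candidate
peak groups by a simplified weak/strong rule: peaks overlapping across
replicates (transitive closure, >= 1 bp) form a candidate group; the group
is confirmed iff its Fisher-combined p-value passes the strong threshold,
every member passes the weak threshold, and enough distinct replicates
support it.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from regulonkit.genome_intervals import GenomicInterval

__all__ = [
    "Peak",
    "ConsensusConfig",
    "ConsensusPeak",
    "read_narrowpeak",
    "write_narrowpeak",
    "fisher_combine",
    "build_consensus",
    "write_consensus_audit",
]


@dataclass(frozen=True)
class Peak:
    """A scored peak from one replicate (1-based inclusive interval)."""

    interval: GenomicInterval
    score: float = 0.0
    neglog10_p: float = 0.0
    summit_offset: int = -1  # bp from interval start; -1 if absent
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.neglog10_p < 0:
            raise ValueError("neglog10_p must be >= 0")
        if not (-1 <= self.summit_offset <= len(self.interval) - 1):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak of length {len(self.interval)}"
            )

    @property
    def pvalue(self) -> float:
        return 10.0 ** (-self.neglog10_p)


@dataclass(frozen=True)
class ConsensusConfig:
    """Thresholds for the weak/strong confirmation rule (raw p-values)."""

    weak_threshold: float = 1e-4
    strong_threshold: float = 1e-8
    min_supporting_replicates: int = 1

    def __post_init__(self) -> None:
        if self.strong_threshold > self.weak_threshold:
            raise ValueError("strong_threshold must be <= weak_threshold")
        if self.min_supporting_replicates < 0:
            raise ValueError("min_supporting_replicates must be >= 0")


@dataclass(frozen=True)
class ConsensusPeak:
    """A confirmed group of overlapping replicate peaks (union interval)."""

    interval: GenomicInterval
    combined_neglog10_p: float
    n_replicates_supporting: int
    member_peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        if self.n_replicates_supporting < 1:
            raise ValueError("a consensus peak needs >= 1 supporting replicate")
        for p in self.member_peaks:
            iv = p.interval
            if not (
                iv.seqid == self.interval.seqid
                and self.interval.start <= iv.start
                and iv.end <= self.interval.end
            ):
                raise ValueError("consensus interval must cover every member peak")


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Parse an ENCODE narrowPeak (BED6+4) file into 1-based Peaks.

    narrowPeak coordinates are 0-based half-open; they are converted to
    1-based inclusive (start+1, end).  Column 8 is -log10(p); column 10 is
    the summit offset from the interval start.  Missing optional columns
    fall back to score 0, -log10(p) 0 and summit -1.
    """
    replicate_id = Path(path).stem
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                seqid = cols[0]
                start0, end0 = int(cols[1]), int(cols[2])
                if end0 <= start0:
                    raise ValueError("end <= start")
                score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
                neglog10_p = float(cols[7]) if len(cols) > 7 and cols[7] != "." else 0.0
                summit = int(cols[9]) if len(cols) > 9 and cols[9] != "." else -1
                peaks.append(
                    Peak(
                        interval=GenomicInterval(seqid, start0 + 1, end0),
                        score=score,
                        neglog10_p=neglog10_p,
                        summit_offset=summit,
                        replicate_id=replicate_id,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed narrowPeak record ({exc})") from exc
    return peaks


def write_narrowpeak(peaks: Iterable[ConsensusPeak], path: str | Path) -> None:
    """Write consensus peaks back out as narrowPeak (0-based half-open)."""
    with open(path, "w") as fh:
        for i, cp in enumerate(peaks):
            iv = cp.interval
            fh.write(
                "\t".join(
                    [
                        iv.seqid,
                        str(iv.start - 1),
                        str(iv.end),
                        f"consensus_{i + 1}",
                        "0",
                        ".",
                        "0",
                        f"{cp.combined_neglog10_p:.6g}",
                        "-1",
                        "-1",
                    ]
                )
                + "\n"
            )


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's method: X = -2 sum(ln p_i) ~ chi-square with 2k df.

    Zero p-values are clamped to the smallest positive float with a warning.
    """
    if len(pvalues) == 0:
        raise ValueError("fisher_combine requires a non-empty p-value list")
    ps = np.asarray(pvalues, dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(ps == 0):
        warnings.warn("p-value of 0 clamped to smallest positive float", stacklevel=2)
        ps = np.maximum(ps, sys.float_info.min)
    x = -2.0 * np.sum(np.log(ps))
    return float(stats.chi2.sf(x, df=2 * len(ps)))


def _group_overlapping(peaks: list[Peak]) -> list[list[Peak]]:
    """Maximal groups of transitively overlapping peaks (per seqid sweep)."""
    groups: list[list[Peak]] = []
    by_seqid: dict[str, list[Peak]] = {}
    for p in peaks:
        by_seqid.setdefault(p.interval.seqid, []).append(p)
    for seqid in sorted(by_seqid):
        chrom = sorted(
            by_seqid[seqid], key=lambda p: (p.interval.start, p.interval.end, p.replicate_id)
        )
        current: list[Peak] = []
        reach = -1
        for p in chrom:
            if current and p.interval.start <= reach:
                current.append(p)
                reach = max(reach, p.interval.end)
            else:
                if current:
                    groups.append(current)
                current = [p]
                reach = p.interval.end
        if current:
            groups.append(current)
    return groups


def build_consensus(
    replicate_sets: Sequence[Sequence[Peak]], cfg: ConsensusConfig | None = None
) -> list[ConsensusPeak]:
    """Confirm consensus peaks across replicate peak sets.

    Output is deterministic: sorted by seqid then start, and invariant to
    the order of replicate sets and within-replicate peak order.
    """
    if len(replicate_sets) == 0:
        raise ValueError("at least one replicate peak set is required")
    cfg = cfg or ConsensusConfig()
    all_peaks = [p for rep in replicate_sets for p in rep]
    out: list[ConsensusPeak] = []
    for group in _group_overlapping(all_peaks):
        pvals = [p.pvalue for p in group]
        if any(pv > cfg.weak_threshold for pv in pvals):
            continue
        combined = fisher_combine(pvals)
        if combined > cfg.strong_threshold:
            continue
        n_reps = len({p.replicate_id for p in group})
        if n_reps < cfg.min_supporting_replicates:
            continue
        seqid = group[0].interval.seqid
        union = GenomicInterval(
            seqid,
            min(p.interval.start for p in group),
            max(p.interval.end for p in group),
        )
        with np.errstate(divide="ignore"):
            combined_nlp = float(-np.log10(combined)) if combined > 0 else float("inf")
        out.append(
            ConsensusPeak(
                interval=union,
                combined_neglog10_p=combined_nlp,
                n_replicates_supporting=n_reps,
                member_peaks=tuple(
                    sorted(group, key=lambda p: (p.interval.start, p.interval.end, p.replicate_id))
                ),
            )
        )
    out.sort(key=lambda cp: (cp.interval.seqid, cp.interval.start, cp.interval.end))
    return out


def write_consensus_audit(consensus: Sequence[ConsensusPeak], path: str | Path) -> None:
    """TSV audit table: group id, member peaks, replicate support, combined p."""
    with open(path, "w") as fh:
        fh.write("group_id\tseqid\tstart\tend\tn_replicates\tcombined_neglog10_p\tmembers\n")
        for i, cp in enumerate(consensus):
            members = ",".join(
                f"{p.replicate_id}:{p.interval.start}-{p.interval.end}" for p in cp.member_peaks
            )
            fh.write(
                f"consensus_{i + 1}\t{cp.interval.seqid}\t{cp.interval.start}\t"
                f"{cp.interval.end}\t{cp.n_replicates_supporting}\t"
                f"{cp.combined_neglog10_p:.6g}\t{members}\n"
            )
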