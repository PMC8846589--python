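"""Degenerate consensus motifs: parsing, expansion, double-strand scanning,
and positional (central) enrichment within peak windows.

Matching is literal IUPAC set membership per position — not PWM scoring.
``N`` in the subject sequence never matches any motif symbol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from scipy import stats

from regulonkit.genome_intervals import GenomicInterval

__all__ = [
    "IUPAC_CODES",
    "DegenerateMotif",
    "MotifHit",
    "CentralityConfig",
    "parse_consensus",
    "expand_iupac",
    "reverse_complement",
    "scan_sequence",
    "central_enrichment_test",
    "write_hits_bed",
]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASE_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

_PAREN_RE = re.compile(r"\(([ACGT](?:/[ACGT])+)\)")


@dataclass(frozen=True)
class DegenerateMotif:
    """A labelled consensus over the IUPAC nucleotide alphabet."""

    consensus: str
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.consensus) < 1:
            raise ValueError("motif consensus must be non-empty")
        bad = [c for c in self.consensus if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"invalid IUPAC symbol(s) in consensus: {bad}")

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifHit:
    """A located motif match, reported on forward-strand coordinates.

    ``start`` is the 1-based position of the leftmost matched base on the
    forward strand regardless of hit strand; ``matched_seq`` is the
    forward-strand slice of the matched window.
    """

    seqid: str
    start: int
    strand: str
    matched_seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched_seq) - 1


@dataclass(frozen=True)
class CentralityConfig:
    """Fraction of the window counted as its central region."""

    central_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.central_fraction < 1.0):
            raise ValueError("central_fraction must lie in (0, 1)")


def parse_consensus(text: str, label: str = "") -> DegenerateMotif:
    """Normalize a consensus written in IUPAC or parenthetical notation.

    ``"AT(A/T)ATT(A/T)AT"`` -> ``ATWATTWAT``; an unknown symbol or an
    unresolvable parenthetical is an error.
    """

    def _collapse(match: re.Match[str]) -> str:
        bases = frozenset(match.group(1).split("/"))
        code = _SET_TO_CODE.get(bases)
        if code is None:
            raise ValueError(f"cannot map base set {sorted(bases)} to an IUPAC code")
        return code

    normalized = _PAREN_RE.sub(_collapse, text.strip().upper())
    if "(" in normalized or ")" in normalized or "/" in normalized:
        raise ValueError(f"malformed parenthetical notation in {text!r}")
    return DegenerateMotif(consensus=normalized, label=label)


def expand_iupac(m: DegenerateMotif) -> set[str]:
    """All concrete ACGT sequences matching the consensus (Cartesian expansion)."""
    choices = [sorted(IUPAC_CODES[c]) for c in m.consensus]
    return {"".join(combo) for combo in product(*choices)}


def reverse_complement(seq: str) -> str:
    """Reverse complement, preserving IUPAC degeneracy codes."""
    return seq.translate(_BASE_COMPLEMENT)[::-1]


def _motif_regex(m: DegenerateMotif) -> re.Pattern[str]:
    # N in the subject never matches, so the character classes are concrete.
    return re.compile("".join(f"[{''.join(sorted(IUPAC_CODES[c]))}]" for c in m.consensus))


def scan_sequence(
    seq: str,
    m: DegenerateMotif,
    both_strands: bool = True,
    seqid: str = "",
    offset: int = 0,
) -> list[MotifHit]:
    """All (overlapping) motif matches in ``seq``, optionally on both strands.

    Reverse-strand hits are reported at the forward-strand coordinates of the
    matched window, with ``matched_seq`` being the forward-strand slice.
    ``offset`` shifts reported 1-based starts (for scanning sub-windows of a
    scaffold).  Hits are sorted by start, then '+' before '-'.
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    fwd = _motif_regex(m)
    pos = 0
    while (match := fwd.search(seq, pos)) is not None:
        hits.append(
            MotifHit(
                seqid=seqid,
                start=offset + match.start() + 1,
                strand="+",
                matched_seq=match.group(),
            )
        )
        pos = match.start() + 1
    if both_strands:
        rev = _motif_regex(DegenerateMotif(reverse_complement(m.consensus), m.label))
        pos = 0
        while (match := rev.search(seq, pos)) is not None:
            hits.append(
                MotifHit(
                    seqid=seqid,
                    start=offset + match.start() + 1,
                    strand="-",
                    matched_seq=match.group(),
                )
            )
            pos = match.start() + 1
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def central_enrichment_test(
    hits_per_window: Sequence[tuple[GenomicInterval, Sequence[int]]],
    cfg: CentralityConfig | None = None,
) -> tuple[int, int, float]:
    """Binomial test for concentration of hits near window centers.

    A hit position (its midpoint, 1-based) is "central" when it falls within
    the middle ``central_fraction`` of its window.  Under a uniform null the
    central count is Binomial(n_hits, central_fraction); the returned p-value
    is the one-sided upper tail.  Returns ``(n_hits, n_central, p)``; an
    empty hit list gives p = 1.0.
    """
    cfg = cfg or CentralityConfig()
    n_hits = 0
    n_central = 0
    for window, positions in hits_per_window:
        mid = (window.start + window.end) / 2.0
        half = len(window) * cfg.central_fraction / 2.0
        for pos in positions:
            if not (window.start <= pos <= window.end):
                raise ValueError(f"hit position {pos} outside window {window}")
            n_hits += 1
            if abs(pos - mid) <= half:
                n_central += 1
    if n_hits == 0:
        return 0, 0, 1.0
    p = float(stats.binom.sf(n_central - 1, n_hits, cfg.central_fraction))
    return n_hits, n_central, p


def write_hits_bed(hits: Iterable[MotifHit], path: str) -> None:
    """Write hits as BED6 (0-based half-open), matched sequence in the name."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.seqid}\t{h.start - 1}\t{h.end}\t{h.matched_seq}\t0\t{h.strand}\n"
            )
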