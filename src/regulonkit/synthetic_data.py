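"""Seeded synthetic study generator.

Produces a complete miniature input set — genome FASTA, gene models (GFF3),
per-replicate ChIP peaks (narrowPeak), a differential-expression table, a
metacell footprint matrix — plus a machine-readable truth record, so every
pipeline stage can be tested end-to-end without external downloads.

Design guarantees (at default parameters):

* peaks for bound genes are centered on a motif instance planted inside the
  gene territory, with p-values far below the confirmation thresholds;
* decoy peaks sit in intergenic space, never touch a territory, and carry
  p-values that fail the weak threshold;
* planted regulatory effects sit far from the significance boundary, so a
  correct pipeline recovers the planted truth exactly;
* all output derives from one seeded random stream, and a fixed seed yields
  byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from regulonkit.genome_intervals import (
    GeneModel,
    GenomicInterval,
    PromoterRule,
    gene_territory,
    overlaps,
)
from regulonkit.motif_scan import DegenerateMotif, expand_iupac, parse_consensus

__all__ = ["SimConfig", "TruthRecord", "simulate_study", "planted_motif_positions"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study; one seed drives every file."""

    seed: int = 0
    n_scaffolds: int = 4
    scaffold_length_bp: int = 200_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (500, 2000)
    n_replicates: int = 3
    n_true_bound_genes: int = 60
    frac_activated: float = 0.5
    frac_repressed: float = 0.25
    motif_consensus: str = "GCATWATTWAT"
    peak_width_range: tuple[int, int] = (200, 400)
    motif_plant_prob: float = 1.0
    summit_jitter_bp: int = 10
    n_decoy_peaks: int = 40
    n_metacells: int = 5
    n_exclusive_markers: int = 3
    n_unbound_de_genes: int = 10
    de_effect_log2fc_magnitude: float = 3.0
    de_null_padj_floor: float = 0.5
    promoter_rule: PromoterRule = field(default_factory=PromoterRule)
    # minimum intergenic gap; must exceed territory extension + peak reach
    # on both sides so peaks never straddle two territories
    min_intergenic_gap: int = 1500

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_activated <= 1.0 and 0.0 <= self.frac_repressed <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_activated + self.frac_repressed > 1.0:
            raise ValueError("frac_activated + frac_repressed must be <= 1")
        if self.n_true_bound_genes > self.n_genes:
            raise ValueError("n_true_bound_genes cannot exceed n_genes")
        if self.n_metacells < 2:
            raise ValueError("need >= 2 metacells (one activation- and one repression-skewed)")

    @property
    def motif(self) -> DegenerateMotif:
        return parse_consensus(self.motif_consensus)


@dataclass
class TruthRecord:
    """Planted ground truth of one synthetic study."""

    bound_genes: list[str]
    activated_genes: list[str]
    repressed_genes: list[str]
    tf_gene_id: str | None
    # metacell id -> {"activated": [...], "repressed": [...], "exclusive_markers": [...]}
    metacells: dict[str, dict[str, list[str]]]
    # (seqid, 1-based start, planted concrete sequence, gene_id)
    planted_motifs: list[tuple[str, int, str, str]]

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["planted_motifs"] = [list(t) for t in self.planted_motifs]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        payload["planted_motifs"] = [tuple(t) for t in payload["planted_motifs"]]
        return cls(**payload)


def planted_motif_positions(truth: TruthRecord) -> list[tuple[str, int, int, str]]:
    """Planted motifs as BED-convertible tuples (seqid, start, end, sequence),
    1-based inclusive."""
    return [
        (seqid, start, start + len(seq) - 1, seq)
        for seqid, start, seq, _gene in truth.planted_motifs
    ]


def _sample(rng: np.random.Generator, pool: Sequence[str], k: int) -> list[str]:
    if k <= 0 or len(pool) == 0:
        return []
    k = min(k, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Lay out non-overlapping genes left to right across scaffolds.

    The margin and gap sizes guarantee that territories (and any peak
    planted near a TSS) of neighbouring genes cannot touch.
    """
    margin = cfg.promoter_rule.upstream_bp + max(cfg.peak_width_range) + 100
    genes: list[GeneModel] = []
    scaffold = 1
    cursor = margin
    lo, hi = cfg.gene_length_range
    for i in range(cfg.n_genes):
        length = int(rng.integers(lo, hi + 1))
        gap = int(rng.integers(cfg.min_intergenic_gap, cfg.min_intergenic_gap + 1000))
        if cursor + length + margin > cfg.scaffold_length_bp:
            scaffold += 1
            cursor = margin
            if scaffold > cfg.n_scaffolds:
                raise ValueError(
                    "infeasible packing: genes do not fit the configured genome "
                    f"(placed {i} of {cfg.n_genes})"
                )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:04d}",
                span=GenomicInterval(f"scaffold_{scaffold}", cursor, cursor + length - 1),
                strand=strand,
            )
        )
        cursor += length + gap
    return genes


def simulate_study(cfg: SimConfig, out_dir: str | Path) -> TruthRecord:
    """Generate the full synthetic study under ``out_dir``.

    Writes genome.fa, genes.gff3, rep{i}.narrowPeak, de.tsv, metacells.tsv
    and truth.json; returns the TruthRecord.
    """
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)

    # --- plan everything in memory first (packing errors fire before any write)
    genes = _place_genes(cfg, rng)
    gene_by_id = {g.gene_id: g for g in genes}
    territories = {g.gene_id: gene_territory(g, cfg.promoter_rule) for g in genes}

    scaffolds = {
        f"scaffold_{i + 1}": rng.integers(0, 4, size=cfg.scaffold_length_bp)
        for i in range(cfg.n_scaffolds)
    }

    gene_ids = [g.gene_id for g in genes]
    bound = _sample(rng, gene_ids, cfg.n_true_bound_genes)
    n_act = int(round(cfg.frac_activated * len(bound)))
    n_rep = int(round(cfg.frac_repressed * len(bound)))
    activated = _sample(rng, bound, n_act)
    remaining = [g for g in bound if g not in set(activated)]
    repressed = _sample(rng, remaining, n_rep)
    tf_gene_id = repressed[0] if repressed else None

    expansions = sorted(expand_iupac(cfg.motif))
    motif_len = len(cfg.motif)

    planted: list[tuple[str, int, str, str]] = []
    # replicate id -> list of (interval, score, neglog10_p, summit_offset)
    rep_peaks: dict[str, list[tuple[GenomicInterval, float, float, int]]] = {
        f"rep{r + 1}": [] for r in range(cfg.n_replicates)
    }
    for gid in bound:
        gene = gene_by_id[gid]
        upstream_offset = int(rng.integers(50, 201))
        if gene.strand == "+":
            motif_mid = gene.tss - upstream_offset
        else:
            motif_mid = gene.tss + upstream_offset
        motif_start = motif_mid - motif_len // 2
        chosen = expansions[int(rng.integers(len(expansions)))]
        if rng.random() < cfg.motif_plant_prob:
            arr = scaffolds[gene.seqid]
            idx = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in chosen])
            arr[motif_start - 1 : motif_start - 1 + motif_len] = idx
            planted.append((gene.seqid, motif_start, chosen, gid))
        for rep_id in rep_peaks:
            width = int(rng.integers(*cfg.peak_width_range))
            jitter = int(rng.integers(-cfg.summit_jitter_bp, cfg.summit_jitter_bp + 1))
            center = motif_mid + jitter
            start = max(1, center - width // 2)
            end = min(cfg.scaffold_length_bp, start + width - 1)
            nlp = float(rng.uniform(10.0, 20.0))
            rep_peaks[rep_id].append(
                (GenomicInterval(gene.seqid, start, end), nlp * 10, nlp, center - start)
            )

    # decoys: intergenic, weak p-values -> never confirmed; they must touch
    # neither a territory nor a true peak (a weak member would sink the
    # whole consensus group)
    avoid = list(territories.values())
    avoid.extend(iv for peaks in rep_peaks.values() for iv, *_ in peaks)
    rep_ids = sorted(rep_peaks)
    for _ in range(cfg.n_decoy_peaks):
        for _attempt in range(1000):
            seqid = f"scaffold_{int(rng.integers(cfg.n_scaffolds)) + 1}"
            width = int(rng.integers(*cfg.peak_width_range))
            start = int(rng.integers(1, cfg.scaffold_length_bp - width))
            iv = GenomicInterval(seqid, start, start + width - 1)
            if not any(overlaps(iv, t) for t in avoid):
                break
        else:
            raise ValueError("infeasible packing: cannot place decoy peaks intergenically")
        nlp = float(rng.uniform(1.0, 3.5))  # p in [10^-3.5, 0.1] > weak threshold
        rep_id = rep_ids[int(rng.integers(len(rep_ids)))]
        rep_peaks[rep_id].append((iv, nlp * 10, nlp, width // 2))

    # --- differential expression table
    act_set, rep_set = set(activated), set(repressed)
    unbound = [g for g in gene_ids if g not in set(bound)]
    unbound_de = _sample(rng, unbound, cfg.n_unbound_de_genes)
    unbound_down = set(unbound_de[: len(unbound_de) // 2])
    unbound_up = set(unbound_de[len(unbound_de) // 2 :])
    de_rows: list[tuple[str, float, float]] = []
    for gid in gene_ids:
        if gid in act_set or gid in unbound_down:
            l2fc = -(cfg.de_effect_log2fc_magnitude + float(rng.uniform(0, 1)))
            padj = 10.0 ** float(rng.uniform(-8, -4))
        elif gid in rep_set or gid in unbound_up:
            l2fc = cfg.de_effect_log2fc_magnitude + float(rng.uniform(0, 1))
            padj = 10.0 ** float(rng.uniform(-8, -4))
        else:
            l2fc = float(rng.normal(0, 0.2))
            padj = float(rng.uniform(cfg.de_null_padj_floor, 1.0))
        de_rows.append((gid, l2fc, padj))

    # --- metacell footprint matrix with one activation- and one
    # repression-skewed metacell; exclusive markers live only in the former
    mc_ids = [f"mc{i + 1:02d}" for i in range(cfg.n_metacells)]
    act_skew, rep_skew = mc_ids[0], mc_ids[1]
    background = mc_ids[2:]
    exclusives = _sample(rng, activated, cfg.n_exclusive_markers)
    other_act = [g for g in activated if g not in set(exclusives)]

    represented: dict[str, set[str]] = {mc: set() for mc in mc_ids}
    mc_truth: dict[str, dict[str, list[str]]] = {}
    act_in_actskew = exclusives + _sample(rng, other_act, 9)
    rep_in_actskew = _sample(rng, repressed, 1)
    represented[act_skew] = set(act_in_actskew) | set(rep_in_actskew)
    rep_in_repskew = _sample(rng, repressed, 10)
    act_in_repskew = _sample(rng, other_act, 2)
    represented[rep_skew] = set(rep_in_repskew) | set(act_in_repskew)

    # every non-exclusive class gene used above must also appear elsewhere,
    # so the planted exclusives are exactly the exclusive markers
    shared = (represented[act_skew] | represented[rep_skew]) - set(exclusives)
    if background:
        for gid in sorted(shared):
            represented[background[int(rng.integers(len(background)))]].add(gid)
    else:
        for gid in sorted(shared - represented[rep_skew]):
            represented[rep_skew].add(gid)
        for gid in sorted(shared - represented[act_skew]):
            represented[act_skew].add(gid)
    non_class = [g for g in gene_ids if g not in act_set | rep_set]
    for mc in background:
        represented[mc] |= set(_sample(rng, non_class, 20))

    for mc in mc_ids:
        act_here = sorted(represented[mc] & act_set)
        rep_here = sorted(represented[mc] & rep_set)
        excl_here = sorted(
            g
            for g in represented[mc] & (act_set | rep_set)
            if not any(g in represented[o] for o in mc_ids if o != mc)
        )
        mc_truth[mc] = {
            "activated": act_here,
            "repressed": rep_here,
            "exclusive_markers": excl_here,
        }

    footprint = np.zeros((len(gene_ids), len(mc_ids)))
    for j, mc in enumerate(mc_ids):
        for gid in sorted(represented[mc]):
            footprint[gene_ids.index(gid), j] = float(rng.uniform(0.1, 1.0))

    # --- write everything
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_fasta(scaffolds, out_dir / "genome.fa")
    _write_gff3(genes, out_dir / "genes.gff3")
    for rep_id in rep_ids:
        _write_narrowpeak_rows(rep_peaks[rep_id], rep_id, out_dir / f"{rep_id}.narrowPeak")
    with open(out_dir / "de.tsv", "w") as fh:
        fh.write("gene_id\tlog2fc\tpadj\n")
        for gid, l2fc, padj in de_rows:
            fh.write(f"{gid}\t{l2fc:.6g}\t{padj:.6g}\n")
    with open(out_dir / "metacells.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(mc_ids) + "\n")
        for i, gid in enumerate(gene_ids):
            vals = "\t".join(f"{footprint[i, j]:.6g}" for j in range(len(mc_ids)))
            fh.write(f"{gid}\t{vals}\n")

    truth = TruthRecord(
        bound_genes=sorted(bound),
        activated_genes=sorted(activated),
        repressed_genes=sorted(repressed),
        tf_gene_id=tf_gene_id,
        metacells=mc_truth,
        planted_motifs=sorted(planted),
    )
    truth.to_json(out_dir / "truth.json")
    return truth


def _write_fasta(scaffolds: dict[str, np.ndarray], path: Path) -> None:
    with open(path, "w") as fh:
        for seqid in sorted(scaffolds):
            fh.write(f">{seqid}\n")
            seq = "".join(_BASES[scaffolds[seqid]])
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _write_gff3(genes: Sequence[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.seqid}\tregulonkit_sim\tgene\t{g.span.start}\t{g.span.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def _write_narrowpeak_rows(
    rows: Sequence[tuple[GenomicInterval, float, float, int]], rep_id: str, path: Path
) -> None:
    rows = sorted(rows, key=lambda r: (r[0].seqid, r[0].start, r[0].end))
    with open(path, "w") as fh:
        for i, (iv, score, nlp, summit) in enumerate(rows):
            fh.write(
                f"{iv.seqid}\t{iv.start - 1}\t{iv.end}\t{rep_id}_peak{i + 1}\t"
                f"{score:.6g}\t.\t{score / 10:.6g}\t{nlp:.6g}\t-1\t{summit}\n"
            )
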