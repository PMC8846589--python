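import numpy as np
import pytest

from regulonkit.genome_intervals import GenomicInterval
from regulonkit.motif_scan import (
    CentralityConfig,
    DegenerateMotif,
    central_enrichment_test,
    expand_iupac,
    parse_consensus,
    reverse_complement,
    scan_sequence,
)

from conftest import PROBE_WITH_MOTIF, PROBE_WITHOUT_MOTIF

CORE = parse_consensus("AT(A/T)ATT(A/T)AT")  # ATWATTWAT
EXTENDED = parse_consensus("GCAT(A/T)ATT(A/T)AT")  # GCATWATTWAT


def oracle_scan(seq, motif, both_strands=True):
    """Exhaustive window-matching oracle built on explicit expansion."""
    seq = seq.upper()
    expansions = expand_iupac(motif)
    w = len(motif)
    hits = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if window in expansions:
            hits.append((i + 1, "+"))
        if both_strands and reverse_complement(window) in expansions:
            hits.append((i + 1, "-"))
    return sorted(hits)


class TestParseConsensus:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("AT(A/T)ATT(A/T)AT", "ATWATTWAT"),
            ("GCAT(A/T)ATT(A/T)AT", "GCATWATTWAT"),
            ("AT(T/A)ATT(A/T)AT", "ATWATTWAT"),
            ("A(A/C)G", "AMG"),
            ("acgt", "ACGT"),
            ("NRYSWKMBDHV", "NRYSWKMBDHV"),
        ],
    )
    def test_normalization(self, text, expected):
        assert parse_consensus(text).consensus == expected

    @pytest.mark.parametrize("bad", ["AXT", "A(A/Z)T", "A(A/T", ""])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_consensus(bad)


class TestExpandIupac:
    def test_core_expansion(self):
        assert expand_iupac(CORE) == {"ATAATTAAT", "ATAATTTAT", "ATTATTAAT", "ATTATTTAT"}

    def test_extended_expansion_size(self):
        assert len(expand_iupac(EXTENDED)) == 4

    def test_no_degeneracy(self):
        assert expand_iupac(DegenerateMotif("ACGT")) == {"ACGT"}

    def test_core_nested_in_extended(self):
        # every core expansion is an extended expansion minus the GC prefix
        extended = expand_iupac(EXTENDED)
        for seq in expand_iupac(CORE):
            assert any(e[2:] == seq for e in extended)


class TestScanSequence:
    def test_probe_with_motif_single_hit(self):
        hits = scan_sequence(PROBE_WITH_MOTIF, CORE, both_strands=True)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand, hits[0].matched_seq) == (22, "+", "ATTATTAAT")
        assert oracle_scan(PROBE_WITH_MOTIF, CORE) == [(22, "+")]

    def test_probe_without_motif_no_hits(self):
        assert scan_sequence(PROBE_WITHOUT_MOTIF, CORE, both_strands=True) == []
        assert oracle_scan(PROBE_WITHOUT_MOTIF, CORE) == []

    def test_self_match(self):
        hits = scan_sequence("ATTATTAAT", CORE, both_strands=True)
        assert [(h.start, h.strand) for h in hits] == [(1, "+")]

    def test_overlapping_hits_all_reported(self):
        # AAAA contains three AA windows
        hits = scan_sequence("AAAA", DegenerateMotif("AA"), both_strands=False)
        assert [h.start for h in hits] == [1, 2, 3]

    def test_n_never_matches(self):
        assert scan_sequence("ATNATTAAT", CORE) == []
        assert scan_sequence("ANA", DegenerateMotif("ANA"), both_strands=False) == []

    def test_offset_shifts_coordinates(self):
        hits = scan_sequence("ATTATTAAT", CORE, seqid="s", offset=100)
        assert hits[0].start == 101

    @pytest.mark.parametrize("seed", range(100))
    def test_oracle_equivalence_random_2kb(self, seed):
        rng = np.random.default_rng(seed)
        # AT-rich alphabet so hits actually occur
        seq = "".join(rng.choice(list("AATTGC"), size=2000))
        got = [(h.start, h.strand) for h in scan_sequence(seq, CORE, both_strands=True)]
        assert sorted(got) == oracle_scan(seq, CORE)

    @pytest.mark.parametrize("seed", range(20))
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), p=[0.35, 0.15, 0.15, 0.35], size=1000))
        fwd = scan_sequence(seq, CORE, both_strands=True)
        rev = scan_sequence(reverse_complement(seq), CORE, both_strands=True)
        # reflect positions and swap strands
        L, w = len(seq), len(CORE)
        reflected = sorted(
            (L - h.start - w + 2, "+" if h.strand == "-" else "-") for h in rev
        )
        assert sorted((h.start, h.strand) for h in fwd) == reflected

    def test_matched_seq_invariant(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("AT"), size=500))
        for h in scan_sequence(seq, CORE, both_strands=True):
            window = seq[h.start - 1 : h.start + len(CORE) - 1]
            assert h.matched_seq == window
            probe = window if h.strand == "+" else reverse_complement(window)
            assert probe in expand_iupac(CORE)


class TestCentralEnrichment:
    def win(self, start=1, end=100):
        return GenomicInterval("s", start, end)

    def test_all_central(self):
        # 10 hits at the exact center of their windows
        data = [(self.win(), [50])] * 10
        n, k, p = central_enrichment_test(data, CentralityConfig(0.2))
        assert (n, k) == (10, 10)
        assert p == pytest.approx(0.2**10, rel=1e-9)

    def test_no_hits(self):
        assert central_enrichment_test([]) == (0, 0, 1.0)

    def test_one_of_five_central(self):
        data = [(self.win(), [50])] + [(self.win(), [5])] * 4
        n, k, p = central_enrichment_test(data, CentralityConfig(0.2))
        assert (n, k) == (5, 1)
        assert p == pytest.approx(1 - 0.8**5, rel=1e-9)  # 0.67232

    def test_position_outside_window_rejected(self):
        with pytest.raises(ValueError):
            central_enrichment_test([(self.win(), [101])])

    def test_super_uniform_under_null(self):
        # uniform hit placement: empirical rejection rate at 5% stays <= 7%
        rng = np.random.default_rng(2024)
        rejections = 0
        trials = 1000
        for _ in range(trials):
            windows = [
                (self.win(1, 200), rng.integers(1, 201, size=1).tolist())
                for _ in range(20)
            ]
            _, _, p = central_enrichment_test(windows, CentralityConfig(0.2))
            if p <= 0.05:
                rejections += 1
        assert rejections / trials <= 0.07
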