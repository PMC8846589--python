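import math
from itertools import combinations

import numpy as np
import pytest

from regulonkit.genome_intervals import GenomicInterval
from regulonkit.peak_consensus import (
    ConsensusConfig,
    Peak,
    build_consensus,
    fisher_combine,
    read_narrowpeak,
)


def mkpeak(seqid, start, end, p=1e-9, rep="rep1"):
    return Peak(
        interval=GenomicInterval(seqid, start, end),
        neglog10_p=-math.log10(p),
        replicate_id=rep,
    )


class TestReadNarrowpeak:
    def test_coordinate_conversion(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr1\t99\t200\tp1\t100\t.\t5.0\t6.0\t4.5\t50\n")
        (peak,) = read_narrowpeak(f)
        assert peak.interval == GenomicInterval("chr1", 100, 200)
        assert peak.neglog10_p == 6.0
        assert peak.summit_offset == 50
        assert peak.replicate_id == "a"

    def test_empty_file(self, tmp_path):
        f = tmp_path / "empty.narrowPeak"
        f.write_text("")
        assert read_narrowpeak(f) == []

    def test_end_not_after_start_errors_with_line_number(self, tmp_path):
        f = tmp_path / "bad.narrowPeak"
        f.write_text("chr1\t99\t200\tp\t0\t.\t0\t1\t-1\t-1\nchr1\t50\t50\tp\t0\t.\t0\t1\t-1\t-1\n")
        with pytest.raises(ValueError, match="line 2"):
            read_narrowpeak(f)

    def test_missing_optional_columns_default(self, tmp_path):
        f = tmp_path / "short.narrowPeak"
        f.write_text("chr1\t0\t10\n")
        (peak,) = read_narrowpeak(f)
        assert peak.score == 0.0
        assert peak.neglog10_p == 0.0
        assert peak.summit_offset == -1


class TestFisherCombine:
    def test_single_p_unchanged(self):
        assert fisher_combine([0.5]) == pytest.approx(0.5, rel=1e-12)

    def test_pair_closed_form(self):
        # X = -2(ln .1 + ln .1) = 9.21034; chi2_4 sf(x) = exp(-x/2)(1 + x/2)
        x = -2 * (math.log(0.1) + math.log(0.1))
        expected = math.exp(-x / 2) * (1 + x / 2)  # 0.05605170185988093
        assert fisher_combine([0.1, 0.1]) == pytest.approx(expected, rel=1e-12)

    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == 1.0

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            p = fisher_combine([0.0, 0.5])
        assert 0.0 <= p < 1e-100

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([])

    @pytest.mark.parametrize("k", [1, 2, 3, 5, 8])
    def test_matches_chi2_closed_form(self, k):
        # chi2 with 2k df has sf(x) = exp(-x/2) * sum_{j<k} (x/2)^j / j!
        rng = np.random.default_rng(k)
        ps = rng.uniform(0.001, 1.0, size=k)
        x = -2 * np.sum(np.log(ps))
        expected = math.exp(-x / 2) * sum((x / 2) ** j / math.factorial(j) for j in range(k))
        assert fisher_combine(ps) == pytest.approx(expected, rel=1e-12)


def brute_force_consensus(replicate_sets, cfg):
    """Independent oracle: exhaustive pairwise-overlap transitive closure,
    then the weak/strong/support rule, applied group by group."""
    peaks = [p for rep in replicate_sets for p in rep]
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        a, b = peaks[i].interval, peaks[j].interval
        if a.seqid == b.seqid and a.start <= b.end and b.start <= a.end:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(peaks[i])
    confirmed = []
    for members in groups.values():
        ps = [m.pvalue for m in members]
        if max(ps) > cfg.weak_threshold:
            continue
        if fisher_combine(ps) > cfg.strong_threshold:
            continue
        if len({m.replicate_id for m in members}) < cfg.min_supporting_replicates:
            continue
        confirmed.append(
            (
                members[0].interval.seqid,
                min(m.interval.start for m in members),
                max(m.interval.end for m in members),
                len(members),
            )
        )
    return sorted(confirmed)


class TestBuildConsensus:
    def test_singleton_strong_peak_confirmed(self):
        out = build_consensus([[mkpeak("s", 100, 200, p=1e-9)]])
        assert len(out) == 1
        assert out[0].interval == GenomicInterval("s", 100, 200)

    def test_pair_combined_passes_strong(self):
        # each 1e-5 > strong alone, combined 2.4e-9 <= 1e-8
        out = build_consensus(
            [[mkpeak("s", 100, 200, p=1e-5, rep="r1")], [mkpeak("s", 150, 250, p=1e-5, rep="r2")]]
        )
        assert len(out) == 1
        assert out[0].n_replicates_supporting == 2
        assert out[0].interval == GenomicInterval("s", 100, 250)

    def test_weak_member_sinks_group(self):
        out = build_consensus(
            [[mkpeak("s", 100, 200, p=1e-3, rep="r1")], [mkpeak("s", 150, 250, p=1e-12, rep="r2")]]
        )
        assert out == []

    def test_min_supporting_replicates(self):
        cfg = ConsensusConfig(min_supporting_replicates=2)
        out = build_consensus([[mkpeak("s", 100, 200, p=1e-9, rep="r1")], []], cfg)
        assert out == []

    def test_combined_p_below_strong_always(self):
        rng = np.random.default_rng(0)
        reps = [
            [
                mkpeak("s", int(s), int(s) + 50, p=10.0 ** -rng.uniform(2, 12), rep=f"r{r}")
                for s in rng.integers(1, 2000, size=8)
            ]
            for r in range(3)
        ]
        cfg = ConsensusConfig()
        for cp in build_consensus(reps, cfg):
            assert 10.0 ** -cp.combined_neglog10_p <= cfg.strong_threshold * (1 + 1e-9)

    def test_order_invariance(self):
        rng = np.random.default_rng(42)
        reps = [
            [
                mkpeak("s", int(s), int(s) + 80, p=10.0 ** -rng.uniform(4, 12), rep=f"r{r}")
                for s in rng.integers(1, 3000, size=10)
            ]
            for r in range(3)
        ]
        base = build_consensus(reps)
        shuffled = [list(reversed(rep)) for rep in reversed(reps)]
        assert build_consensus(shuffled) == base

    def test_identity_with_permissive_thresholds(self):
        cfg = ConsensusConfig(weak_threshold=1.0, strong_threshold=1.0)
        peaks = [mkpeak("s", 100, 200, p=0.9), mkpeak("s", 300, 400, p=0.5)]
        out = build_consensus([peaks], cfg)
        assert [cp.interval for cp in out] == [p.interval for p in peaks]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_reps = int(rng.integers(1, 4))
        reps = []
        for r in range(n_reps):
            n_peaks = int(rng.integers(0, 8))
            reps.append(
                [
                    mkpeak(
                        rng.choice(["sA", "sB"]),
                        int(s),
                        int(s) + int(rng.integers(20, 120)),
                        p=10.0 ** -rng.uniform(1, 14),
                        rep=f"r{r}",
                    )
                    for s in rng.integers(1, 600, size=n_peaks)
                ]
            )
        if not reps:
            return
        cfg = ConsensusConfig()
        got = sorted(
            (cp.interval.seqid, cp.interval.start, cp.interval.end, len(cp.member_peaks))
            for cp in build_consensus(reps, cfg)
        )
        assert got == brute_force_consensus(reps, cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        ConsensusConfig(weak_threshold=1e-8, strong_threshold=1e-4)
    with pytest.raises(ValueError):
        build_consensus([])
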