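"""Kmer stage: brute-force oracle equivalence, canonical closure, filter
semantics, and differential-call symmetry/null properties."""

from __future__ import annotations

import numpy as np
import pytest

import wgadiff as w
from wgadiff.kmers import canonical, read_unique_count
from wgadiff.simulate import revcomp


# ---------------------------------------------------------------- oracles

def brute_count(reads: list[str], k: int) -> dict[str, int]:
    """Five-line dictionary oracle over all windows."""
    counts: dict[str, int] = {}
    for seq in reads:
        for i in range(len(seq) - k + 1):
            win = seq[i:i + k]
            if set(win) <= set("ACGT"):
                key = min(win, revcomp(win))
                counts[key] = counts.get(key, 0) + 1
    return counts


def brute_unique(present: dict[str, int], absent: dict[str, int],
                 min_present: int, max_absent: int) -> set[str]:
    keys = set(present) | set(absent)
    return {k for k in keys
            if present.get(k, 0) >= min_present and absent.get(k, 0) <= max_absent}


def random_reads(rng, n_reads=20, length=50) -> list[str]:
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n_reads)]


# ------------------------------------------------------------ count_kmers

class TestCountKmers:
    def test_read_shorter_than_k_empty(self):
        assert w.count_kmers(["ACGT"], 5).counts == {}

    def test_hand_enumerated_windows(self):
        table = w.count_kmers(["ACGTA"], 4)
        # canon("ACGT") = "ACGT" (its own revcomp); canon("CGTA") = "CGTA"
        assert table.counts == {"ACGT": 1, "CGTA": 1}
        assert table.total_kmers == 2

    @pytest.mark.parametrize("k", [3, 15, 25])
    def test_matches_brute_force_oracle(self, k):
        rng = np.random.default_rng(500 + k)
        for _ in range(10):
            reads = random_reads(rng)
            assert w.count_kmers(reads, k).counts == brute_count(reads, k)

    def test_keys_are_canonical(self):
        rng = np.random.default_rng(7)
        table = w.count_kmers(random_reads(rng), 11)
        assert all(canonical(kmer) == kmer for kmer in table.counts)

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(8)
        reads = random_reads(rng)
        fwd = w.count_kmers(reads, 15)
        rev = w.count_kmers([revcomp(r) for r in reads], 15)
        assert fwd.counts == rev.counts

    def test_non_acgt_windows_skipped(self):
        table = w.count_kmers(["ACGNACG"], 3)
        assert table.counts == brute_count(["ACGNACG"], 3)
        assert "CGN" not in table.counts and canonical("GNA") not in table.counts

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            w.count_kmers(["ACGT"], 0)

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        table = w.count_kmers(random_reads(rng), 13)
        path = tmp_path / "kmers.tsv"
        table.to_tsv(path)
        assert w.KmerTable.from_tsv(path).counts == table.counts


# ----------------------------------------------------------- unique_kmers

class TestUniqueKmers:
    def test_identical_tables_yield_empty_set(self):
        rng = np.random.default_rng(10)
        t = w.count_kmers(random_reads(rng), 15)
        assert w.unique_kmers(t, t, w.FilterConfig(k=15)) == set()

    def test_well_supported_absent_kmer_is_unique(self):
        present = w.KmerTable(k=3, counts={"AAA": 5})
        absent = w.KmerTable(k=3, counts={})
        assert w.unique_kmers(present, absent, min_count_present=3) == {"AAA"}

    @pytest.mark.parametrize("k", [3, 15, 25])
    def test_matches_brute_force_oracle(self, k):
        rng = np.random.default_rng(600 + k)
        for _ in range(10):
            a = w.count_kmers(random_reads(rng), k)
            b = w.count_kmers(random_reads(rng), k)
            got = w.unique_kmers(a, b, min_count_present=2, max_count_absent=1)
            assert got == brute_unique(a.counts, b.counts, 2, 1)

    def test_mismatched_k_rejected(self):
        a = w.KmerTable(k=3, counts={})
        b = w.KmerTable(k=5, counts={})
        with pytest.raises(ValueError, match="mismatch"):
            w.unique_kmers(a, b, min_count_present=1)

    def test_monotone_in_min_count_present(self):
        rng = np.random.default_rng(11)
        a = w.count_kmers(random_reads(rng, n_reads=40), 15)
        b = w.count_kmers(random_reads(rng, n_reads=40), 15)
        sets = [w.unique_kmers(a, b, min_count_present=m) for m in (1, 2, 3, 5)]
        for lo, hi in zip(sets[1:], sets):
            assert lo <= hi


# ----------------------------------------------------------- filter_reads

def _as_reads(seqs):
    return [(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)]


class TestFilterReads:
    def test_empty_unique_set_retains_nothing(self):
        reads = _as_reads(["A" * 50, "C" * 50])
        kept, _, stats = w.filter_reads(reads, None, set(), w.FilterConfig())
        assert kept == [] and stats.n_retained == 0 and stats.n_discarded == 2

    def test_snv_spanning_read_retained(self, genome):
        # a read over a planted SNV carries up to k sample-unique kmers
        k = 25
        pos = 10_000
        ref_read = genome.sequence[pos - 50:pos + 50]
        alt_base = "A" if genome.sequence[pos] != "A" else "C"
        alt_read = ref_read[:50] + alt_base + ref_read[51:]
        assert alt_read != ref_read
        unique = {canonical(alt_read[i:i + k]) for i in range(50 - k + 1, 51)}
        assert len(unique) == k
        cfg = w.FilterConfig(k=k, min_unique_per_read=2)
        kept, _, _ = w.filter_reads(_as_reads([alt_read, ref_read]), None, unique, cfg)
        assert [r[1] for r in kept] == [alt_read]

    def test_retention_is_definitional(self):
        rng = np.random.default_rng(12)
        reads = _as_reads(random_reads(rng, n_reads=60, length=60))
        table = w.count_kmers([r[1] for r in reads], 15)
        unique = set(list(table.counts)[::3])
        cfg = w.FilterConfig(k=15, min_unique_per_read=2)
        kept, _, _ = w.filter_reads(reads, None, unique, cfg)
        kept_ids = {r[0] for r in kept}
        for rid, seq, _ in reads:
            n = read_unique_count(seq, unique, 15)
            assert (rid in kept_ids) == (n >= 2)

    def test_pair_policy_either_vs_both(self):
        cfg_e = w.FilterConfig(k=11, min_unique_per_read=1, pair_policy="either")
        cfg_b = w.FilterConfig(k=11, min_unique_per_read=1, pair_policy="both")
        hit = "ACGTACGTACG"
        r1 = _as_reads([hit + "A" * 20])
        r2 = _as_reads(["T" * 31])
        unique = {canonical(hit)}
        kept_e, _, _ = w.filter_reads(r1, r2, unique, cfg_e)
        kept_b, _, _ = w.filter_reads(r1, r2, unique, cfg_b)
        assert len(kept_e) == 1 and len(kept_b) == 0

    def test_unequal_mate_lists_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            w.filter_reads(_as_reads(["A" * 30]), [], set(), w.FilterConfig())

    def test_monotone_in_min_unique_per_read(self):
        rng = np.random.default_rng(13)
        reads = _as_reads(random_reads(rng, n_reads=60, length=60))
        table = w.count_kmers([r[1] for r in reads], 15)
        unique = set(list(table.counts)[::2])
        kept_sizes = []
        for m in (1, 2, 4, 8):
            cfg = w.FilterConfig(k=15, min_unique_per_read=m)
            kept, _, _ = w.filter_reads(reads, None, unique, cfg)
            kept_sizes.append(len(kept))
        assert kept_sizes == sorted(kept_sizes, reverse=True)


# ------------------------------------------------------ differential_call

class TestDifferentialCall:
    def test_identical_samples_null(self, clean_readset, reference):
        sample = (list(clean_readset.reads1)[:300], list(clean_readset.reads2)[:300])
        res = w.differential_call(sample, sample, reference,
                                  w.FilterConfig(), w.CallParams())
        assert res.n_unique_a == res.n_unique_b == 0
        assert res.stats_a.n_retained == res.stats_b.n_retained == 0
        assert res.calls_a == res.calls_b == ()

    def test_swapping_samples_swaps_outputs(self, diploid, whole_genome_kit, reference):
        haps, _ = diploid
        cfg = w.ReadSimConfig(depth=10.0, seed=21)
        a = w.simulate_reads(haps, whole_genome_kit, cfg)
        b = w.simulate_reads(haps, whole_genome_kit,
                             w.ReadSimConfig(depth=10.0, seed=22))
        sa = (list(a.reads1), list(a.reads2))
        sb = (list(b.reads1), list(b.reads2))
        fwd = w.differential_call(sa, sb, reference, w.FilterConfig(), w.CallParams())
        rev = w.differential_call(sb, sa, reference, w.FilterConfig(), w.CallParams())
        assert fwd.calls_a == rev.calls_b and fwd.calls_b == rev.calls_a

    def test_extra_variants_recovered_in_their_sample(self, genome, reference):
        # sample B carries 12 extra planted SNVs; they must surface as
        # B-specific calls and none as A-specific
        haps_a, _ = w.plant_variants(genome, 0, seed=31)
        haps_b, extra = w.plant_variants(genome, 12, het_fraction=0.0,
                                         min_spacing=500, seed=32)
        kit = w.CaptureKit(name="whole", targets=((genome.name, 0, genome.length),),
                           efficiency=1.0)
        cfg = w.ReadSimConfig(depth=30.0, base_error_rate=0.0, seed=33)
        ra = w.simulate_reads(haps_a, kit, cfg)
        rb = w.simulate_reads(haps_b, kit, w.ReadSimConfig(
            depth=30.0, base_error_rate=0.0, seed=34))
        res = w.differential_call((list(ra.reads1), list(ra.reads2)),
                                  (list(rb.reads1), list(rb.reads2)),
                                  reference, w.FilterConfig(), w.CallParams())
        b_keys = {c.key for c in res.calls_b if c.is_pass}
        recovered = len(b_keys & extra.keys())
        assert recovered >= 0.9 * len(extra.keys())
        assert len(res.calls_a) == 0
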