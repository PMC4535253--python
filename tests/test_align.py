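"""Aligner, pileup, genotyper, and hard filter against independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

import wgadiff as w
from wgadiff.align import PileupColumn, align_reads
from wgadiff.simulate import revcomp
from wgadiff import io as wio


@pytest.fixture(scope="module")
def small_ref():
    g = w.simulate_genome(5_000, 0.5, seed=201)
    return {g.name: g.sequence}


@pytest.fixture(scope="module")
def index(small_ref):
    return w.build_index(small_ref, seed_k=15)


def brute_align(seq: str, reference: dict[str, str]):
    """Exhaustive Hamming scan of both strands; returns (nm, contig, pos,
    strand) of the best placement (lowest (contig, pos) on ties)."""
    best = None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        for contig in sorted(reference):
            ref = np.frombuffer(reference[contig].encode(), dtype=np.uint8)
            for pos in range(len(ref) - len(s) + 1):
                nm = int(np.count_nonzero(ref[pos:pos + len(s)] != arr))
                cand = (nm, contig, pos, strand)
                if best is None or cand[:3] < best[:3]:
                    best = cand
    return best


class TestBuildIndex:
    def test_reference_kmers_found_at_true_positions(self, small_ref, index):
        seq = small_ref["chr1"]
        rng = np.random.default_rng(1)
        for pos in rng.integers(0, len(seq) - 15, 30):
            assert ("chr1", int(pos)) in index.table[seq[pos:pos + 15]]

    def test_absent_seed_has_no_hits(self, small_ref, index):
        absent = "N" * 15  # never occurs in an ACGT reference
        assert index.table.get(absent, []) == []

    def test_rebuild_identical(self, small_ref):
        a = w.build_index(small_ref, 15)
        b = w.build_index(small_ref, 15)
        assert a.table == b.table

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            w.build_index({}, 15)


class TestAlignRead:
    def test_exact_copy_maps_to_origin(self, small_ref, index):
        seq = small_ref["chr1"][1_000:1_100]
        rec = w.align_read("r", seq, index)
        assert (rec.aligned, rec.contig, rec.position, rec.strand,
                rec.n_mismatch, rec.mapq_proxy) == (True, "chr1", 1_000, "+", 0, 60)

    def test_reverse_complement_copy_maps_reverse(self, small_ref, index):
        seq = revcomp(small_ref["chr1"][2_000:2_100])
        rec = w.align_read("r", seq, index)
        assert (rec.contig, rec.position, rec.strand) == ("chr1", 2_000, "-")
        assert rec.seq == small_ref["chr1"][2_000:2_100]

    def test_two_copy_repeat_gives_mapq_zero(self):
        core = w.simulate_genome(3_000, 0.5, seed=202).sequence
        repeat = core[:200]
        ref = {"chr1": core + repeat + core[200:400] + repeat}
        idx = w.build_index(ref, 15)
        rec = w.align_read("r", repeat[:100], idx)
        assert rec.mapq_proxy == 0 and rec.n_mismatch == 0

    @pytest.mark.parametrize("n_subs", [1, 2, 3])
    def test_substituted_reads_match_brute_force(self, small_ref, index, n_subs):
        rng = np.random.default_rng(300 + n_subs)
        seq = small_ref["chr1"]
        for _ in range(5):
            pos = int(rng.integers(0, len(seq) - 100))
            read = list(seq[pos:pos + 100])
            for i in rng.choice(100, n_subs, replace=False):
                read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
            read = "".join(read)
            rec = w.align_read("r", read, index, max_mismatch=4)
            nm, contig, bpos, strand = brute_align(read, small_ref)
            assert rec.aligned
            assert (rec.n_mismatch, rec.contig, rec.position) == (nm, contig, bpos)

    def test_unalignable_read_returns_unaligned(self, index):
        rec = w.align_read("r", "ACGT" * 25, index, max_mismatch=4)
        assert not rec.aligned


class TestMakePileup:
    def test_single_clean_read_depth_one(self, small_ref, index):
        seq = small_ref["chr1"][100:200]
        rec = w.align_read("r", seq, index)
        pile = w.make_pileup([rec], small_ref, min_mapq=20)
        d = pile.depth_array("chr1")
        assert d[100:200].tolist() == [1] * 100
        assert d.sum() == 100
        col = pile.column("chr1", 151)
        assert col.base_counts[small_ref["chr1"][150]] == 1 and col.depth == 1

    def test_overlapping_reads_sum(self, small_ref, index):
        r1 = w.align_read("a", small_ref["chr1"][100:200], index)
        r2 = w.align_read("b", small_ref["chr1"][150:250], index)
        d = w.make_pileup([r1, r2], small_ref).depth_array("chr1")
        assert d[150:200].tolist() == [2] * 50
        assert d[100:150].tolist() == [1] * 50

    def test_depth_equals_interval_arithmetic_oracle(self, small_ref, index):
        rng = np.random.default_rng(17)
        seq = small_ref["chr1"]
        recs = []
        for _ in range(50):
            pos = int(rng.integers(0, len(seq) - 100))
            s = seq[pos:pos + 100]
            recs.append(w.align_read(f"r{pos}", s if rng.random() < 0.5
                                     else revcomp(s), index))
        pile = w.make_pileup(recs, small_ref, min_mapq=20)
        oracle = np.zeros(len(seq), dtype=int)
        for r in recs:
            if r.aligned and r.mapq_proxy >= 20:
                oracle[r.position:r.end] += 1
        assert np.array_equal(pile.depth_array("chr1"), oracle)

    def test_reverse_strand_bases_land_correctly(self, small_ref, index):
        seq = revcomp(small_ref["chr1"][300:400])
        rec = w.align_read("r", seq, index)
        pile = w.make_pileup([rec], small_ref)
        col = pile.column("chr1", 301)
        assert col.base_counts[small_ref["chr1"][300]] == 1
        assert col.base_counts_rev[small_ref["chr1"][300]] == 1

    def test_out_of_bounds_alignment_rejected(self, small_ref):
        bad = w.AlignmentRecord("r", "chr1", 4_950, "+", 0, 60, True, "A" * 100, 100)
        with pytest.raises(ValueError, match="beyond contig end"):
            w.make_pileup([bad], small_ref)


def _col(ref, counts, fwd=None, rev=None):
    fwd = fwd or {b: counts.get(b, 0) // 2 for b in "ACGT"}
    rev = rev or {b: counts.get(b, 0) - fwd[b] for b in "ACGT"}
    full = {b: counts.get(b, 0) for b in "ACGT"}
    return PileupColumn("chr1", 100, ref, full, fwd, rev)


def diploid_loglik(n_ref, n_alt, genotype, e):
    """Independent evaluation of the per-read binomial error model."""
    p_ref = {"RR": 1 - e, "RA": 0.5 * (1 - e) + 0.5 * e / 3, "AA": e / 3}[genotype]
    p_alt = {"RR": e / 3, "RA": 0.5 * (1 - e) + 0.5 * e / 3, "AA": 1 - e}[genotype]
    return n_ref * math.log(p_ref) + n_alt * math.log(p_alt)


class TestGenotypeSite:
    def test_all_ref_no_call(self):
        assert w.genotype_site(_col("A", {"A": 10}), 0.01) is None

    def test_balanced_het_called(self):
        call = w.genotype_site(_col("A", {"A": 5, "G": 5}), 0.01)
        assert call is not None and call.genotype == "0/1"
        # the winning likelihood must dominate both homozygous models
        ll_ra = diploid_loglik(5, 5, "RA", 0.01)
        assert ll_ra > diploid_loglik(5, 5, "RR", 0.01)
        assert ll_ra > diploid_loglik(5, 5, "AA", 0.01)

    def test_hom_alt_high_confidence(self):
        call = w.genotype_site(_col("A", {"C": 12}), 0.01)
        assert call.genotype == "1/1" and call.qual > 30
        assert call.alt == "C" and call.depth == 12

    def test_posterior_matches_direct_evaluation(self):
        e, n_ref, n_alt = 0.01, 7, 3
        call = w.genotype_site(_col("A", {"A": n_ref, "T": n_alt}), e)
        lls = [diploid_loglik(n_ref, n_alt, g, e) for g in ("RR", "RA", "AA")]
        mx = max(lls)
        posts = [math.exp(v - mx) for v in lls]
        posts = [p / sum(posts) for p in posts]
        expected_qual = -10 * math.log10(1 - posts[1])
        assert call.genotype == "0/1"
        assert call.qual == pytest.approx(expected_qual, rel=1e-6)

    def test_zero_depth_no_call(self):
        assert w.genotype_site(_col("A", {}), 0.01) is None

    def test_alt_tie_broken_to_smallest_base(self):
        call = w.genotype_site(_col("A", {"A": 2, "C": 4, "T": 4}), 0.01)
        assert call.alt == "C"


class TestHardFilter:
    def _call(self, **kw):
        base = dict(contig="chr1", pos=10, ref="A", alt="G", genotype="0/1",
                    qual=50.0, depth=20, alt_depth=10, alt_fwd=5, alt_rev=5)
        base.update(kw)
        return w.VariantCall(**base)

    def test_clean_call_passes(self):
        out = w.hard_filter([self._call()], w.HardFilterParams(), mean_depth=25)
        assert out[0].is_pass

    def test_low_depth_flagged(self):
        out = w.hard_filter([self._call(depth=2, alt_depth=1, alt_fwd=1, alt_rev=0,
                                        qual=40.0)],
                            w.HardFilterParams(), mean_depth=25)
        assert "LowDepth" in out[0].filters

    def test_annotation_never_alters_call_content(self):
        c = self._call(qual=5.0, depth=1, alt_depth=1, alt_fwd=1, alt_rev=0)
        out = w.hard_filter([c], w.HardFilterParams(), mean_depth=25)[0]
        assert (out.pos, out.genotype, out.alt) == (c.pos, c.genotype, c.alt)
        assert not out.is_pass

    def test_random_calls_match_brute_force_predicates(self):
        rng = np.random.default_rng(23)
        params = w.HardFilterParams()
        mean_depth = 25.0
        calls = []
        for i in range(1000):
            depth = int(rng.integers(1, 150))
            alt = int(rng.integers(1, depth + 1))
            fwd = int(rng.integers(0, alt + 1))
            calls.append(self._call(pos=i + 1, qual=float(rng.uniform(0, 80)),
                                    depth=depth, alt_depth=alt, alt_fwd=fwd,
                                    alt_rev=alt - fwd))
        out = w.hard_filter(calls, params, mean_depth)
        for c, o in zip(calls, out):
            expected = set()
            if c.qual < 30:
                expected.add("LowQual")
            if c.depth < 4:
                expected.add("LowDepth")
            if c.depth > 4 * mean_depth:
                expected.add("HighDepth")
            if c.alt_depth / c.depth < 0.2:
                expected.add("LowAltFraction")
            if max(c.alt_fwd, c.alt_rev) / c.alt_depth > 0.95:
                expected.add("StrandBias")
            assert set(o.filters) == expected


class TestCallPipeline:
    def test_clean_recovery_on_fixture(self, clean_callresult, diploid):
        _, truth = diploid
        passes = [c for c in clean_callresult.calls if c.is_pass]
        ev = w.evaluate_against_truth(passes, truth)
        assert ev.sensitivity >= 0.95 and ev.precision >= 0.95

    def test_zero_reads_gives_valid_empty_vcf(self, reference, tmp_path):
        res = w.call_pipeline([], [], reference)
        assert res.calls == [] and res.mean_depth == 0.0
        path = tmp_path / "empty.vcf"
        wio.write_vcf(path, res.calls, {c: len(s) for c, s in reference.items()})
        assert wio.read_vcf(path) == []

    def test_same_inputs_byte_identical_vcf(self, clean_readset, reference, tmp_path):
        lengths = {c: len(s) for c, s in reference.items()}
        blobs = []
        for tag in ("a", "b"):
            res = w.call_pipeline(list(clean_readset.reads1)[:500],
                                  list(clean_readset.reads2)[:500], reference)
            p = tmp_path / f"{tag}.vcf"
            wio.write_vcf(p, res.calls, lengths)
            blobs.append(p.read_bytes())
        assert blobs[0] == blobs[1]

    def test_calls_invariant_to_read_order(self, clean_readset, reference):
        r1 = list(clean_readset.reads1)[:400]
        r2 = list(clean_readset.reads2)[:400]
        fwd = w.call_pipeline(r1, r2, reference)
        rev = w.call_pipeline(r1[::-1], r2[::-1], reference)
        assert fwd.calls == rev.calls
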