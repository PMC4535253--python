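"""Minimal map-first SNV detection: seed-and-extend ungapped alignment,
pileup, diploid genotyping, and hard filtering.

The aligner proposes candidate placements from exact seed hits taken at a
fixed stride along the read (both orientations), scores each candidate by
ungapped Hamming distance, and keeps the best.  A mapping-quality proxy on
the conventional 0-60 scale encodes placement confidence: 60 for a unique
best placement, 0 for a tie, and an intermediate value scaled by the
mismatch margin otherwise.  Reads spanning simulated chimera junctions
align poorly or with clustered mismatches — exactly the artifact class the
downstream concordance analysis studies.

The genotyper evaluates diploid likelihoods {RR, RA, AA} per pileup column
under a symmetric per-base error model with a flat prior; hard filtering
annotates (never deletes) calls that fail fixed quality/depth/allele-balance
/strand predicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from wgadiff import io as wio
from wgadiff.simulate import revcomp, _ENC, BASES
from wgadiff.variants import VariantCall


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    contig: str
    position: int          # 0-based leftmost reference offset
    strand: str            # "+" or "-"
    n_mismatch: int
    mapq_proxy: int        # 0-60
    aligned: bool
    seq: str               # read sequence in reference-forward orientation
    length: int

    @property
    def end(self) -> int:
        return self.position + self.length


@dataclass(frozen=True)
class PileupColumn:
    contig: str
    position: int          # 1-based
    ref_base: str
    base_counts: dict[str, int]
    base_counts_fwd: dict[str, int]
    base_counts_rev: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


@dataclass(frozen=True)
class HardFilterParams:
    """Fixed-threshold post-call filter (a hard-filter analog; annotates,
    never deletes)."""

    min_qual: float = 30.0
    min_depth: int = 4
    max_depth_factor: float = 4.0      # multiple of mean depth
    min_alt_fraction: float = 0.2
    strand_bias_max: float = 0.95      # max share of alt reads on one strand

    def __post_init__(self):
        for name in ("min_qual", "min_depth", "max_depth_factor",
                     "min_alt_fraction", "strand_bias_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CallParams:
    """Parameters of the full map-and-call stage."""

    seed_k: int = 15
    max_mismatch: int = 4
    min_mapq: int = 20
    genotyping_error: float = 0.01
    hard_filter: HardFilterParams = field(default_factory=HardFilterParams)


@dataclass
class SeedIndex:
    seed_k: int
    table: dict[str, list[tuple[str, int]]]
    contigs: dict[str, np.ndarray]     # uint8-encoded sequences
    contig_seqs: dict[str, str]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contig_seqs.items()}


@dataclass
class Pileup:
    """Per-contig strand-resolved base tallies."""

    fwd: dict[str, np.ndarray]         # shape (4, contig length)
    rev: dict[str, np.ndarray]
    contig_seqs: dict[str, str]

    def depth_array(self, contig: str) -> np.ndarray:
        return self.fwd[contig].sum(axis=0) + self.rev[contig].sum(axis=0)

    def depth_arrays(self) -> dict[str, np.ndarray]:
        return {c: self.depth_array(c) for c in self.fwd}

    def column(self, contig: str, position: int) -> PileupColumn:
        """Column at a 1-based position."""
        i = position - 1
        f = self.fwd[contig][:, i]
        r = self.rev[contig][:, i]
        return PileupColumn(
            contig=contig, position=position,
            ref_base=self.contig_seqs[contig][i],
            base_counts={b: int(f[j] + r[j]) for j, b in enumerate(BASES)},
            base_counts_fwd={b: int(f[j]) for j, b in enumerate(BASES)},
            base_counts_rev={b: int(r[j]) for j, b in enumerate(BASES)},
        )


@dataclass
class CallResult:
    calls: list[VariantCall]
    alignments: list[AlignmentRecord]
    depth: dict[str, np.ndarray]
    mean_depth: float


# ------------------------------------------------------------- operations

def build_index(reference: dict[str, str], seed_k: int = 15) -> SeedIndex:
    """Exact-lookup index from every reference seed_k-mer (forward strand)
    to its positions; reads are queried in both orientations."""
    if not reference or all(len(s) == 0 for s in reference.values()):
        raise ValueError("empty reference")
    table: dict[str, list[tuple[str, int]]] = {}
    contigs = {}
    for name, seq in reference.items():
        seq = seq.upper()
        contigs[name] = np.frombuffer(seq.encode(), dtype=np.uint8)
        for i in range(len(seq) - seed_k + 1):
            table.setdefault(seq[i:i + seed_k], []).append((name, i))
    return SeedIndex(seed_k=seed_k, table=table, contigs=contigs,
                     contig_seqs={n: s.upper() for n, s in reference.items()})


def align_read(read_id: str, seq: str, index: SeedIndex,
               max_mismatch: int = 4) -> AlignmentRecord:
    """Seed-and-extend ungapped placement of one read.

    Seeds at stride len//4 (plus an end-anchored seed) in both orientations
    propose candidates; the candidate with the fewest mismatches wins, ties
    broken to the lowest (contig, position) with mapq 0.  Unalignable reads
    return ``aligned=False``.
    """
    seq = seq.upper()
    L = len(seq)
    k = index.seed_k
    if L < k:
        return AlignmentRecord(read_id, "", -1, "+", -1, 0, False, seq, L)
    stride = max(1, L // 4)
    offsets = list(range(0, L - k + 1, stride))
    if offsets[-1] != L - k:
        offsets.append(L - k)

    candidates: dict[tuple[str, int, str], None] = {}
    oriented = {"+": seq, "-": revcomp(seq)}
    for strand, s in oriented.items():
        for off in offsets:
            for contig, pos in index.table.get(s[off:off + k], ()):
                cand = pos - off
                if 0 <= cand <= len(index.contigs[contig]) - L:
                    candidates[(contig, cand, strand)] = None
    if not candidates:
        return AlignmentRecord(read_id, "", -1, "+", -1, 0, False, seq, L)

    arrs = {st: np.frombuffer(s.encode(), dtype=np.uint8)
            for st, s in oriented.items()}
    scored = []
    for contig, pos, strand in candidates:
        ref_arr = index.contigs[contig]
        nm = int(np.count_nonzero(ref_arr[pos:pos + L] != arrs[strand]))
        scored.append((nm, contig, pos, strand))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    best_nm, contig, pos, strand = scored[0]
    if len(scored) == 1:
        mapq = 60
    else:
        margin = scored[1][0] - best_nm
        mapq = 0 if margin == 0 else min(60, 6 * margin)
    aligned = best_nm <= max_mismatch
    return AlignmentRecord(
        read_id=read_id, contig=contig if aligned else "",
        position=pos if aligned else -1, strand=strand,
        n_mismatch=best_nm, mapq_proxy=mapq if aligned else 0,
        aligned=aligned, seq=oriented[strand], length=L,
    )


def align_reads(reads, index: SeedIndex, max_mismatch: int = 4,
                ) -> list[AlignmentRecord]:
    """Align an iterable of (name, seq, qual) reads, mates independently."""
    return [align_read(name, seq, index, max_mismatch) for name, seq, _ in reads]


def make_pileup(alignments, reference: dict[str, str],
                min_mapq: int = 20) -> Pileup:
    """Strand-resolved base tallies from alignments with mapq >= min_mapq.

    Reverse-strand reads were stored reference-forward at alignment time, so
    their bases land at the correct offsets directly.
    """
    ref = {n: s.upper() for n, s in reference.items()}
    fwd = {n: np.zeros((4, len(s)), dtype=np.int32) for n, s in ref.items()}
    rev = {n: np.zeros((4, len(s)), dtype=np.int32) for n, s in ref.items()}
    for a in alignments:
        if not a.aligned or a.mapq_proxy < min_mapq:
            continue
        clen = len(ref[a.contig])
        if a.position + a.length > clen:
            raise ValueError(
                f"alignment beyond contig end: {a.read_id} at "
                f"{a.contig}:{a.position}+{a.length} > {clen}"
            )
        enc = _ENC[np.frombuffer(a.seq.encode(), dtype=np.uint8)]
        ok = enc < 4
        positions = np.arange(a.position, a.position + a.length)[ok]
        target = fwd if a.strand == "+" else rev
        np.add.at(target[a.contig], (enc[ok], positions), 1)
    return Pileup(fwd=fwd, rev=rev, contig_seqs=ref)


def _genotype_from_counts(ref_base: str, counts: dict[str, int],
                          fwd: dict[str, int], rev: dict[str, int],
                          contig: str, position: int, error_rate: float,
                          ) -> VariantCall | None:
    depth = sum(counts.values())
    if depth == 0 or ref_base not in BASES:
        return None
    e = error_rate
    non_ref = [(counts[b], b) for b in BASES if b != ref_base]
    alt_count = max(c for c, _ in non_ref)
    alt = min(b for c, b in non_ref if c == alt_count)  # tie -> smallest base
    if alt_count == 0:
        return None

    def p_base(b: str, genotype: tuple[str, str]) -> float:
        return sum((1 - e) if b == g else e / 3 for g in genotype) / 2

    lls = []
    for genotype in ((ref_base, ref_base), (ref_base, alt), (alt, alt)):
        ll = 0.0
        for b in BASES:
            n = counts[b]
            if n:
                ll += n * math.log(p_base(b, genotype))
        lls.append(ll)
    lls = np.array(lls)
    post = np.exp(lls - logsumexp(lls))
    best_g = int(np.argmax(post))
    if best_g == 0:
        return None
    qual = float(np.clip(-10 * math.log10(max(1 - post[best_g], 1e-12)), 0, 120))
    return VariantCall(
        contig=contig, pos=position, ref=ref_base, alt=alt,
        genotype="0/1" if best_g == 1 else "1/1",
        qual=qual, depth=depth, gq=int(min(99, round(qual))),
        alt_depth=alt_count, alt_fwd=fwd[alt], alt_rev=rev[alt],
    )


def genotype_site(column: PileupColumn, error_rate: float = 0.01,
                  ) -> VariantCall | None:
    """Diploid max-posterior genotype for one pileup column.

    Per-read base likelihoods: P(b|RR) = 1-e for the ref base and e/3
    otherwise; P(b|RA) = (P(b|R)+P(b|A))/2; AA symmetric.  Flat prior over
    {RR, RA, AA}; qual is the phred of 1 - posterior of the winning
    genotype.  Returns None (no-call) at zero depth or when RR wins.
    """
    if column.depth == 0:
        return None
    return _genotype_from_counts(
        column.ref_base, column.base_counts, column.base_counts_fwd,
        column.base_counts_rev, column.contig, column.position, error_rate,
    )


def hard_filter(calls, params: HardFilterParams, mean_depth: float,
                ) -> list[VariantCall]:
    """Annotate each call with every failed predicate; PASS iff none fail.

    Calls are annotated, never deleted; positions and genotypes are
    untouched.
    """
    out = []
    for c in calls:
        failed = []
        if c.qual < params.min_qual:
            failed.append("LowQual")
        if c.depth < params.min_depth:
            failed.append("LowDepth")
        if mean_depth > 0 and c.depth > params.max_depth_factor * mean_depth:
            failed.append("HighDepth")
        if c.depth > 0 and c.alt_depth / c.depth < params.min_alt_fraction:
            failed.append("LowAltFraction")
        if c.alt_depth > 0 and max(c.alt_fwd, c.alt_rev) / c.alt_depth > params.strand_bias_max:
            failed.append("StrandBias")
        out.append(c.with_filters(tuple(failed)))
    return out


def call_pipeline(reads1, reads2, reference: dict[str, str],
                  params: CallParams | None = None) -> CallResult:
    """Align -> pileup -> genotype -> hard-filter.

    ``reads1``/``reads2`` are lists of (name, seq, qual) (reads2 may be None
    or empty for single-end input) or FASTQ paths.  Returns every call,
    annotated; consumers select PASS calls as needed.
    """
    params = params or CallParams()
    if isinstance(reads1, (str, Path)):
        if reads2 is not None:
            reads1, reads2 = wio.read_fastq_pair(reads1, reads2)
        else:
            reads1 = wio.read_fastq(reads1)

    try:
        index = build_index(reference, params.seed_k)
    except Exception as exc:
        raise RuntimeError(f"call_pipeline [index stage]: {exc}") from exc
    all_reads = list(reads1) + (list(reads2) if reads2 else [])
    try:
        alignments = align_reads(all_reads, index, params.max_mismatch)
    except Exception as exc:
        raise RuntimeError(f"call_pipeline [alignment stage]: {exc}") from exc
    try:
        pileup = make_pileup(alignments, reference, params.min_mapq)
    except Exception as exc:
        raise RuntimeError(f"call_pipeline [pileup stage]: {exc}") from exc

    depth = pileup.depth_arrays()
    covered = np.concatenate([d[d > 0] for d in depth.values()]) \
        if any((d > 0).any() for d in depth.values()) else np.array([])
    mean_depth = float(covered.mean()) if covered.size else 0.0

    calls: list[VariantCall] = []
    for contig in sorted(reference):
        ref_enc = _ENC[np.frombuffer(reference[contig].upper().encode(),
                                     dtype=np.uint8)]
        totals = pileup.fwd[contig] + pileup.rev[contig]
        d = totals.sum(axis=0)
        ref_counts = np.where(ref_enc < 4, totals[np.minimum(ref_enc, 3),
                                                  np.arange(len(ref_enc))], 0)
        candidate = np.flatnonzero((d > 0) & (d - ref_counts > 0))
        for i in candidate:
            col = pileup.column(contig, int(i) + 1)
            call = genotype_site(col, params.genotyping_error)
            if call is not None:
                calls.append(call)
    calls = hard_filter(calls, params.hard_filter, mean_depth)
    calls.sort(key=lambda c: (c.contig, c.pos, c.alt))
    return CallResult(calls=calls, alignments=alignments,
                      depth=depth, mean_depth=mean_depth)
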