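"""Reference-free kmer differential read filtering.

The stage works in three steps, each exposed as its own operation:

1. ``count_kmers``  — canonical kmer counts per sample's read set.
2. ``unique_kmers`` — kmers well-supported in one sample and (near-)absent
   from the other; the support threshold screens out singleton
   sequencing-error kmers.
3. ``filter_reads`` — keep only reads carrying enough sample-unique kmers;
   everything that does not differ between the samples is discarded before
   alignment, so mapping errors shared by both libraries cannot masquerade
   as sample-specific variants.

``differential_call`` chains the three steps in both directions and re-calls
variants on the filtered reads with the ordinary map-and-call stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from wgadiff import io as wio
from wgadiff.simulate import revcomp

_ACGT = frozenset("ACGT")


def canonical(kmer: str) -> str:
    """Lexicographic min of a kmer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class KmerTable:
    """Canonical kmer -> count map for one sample's reads."""

    k: int
    counts: dict[str, int]

    @property
    def total_kmers(self) -> int:
        return sum(self.counts.values())

    def get(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    def to_tsv(self, path) -> None:
        """Dump as lexicographically sorted ``kmer\\tcount`` TSV (bit-exact)."""
        with open(path, "w") as fh:
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def from_tsv(cls, path, k: int | None = None) -> "KmerTable":
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                kmer, n = line.rstrip("\n").split("\t")
                counts[kmer] = int(n)
        if k is None:
            if not counts:
                raise ValueError("cannot infer k from an empty table")
            k = len(next(iter(counts)))
        return cls(k=k, counts=counts)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the differential filter.

    min_count_present  a unique kmer must be seen this often in the
                       possessing sample (screens out sequencing errors)
    max_count_absent   highest tolerated count in the other sample
    min_unique_per_read  kmer windows in the unique set needed to keep a read
    pair_policy        'either' keeps both mates if either passes, 'both'
                       requires both, 'single-end' treats reads singly
    """

    k: int = 25
    min_count_present: int = 3
    max_count_absent: int = 0
    min_unique_per_read: int = 2
    pair_policy: str = "either"

    def __post_init__(self):
        if not (11 <= self.k <= 31 and self.k % 2 == 1):
            raise ValueError("k must be odd and in [11, 31]")
        if self.min_count_present < 1:
            raise ValueError("min_count_present must be >= 1")
        if self.min_unique_per_read < 1:
            raise ValueError("min_unique_per_read must be >= 1")
        if self.pair_policy not in ("either", "both", "single-end"):
            raise ValueError("pair_policy must be either|both|single-end")


@dataclass(frozen=True)
class FilterStats:
    n_input: int
    n_retained: int

    @property
    def n_discarded(self) -> int:
        return self.n_input - self.n_retained


def _iter_seqs(source) -> Iterable[str]:
    """Yield sequences from: an iterable of strings, (name, seq, qual)
    tuples, or FASTQ path(s)."""
    if isinstance(source, (str, Path)):
        for _, seq, _ in wio.read_fastq(source):
            yield seq
        return
    for item in source:
        if isinstance(item, str) and not _looks_like_path(item):
            yield item
        elif isinstance(item, (str, Path)):
            for _, seq, _ in wio.read_fastq(item):
                yield seq
        else:
            yield item[1]


def _looks_like_path(s: str) -> bool:
    return s.endswith((".fastq", ".fq", ".fastq.gz", ".fq.gz"))


def read_unique_count(seq: str, unique: set[str], k: int) -> int:
    """Number of length-k windows of ``seq`` whose canonical form is in the
    unique set (windows with non-ACGT characters are skipped)."""
    n = 0
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if not _ACGT.issuperset(window):
            continue
        if canonical(window) in unique:
            n += 1
    return n


# ------------------------------------------------------------- operations

def count_kmers(reads, k: int) -> KmerTable:
    """Count every canonical length-k window of every read.

    ``reads`` may be FASTQ path(s), an iterable of sequences, or an iterable
    of (name, seq, qual) tuples.  Windows containing non-ACGT characters are
    skipped; reads shorter than k contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for idx, seq in enumerate(_iter_seqs(reads)):
        if not isinstance(seq, str):
            raise ValueError(f"malformed read record at index {idx}")
        seq = seq.upper()
        clean = _ACGT.issuperset(seq)
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            if not clean and not _ACGT.issuperset(window):
                continue
            c = canonical(window)
            counts[c] = counts.get(c, 0) + 1
    return KmerTable(k=k, counts=counts)


def unique_kmers(present: KmerTable, absent: KmerTable,
                 config: FilterConfig | None = None, *,
                 min_count_present: int | None = None,
                 max_count_absent: int | None = None) -> set[str]:
    """Kmers with count >= min_count_present in ``present`` and count
    <= max_count_absent in ``absent``.

    Thresholds come from ``config`` when given (its k must match the
    tables'), or from the keyword arguments (any matching table k, useful
    for short-k experiments outside FilterConfig's validated range).
    """
    if present.k != absent.k:
        raise ValueError(
            f"kmer length mismatch: present k={present.k}, absent k={absent.k}"
        )
    if config is not None:
        if present.k != config.k:
            raise ValueError(
                f"kmer length mismatch: tables k={present.k}, config k={config.k}"
            )
        mcp, mca = config.min_count_present, config.max_count_absent
    else:
        mcp = 3 if min_count_present is None else min_count_present
        mca = 0 if max_count_absent is None else max_count_absent
    return {
        kmer for kmer, n in present.counts.items()
        if n >= mcp and absent.get(kmer) <= mca
    }


def filter_reads(reads1: Sequence[wio.Read], reads2: Sequence[wio.Read] | None,
                 unique: set[str], config: FilterConfig,
                 ) -> tuple[list[wio.Read], list[wio.Read], FilterStats]:
    """Retain reads carrying >= min_unique_per_read unique-kmer windows.

    With mates (``reads2`` given), pair_policy 'either' keeps the pair if
    either mate passes and 'both' only if both do.  Input order is
    preserved.  Returns (kept1, kept2, stats); kept2 is empty for
    single-end input.
    """
    k = config.k
    if reads2 is not None:
        if len(reads1) != len(reads2):
            raise ValueError(
                f"mate lists of unequal length: {len(reads1)} vs {len(reads2)}"
            )
        if config.pair_policy == "single-end":
            raise ValueError("pair_policy 'single-end' given paired input")
        kept1, kept2 = [], []
        for r1, r2 in zip(reads1, reads2):
            p1 = read_unique_count(r1[1], unique, k) >= config.min_unique_per_read
            p2 = read_unique_count(r2[1], unique, k) >= config.min_unique_per_read
            keep = (p1 or p2) if config.pair_policy == "either" else (p1 and p2)
            if keep:
                kept1.append(r1)
                kept2.append(r2)
        return kept1, kept2, FilterStats(n_input=2 * len(reads1),
                                         n_retained=2 * len(kept1))
    kept = [r for r in reads1
            if read_unique_count(r[1], unique, k) >= config.min_unique_per_read]
    return kept, [], FilterStats(n_input=len(reads1), n_retained=len(kept))


@dataclass(frozen=True)
class DifferentialCallResult:
    """Per-direction variant calls from the kmer-filtered pipeline."""

    calls_a: tuple            # variants supported only by sample A's reads
    calls_b: tuple
    n_unique_a: int
    n_unique_b: int
    stats_a: FilterStats
    stats_b: FilterStats


def differential_call(sample_a, sample_b, reference: dict[str, str],
                      config: FilterConfig, call_params) -> DifferentialCallResult:
    """Full reference-free differential stage for two samples.

    Each sample is ``(reads1, reads2)`` lists (or a pair of FASTQ paths).
    Counts kmers in both, derives the unique set in each direction, filters
    each sample's reads to those carrying its own unique kmers, and re-calls
    variants on the filtered reads with the ordinary map-and-call stage.
    """
    from wgadiff.align import call_pipeline

    def _load(sample):
        r1, r2 = sample
        if isinstance(r1, (str, Path)):
            return wio.read_fastq_pair(r1, r2)
        return list(r1), list(r2)

    try:
        a1, a2 = _load(sample_a)
        b1, b2 = _load(sample_b)
    except Exception as exc:
        raise RuntimeError(f"differential_call [input stage]: {exc}") from exc

    try:
        table_a = count_kmers(a1 + a2, config.k)
        table_b = count_kmers(b1 + b2, config.k)
    except Exception as exc:
        raise RuntimeError(f"differential_call [counting stage]: {exc}") from exc

    uniq_a = unique_kmers(table_a, table_b, config)
    uniq_b = unique_kmers(table_b, table_a, config)

    try:
        fa1, fa2, stats_a = filter_reads(a1, a2, uniq_a, config)
        fb1, fb2, stats_b = filter_reads(b1, b2, uniq_b, config)
    except Exception as exc:
        raise RuntimeError(f"differential_call [filter stage]: {exc}") from exc

    try:
        res_a = call_pipeline(fa1, fa2, reference, call_params)
        res_b = call_pipeline(fb1, fb2, reference, call_params)
    except Exception as exc:
        raise RuntimeError(f"differential_call [calling stage]: {exc}") from exc

    return DifferentialCallResult(
        calls_a=tuple(res_a.calls), calls_b=tuple(res_b.calls),
        n_unique_a=len(uniq_a), n_unique_b=len(uniq_b),
        stats_a=stats_a, stats_b=stats_b,
    )
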