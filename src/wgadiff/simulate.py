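"""Synthetic exome inputs: reference, diploid truth, capture kits, and reads.

The generator emulates the study design under comparison: paired-end 100 bp
exome sequencing at ~20-30X of the same diploid individual, once from native
genomic DNA and once after Phi29 multiple-displacement amplification (MDA).
The MDA artifact model covers the three artifact classes that matter for
variant calling: chimeric fragments (a known MDA byproduct and a source of
misalignment), strong log-normal amplification bias across loci, and allelic
dropout at heterozygous sites.

Every operation is byte-reproducible given its parameters and seed.
``apply_wga`` with the zero profile is byte-identical to ``simulate_reads``:
the artifact random draws are made on an identical stream and merely scale
to no-ops when the profile is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from wgadiff import io as wio

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")

# base byte -> 0..3 index (255 = not ACGT)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i

# locus granularity for MDA amplification-bias weights
_BIAS_WINDOW = 500


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ------------------------------------------------------------- data types

@dataclass(frozen=True)
class SimulatedGenome:
    """A random haploid reference contig (stand-in for a real reference)."""

    name: str
    sequence: str
    seed: int

    @property
    def length(self) -> int:
        return len(self.sequence)


VariantRecord = tuple[str, int, str, str, str]  # contig, pos(1-based), ref, alt, het|hom


@dataclass(frozen=True)
class PlantedVariantSet:
    """Ground-truth SNVs planted on the diploid haplotypes.

    Positions are 1-based.  ``het`` variants sit on exactly one haplotype,
    ``hom`` on both.
    """

    records: tuple[VariantRecord, ...]

    def __post_init__(self):
        positions = [(r[0], r[1]) for r in self.records]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate variant positions in truth set")
        if list(positions) != sorted(positions):
            raise ValueError("truth records must be position-sorted")

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {(c, p, r, a) for c, p, r, a, _ in self.records}

    def genotype_map(self) -> dict[tuple[str, int, str, str], str]:
        return {(c, p, r, a): ("0/1" if g == "het" else "1/1")
                for c, p, r, a, g in self.records}

    def het_positions(self, contig: str) -> list[int]:
        return [p for c, p, _, _, g in self.records if c == contig and g == "het"]

    def to_vcf(self, path, contig_lengths: dict[str, int]) -> None:
        """Write the truth set as minimal VCF 4.2 (1-based positions)."""
        from wgadiff.variants import VariantCall
        calls = [
            VariantCall(contig=c, pos=p, ref=r, alt=a,
                        genotype="0/1" if g == "het" else "1/1",
                        qual=99.0, depth=0, gq=99)
            for c, p, r, a, g in self.records
        ]
        wio.write_vcf(path, calls, contig_lengths, sample="truth")

    @classmethod
    def from_vcf(cls, path) -> "PlantedVariantSet":
        calls = wio.read_vcf(path)
        recs = tuple(
            (c.contig, c.pos, c.ref, c.alt, "het" if c.genotype == "0/1" else "hom")
            for c in sorted(calls, key=lambda v: (v.contig, v.pos))
        )
        return cls(records=recs)


@dataclass(frozen=True)
class DiploidHaplotypes:
    """The two haplotype sequences of the simulated individual."""

    contig: str
    hap1: str
    hap2: str

    def __post_init__(self):
        if len(self.hap1) != len(self.hap2):
            raise ValueError("haplotypes must be equal length (SNVs only)")

    @property
    def length(self) -> int:
        return len(self.hap1)


@dataclass(frozen=True)
class CaptureKit:
    """An exome capture kit: target intervals plus on-target efficiency.

    Targets are 0-based half-open, sorted, non-overlapping.
    """

    name: str
    targets: tuple[tuple[str, int, int], ...]
    efficiency: float = 0.95

    def __post_init__(self):
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")
        prev_end: dict[str, int] = {}
        for contig, start, end in self.targets:
            if not 0 <= start < end:
                raise ValueError(f"bad target interval {contig}:{start}-{end}")
            if start < prev_end.get(contig, 0) and prev_end.get(contig) is not None:
                if start < prev_end[contig]:
                    raise ValueError("targets overlap or are unsorted")
            prev_end[contig] = end

    @property
    def span(self) -> int:
        return sum(e - s for _, s, e in self.targets)

    def to_bed(self, path) -> None:
        """Write targets as BED (0-based half-open)."""
        wio.write_bed(path, self.targets)


@dataclass(frozen=True)
class WgaProfile:
    """MDA/Phi29 artifact model.

    chimera_rate      per-fragment probability of a single chimeric junction
    extra_error_rate  per-base substitutions added on amplified templates
    bias_sigma        log-scale SD of per-locus amplification weight
    dropout_rate      per-het-site probability that one haplotype's amplicons
                      are suppressed (library-wide, all-or-nothing)
    """

    chimera_rate: float = 0.0
    extra_error_rate: float = 0.0
    bias_sigma: float = 0.0
    dropout_rate: float = 0.0

    def __post_init__(self):
        for name in ("chimera_rate", "extra_error_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.bias_sigma < 0:
            raise ValueError("bias_sigma must be >= 0")

    @classmethod
    def zero(cls) -> "WgaProfile":
        return cls(0.0, 0.0, 0.0, 0.0)

    @classmethod
    def default_mda(cls) -> "WgaProfile":
        """Defaults representative of MDA on nanogram inputs: ~5% chimeric
        200 bp fragments, mild extra error, strong log-normal coverage bias,
        5% allelic dropout."""
        return cls(chimera_rate=0.05, extra_error_rate=0.001,
                   bias_sigma=1.0, dropout_rate=0.05)

    @property
    def is_zero(self) -> bool:
        return (self.chimera_rate == 0 and self.extra_error_rate == 0
                and self.bias_sigma == 0 and self.dropout_rate == 0)


@dataclass(frozen=True)
class ReadSimConfig:
    """Sequencing simulation parameters (2x100PE, 200 bp fragments, ~25X)."""

    read_length: int = 100
    fragment_mean: int = 200
    fragment_sd: int = 20
    depth: float = 25.0
    base_error_rate: float = 0.001
    quality_model: str = "constant"   # constant Q30, or "decaying"
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.read_length > self.fragment_mean + 4 * self.fragment_sd:
            raise ValueError("read_length exceeds fragment_mean + 4*fragment_sd")
        if self.quality_model not in ("constant", "decaying"):
            raise ValueError("quality_model must be 'constant' or 'decaying'")


@dataclass(frozen=True)
class SimulatedReadSet:
    """A paired read set plus the ground-truth annotations needed for
    artifact attribution.

    Read names follow ``frag<i>:<contig>:<start>:<hap>:<chimera-flag>`` so
    that every read's fragment origin, haplotype, and chimera status are
    recoverable without side files.
    """

    contig: str
    reads1: tuple[wio.Read, ...]
    reads2: tuple[wio.Read, ...]
    dropped_het_sites: tuple[int, ...]      # 1-based positions with allelic dropout
    n_fragments: int
    n_chimeric: int

    def write(self, path1, path2) -> None:
        wio.write_fastq(path1, [(f"{n}/1", s, q) for n, s, q in self.reads1])
        wio.write_fastq(path2, [(f"{n}/2", s, q) for n, s, q in self.reads2])


# ------------------------------------------------------------- operations

def simulate_genome(length: int, gc_content: float = 0.5, seed: int = 0,
                    name: str = "chr1") -> SimulatedGenome:
    """I.i.d. random reference with the given GC content, split evenly
    between G and C (and A/T)."""
    if length < 0:
        raise ValueError(f"genome length must be non-negative, got {length}")
    if not 0 <= gc_content <= 1:
        raise ValueError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_content) / 2, gc_content / 2,
                  gc_content / 2, (1 - gc_content) / 2])
    idx = rng.choice(4, size=length, p=p)
    seq = _BASE_ARR[idx].tobytes().decode()
    return SimulatedGenome(name=name, sequence=seq, seed=seed)


def plant_variants(genome: SimulatedGenome, n_snvs: int, het_fraction: float = 0.5,
                   min_spacing: int = 50, seed: int = 0,
                   ) -> tuple[DiploidHaplotypes, PlantedVariantSet]:
    """Plant ``n_snvs`` SNVs with pairwise spacing >= min_spacing.

    hom variants are applied to both haplotypes, het to exactly one
    (chosen at random).  Returns the haplotype pair and the truth set.
    """
    if n_snvs * max(min_spacing, 1) >= genome.length and n_snvs > 0:
        raise ValueError("infeasible: n_snvs * min_spacing >= genome length")
    rng = np.random.default_rng(seed)
    seq = genome.sequence
    if n_snvs == 0:
        return (DiploidHaplotypes(genome.name, seq, seq),
                PlantedVariantSet(records=()))
    slots = genome.length - (n_snvs - 1) * min_spacing
    base_pos = np.sort(rng.choice(slots, size=n_snvs, replace=False))
    positions = base_pos + min_spacing * np.arange(n_snvs)   # 0-based

    hap1 = bytearray(seq, "ascii")
    hap2 = bytearray(seq, "ascii")
    records = []
    for pos in positions:
        ref = seq[pos]
        alt = BASES[(BASES.index(ref) + 1 + rng.integers(0, 3)) % 4]
        is_het = rng.random() < het_fraction
        target_hap = int(rng.integers(0, 2))   # drawn even for hom, for stream stability
        if is_het:
            (hap1 if target_hap == 0 else hap2)[pos] = ord(alt)
            geno = "het"
        else:
            hap1[pos] = ord(alt)
            hap2[pos] = ord(alt)
            geno = "hom"
        records.append((genome.name, int(pos) + 1, ref, alt, geno))
    haps = DiploidHaplotypes(genome.name, hap1.decode(), hap2.decode())
    return haps, PlantedVariantSet(records=tuple(records))


def define_capture_kits(genome: SimulatedGenome, n_targets: int, target_length: int,
                        shared_fraction: float, seed: int = 0,
                        efficiency: float = 0.95, min_gap: int = 500,
                        ) -> tuple[CaptureKit, CaptureKit]:
    """Design two capture kits sharing ``round(shared_fraction * n_targets)``
    targets; the remaining targets are split privately, ties broken toward
    kit A."""
    span_needed = n_targets * (target_length + min_gap)
    if span_needed >= genome.length:
        raise ValueError("infeasible: targets + gaps exceed genome length")
    rng = np.random.default_rng(seed)
    slots = genome.length - target_length - (n_targets - 1) * (target_length + min_gap)
    base = np.sort(rng.choice(slots, size=n_targets, replace=False))
    starts = base + (target_length + min_gap) * np.arange(n_targets)
    intervals = [(genome.name, int(s), int(s) + target_length) for s in starts]

    n_shared = int(round(shared_fraction * n_targets))
    rem = n_targets - n_shared
    n_private_a = (rem + 1) // 2          # ties toward kit A
    order = rng.permutation(n_targets)
    shared = {int(i) for i in order[:n_shared]}
    priv_a = {int(i) for i in order[n_shared:n_shared + n_private_a]}
    kit_a = tuple(iv for i, iv in enumerate(intervals) if i in shared or i in priv_a)
    kit_b = tuple(iv for i, iv in enumerate(intervals)
                  if i in shared or (i not in shared and i not in priv_a))
    return (CaptureKit(name="kitA", targets=kit_a, efficiency=efficiency),
            CaptureKit(name="kitB", targets=kit_b, efficiency=efficiency))


def private_targets(kit_a: CaptureKit, kit_b: CaptureKit,
                    ) -> tuple[list[tuple[str, int, int]], list[tuple[str, int, int]]]:
    """The designed kit-private target intervals (A-only, B-only)."""
    sa, sb = set(kit_a.targets), set(kit_b.targets)
    return (sorted(sa - sb), sorted(sb - sa))


def make_known_panel(truth: PlantedVariantSet, genome: SimulatedGenome,
                     coverage_fraction: float = 0.96, n_extra: int = 500,
                     seed: int = 0) -> set[tuple[str, int, str, str]]:
    """A simulated known-variant panel (dbSNP stand-in): a fixed fraction of
    the subject's true variants plus extra population variants the subject
    does not carry."""
    rng = np.random.default_rng(seed)
    recs = list(truth.records)
    n_in = int(round(coverage_fraction * len(recs)))
    chosen = rng.choice(len(recs), size=n_in, replace=False) if recs else []
    panel = {(recs[i][0], recs[i][1], recs[i][2], recs[i][3]) for i in chosen}
    truth_pos = {(r[0], r[1]) for r in recs}
    added = 0
    while added < n_extra:
        pos = int(rng.integers(0, genome.length))  # 0-based
        if (genome.name, pos + 1) in truth_pos:
            continue
        ref = genome.sequence[pos]
        alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        key = (genome.name, pos + 1, ref, alt)
        if key not in panel:
            panel.add(key)
            added += 1
    return panel


# ----------------------------------------------------- read simulation core

def _quality_string(model: str, length: int) -> str:
    if model == "constant":
        return chr(33 + 30) * length
    # linear decay Q35 -> Q20 along the read
    quals = np.linspace(35, 20, length).round().astype(int)
    return "".join(chr(33 + q) for q in quals)


def simulate_reads(haplotypes: DiploidHaplotypes, kit: CaptureKit,
                   config: ReadSimConfig) -> SimulatedReadSet:
    """Native-DNA paired-end simulation (no amplification artifacts)."""
    return apply_wga(haplotypes, WgaProfile.zero(), kit, config)


def apply_wga(haplotypes: DiploidHaplotypes, profile: WgaProfile,
              kit: CaptureKit, config: ReadSimConfig) -> SimulatedReadSet:
    """Paired-end simulation through the MDA artifact model.

    Fragment starts are drawn so the (mean-length) fragment overlaps a
    capture target with probability ``kit.efficiency`` and genome-wide
    otherwise, weighted by per-window log-normal amplification weights.
    Each fragment picks a haplotype uniformly unless it overlaps a
    dropped-out het site; with probability ``chimera_rate`` its 3' portion
    continues from a uniformly chosen donor locus and strand.
    """
    glen = haplotypes.length
    rl = config.read_length
    fl_mean = config.fragment_mean
    contig = haplotypes.contig
    targets = [(s, e) for c, s, e in kit.targets if c == contig]
    if not targets:
        raise ValueError("capture kit has no targets on the haplotype contig")
    if glen < fl_mean:
        raise ValueError("genome shorter than mean fragment length")

    rng = np.random.default_rng(config.seed)
    span = sum(e - s for s, e in targets)
    n_frag = max(1, round(config.depth * span / (2 * rl)))

    # per-window amplification weights; exp(sigma * z) so the RNG stream is
    # identical for every sigma (zero profile -> all-ones weights)
    n_win = (glen + _BIAS_WINDOW - 1) // _BIAS_WINDOW
    win_w = np.exp(profile.bias_sigma * rng.standard_normal(n_win))
    per_start_w = np.repeat(win_w, _BIAS_WINDOW)[:glen].astype(float)

    valid = np.zeros(glen, dtype=bool)
    max_start = glen - fl_mean
    valid[:max_start + 1] = True
    on_mask = np.zeros(glen, dtype=bool)
    for s, e in targets:
        lo = max(0, s - fl_mean + 1)
        hi = min(glen, e)            # starts in [lo, hi) overlap the target
        on_mask[lo:hi] = True
    on_mask &= valid
    w_on = per_start_w * on_mask
    w_off = per_start_w * valid
    if w_on.sum() == 0:
        raise ValueError("no valid on-target fragment start positions")

    on_target = rng.random(n_frag) < kit.efficiency
    starts = np.empty(n_frag, dtype=np.int64)
    n_on = int(on_target.sum())
    if n_on:
        starts[on_target] = rng.choice(glen, size=n_on, p=w_on / w_on.sum())
    if n_frag - n_on:
        starts[~on_target] = rng.choice(glen, size=n_frag - n_on, p=w_off / w_off.sum())

    lengths = np.clip(np.rint(rng.normal(fl_mean, config.fragment_sd, n_frag)),
                      rl, None).astype(np.int64)
    lengths = np.minimum(lengths, glen - starts)
    lengths = np.maximum(lengths, rl)
    starts = np.minimum(starts, glen - lengths)   # keep fragments in-bounds

    haps_idx = rng.integers(0, 2, n_frag)

    # allelic dropout: per het site, per library, all-or-nothing
    h1 = np.frombuffer(haplotypes.hap1.encode(), dtype=np.uint8)
    h2 = np.frombuffer(haplotypes.hap2.encode(), dtype=np.uint8)
    het_pos = np.flatnonzero(h1 != h2)            # 0-based
    drop_draw = rng.random(len(het_pos))
    forced_hap = rng.integers(0, 2, len(het_pos))
    dropped = drop_draw < profile.dropout_rate
    dropped_sites = het_pos[dropped]
    forced_assigned = np.zeros(n_frag, dtype=bool)
    for site, fh in zip(dropped_sites, forced_hap[dropped]):
        hit = (starts <= site) & (site < starts + lengths) & ~forced_assigned
        haps_idx[hit] = fh
        forced_assigned |= hit

    is_chim = rng.random(n_frag) < profile.chimera_rate
    junction = 1 + (rng.random(n_frag) * (lengths - 1)).astype(np.int64)
    donor_start = rng.integers(0, glen, n_frag)
    donor_strand = rng.integers(0, 2, n_frag)

    hap_seqs = (haplotypes.hap1, haplotypes.hap2)
    qual = _quality_string(config.quality_model, rl)
    reads1, reads2 = [], []
    seq_buf = []
    for i in range(n_frag):
        s, L, h = int(starts[i]), int(lengths[i]), int(haps_idx[i])
        hs = hap_seqs[h]
        if is_chim[i]:
            j = int(junction[i])
            rem = L - j
            ds = int(donor_start[i])
            if donor_strand[i] == 0:
                ds = min(ds, glen - rem)
                tail = hs[ds:ds + rem]
            else:
                ds = max(ds, rem)
                tail = revcomp(hs[ds - rem:ds])
            frag = hs[s:s + j] + tail
        else:
            frag = hs[s:s + L]
        name = f"frag{i}:{contig}:{s}:{h}:{1 if is_chim[i] else 0}"
        seq_buf.append(frag[:rl])
        seq_buf.append(revcomp(frag[-rl:]))
        reads1.append(name)
        reads2.append(name)

    # sequencing + amplification substitution errors, vectorized over all reads
    err_rate = config.base_error_rate + profile.extra_error_rate
    arr = np.frombuffer("".join(seq_buf).encode(), dtype=np.uint8).copy()
    arr = arr.reshape(2 * n_frag, rl)
    err_mask = rng.random(arr.shape) < err_rate
    n_err = int(err_mask.sum())
    if n_err:
        shifts = rng.integers(1, 4, n_err).astype(np.uint8)
        enc = _ENC[arr[err_mask]]
        arr[err_mask] = _BASE_ARR[(enc + shifts) % 4]

    out1, out2 = [], []
    flat = arr.tobytes().decode()
    for i in range(n_frag):
        out1.append((reads1[i], flat[2 * i * rl:(2 * i + 1) * rl], qual))
        out2.append((reads2[i], flat[(2 * i + 1) * rl:(2 * i + 2) * rl], qual))

    return SimulatedReadSet(
        contig=contig,
        reads1=tuple(out1),
        reads2=tuple(out2),
        dropped_het_sites=tuple(int(p) + 1 for p in sorted(dropped_sites)),
        n_fragments=n_frag,
        n_chimeric=int(is_chim.sum()),
    )
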