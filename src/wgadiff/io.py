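"""Readers and writers for the text formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython; VCF parsing to pysam.  The
writers emit the minimal dialects the pipeline itself consumes: VCF 4.2 with
INFO ``DP`` and FORMAT ``GT:DP:GQ``, 3-column BED, and plain 4-line FASTQ.

Coordinate conventions (stated on every writer below): BED intervals are
0-based half-open; VCF positions are 1-based.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from wgadiff.variants import VariantCall

Read = tuple[str, str, str]  # (name, sequence, quality string)


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file as {contig: uppercase sequence}."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, contigs: dict[str, str], with_index: bool = True) -> None:
    """Write FASTA plus a .fai-style index table (name, length, offset,
    linebases, linewidth)."""
    path = Path(path)
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    if with_index:
        # recompute offsets exactly as faidx would for 60-column Biopython output
        lines = []
        offset = 0
        with open(path) as fh:
            text = fh.read()
        pos = 0
        for name, seq in contigs.items():
            header = f">{name}\n"
            assert text[pos:pos + len(header)] == header
            offset = pos + len(header)
            linebases = 60
            lines.append(f"{name}\t{len(seq)}\t{offset}\t{linebases}\t{linebases + 1}")
            nlines = (len(seq) + linebases - 1) // linebases if seq else 0
            pos = offset + len(seq) + nlines
        Path(str(path) + ".fai").write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------- FASTQ

def read_fastq(path) -> list[Read]:
    with _open_text(path) as fh:
        return [(name, seq.upper(), qual) for name, seq, qual in FastqGeneralIterator(fh)]


def write_fastq(path, reads: Iterable[Read]) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq_pair(path1, path2) -> tuple[list[Read], list[Read]]:
    r1, r2 = read_fastq(path1), read_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError(
            f"mate files of unequal length: {len(r1)} vs {len(r2)} records"
        )
    return r1, r2


# ---------------------------------------------------------------- BED

def write_bed(path, intervals: Sequence[tuple[str, int, int]]) -> None:
    """Write intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for contig, start, end in intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED intervals (0-based half-open); extra columns ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


# ---------------------------------------------------------------- VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=wgadiff
{contigs}##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FILTER=<ID=LowQual,Description="Call quality below threshold">
##FILTER=<ID=LowDepth,Description="Depth below threshold">
##FILTER=<ID=HighDepth,Description="Depth above multiple of mean depth">
##FILTER=<ID=LowAltFraction,Description="Alternate allele fraction below threshold">
##FILTER=<ID=StrandBias,Description="Alternate reads concentrated on one strand">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(path, calls: Sequence[VariantCall], contig_lengths: dict[str, int],
              sample: str = "sample1") -> None:
    """Write calls as minimal VCF 4.2 (positions 1-based), sorted by
    (contig, pos, alt)."""
    contig_lines = "".join(
        f"##contig=<ID={name},length={length}>\n" for name, length in contig_lengths.items()
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contig_lines, sample=sample))
        for c in sorted(calls, key=lambda v: (v.contig, v.pos, v.alt)):
            filt = "PASS" if c.is_pass else ";".join(sorted(c.filters))
            fh.write(
                f"{c.contig}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{c.qual:.2f}\t{filt}\t"
                f"DP={c.depth}\tGT:DP:GQ\t{c.genotype}:{c.depth}:{c.gq}\n"
            )


def read_vcf(path) -> list[VariantCall]:
    """Read a (possibly foreign) VCF into VariantCall records.

    Only biallelic SNV records are returned; genotype/depth/GQ are taken from
    the first sample when present.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            gt, dp, gq = "0/1", 0, 0
            if rec.samples:
                s = rec.samples[0]
                gt_tuple = s.get("GT")
                if gt_tuple and None not in gt_tuple:
                    gt = "/".join(str(a) for a in sorted(gt_tuple))
                dp = int(s.get("DP") or rec.info.get("DP", 0) or 0)
                gq = int(s.get("GQ") or 0)
            else:
                dp = int(rec.info.get("DP", 0) or 0)
            filters = tuple(sorted(f for f in rec.filter.keys() if f != "PASS"))
            calls.append(VariantCall(
                contig=rec.contig, pos=rec.pos, ref=ref, alt=alt, genotype=gt,
                qual=float(rec.qual or 0.0), depth=dp, gq=gq, filters=filters,
            ))
    return calls


# ------------------------------------------------------- alignment table

def write_alignment_tsv(path, alignments) -> None:
    """Write alignments (read_id, contig, pos[0-based], strand, n_mismatch,
    mapq_proxy, length) as TSV; unaligned reads get contig '.' and pos -1."""
    with open(path, "w") as fh:
        fh.write("read_id\tcontig\tpos\tstrand\tn_mismatch\tmapq_proxy\tlength\n")
        for a in alignments:
            if a.aligned:
                fh.write(f"{a.read_id}\t{a.contig}\t{a.position}\t{a.strand}\t"
                         f"{a.n_mismatch}\t{a.mapq_proxy}\t{a.length}\n")
            else:
                fh.write(f"{a.read_id}\t.\t-1\t.\t-1\t0\t{a.length}\n")


def read_alignment_tsv(path):
    """Read an alignment TSV back into lightweight AlignmentRecord objects
    (without sequences — enough for coverage work)."""
    from wgadiff.align import AlignmentRecord
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError("not an alignment TSV (missing header)")
        for line in fh:
            rid, contig, pos, strand, nm, mapq, length = line.rstrip("\n").split("\t")
            aligned = contig != "."
            out.append(AlignmentRecord(
                read_id=rid, contig=contig if aligned else "",
                position=int(pos), strand=strand if aligned else "+",
                n_mismatch=int(nm), mapq_proxy=int(mapq),
                aligned=aligned, seq="", length=int(length),
            ))
    return out
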