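"""Coverage and variant-density comparison between two capture kits.

Coverage tracks are per-bin mean depths computed from aligned read
intervals; kit-unique regions are maximal runs of bins where one kit
reaches a depth floor and the other does not.  All intervals are 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CoverageTrack:
    contig: str
    bin_size: int
    depths: np.ndarray          # per-bin mean depth
    contig_length: int

    def __post_init__(self):
        expected = -(-self.contig_length // self.bin_size)
        if len(self.depths) != expected:
            raise ValueError("track length inconsistent with contig/bin size")

    @property
    def total_aligned_bases(self) -> float:
        return float(self.depths.sum() * self.bin_size)


@dataclass(frozen=True)
class RegionSet:
    """Sorted, non-overlapping labeled intervals (0-based half-open)."""

    label: str
    intervals: tuple[tuple[str, int, int], ...]

    @property
    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def base_set(self) -> set[tuple[str, int]]:
        return {(c, p) for c, s, e in self.intervals for p in range(s, e)}


def base_jaccard(a: Sequence[tuple[str, int, int]],
                 b: Sequence[tuple[str, int, int]]) -> float | None:
    """Base-level Jaccard index of two interval collections; None when both
    are empty."""
    sa = {(c, p) for c, s, e in a for p in range(s, e)}
    sb = {(c, p) for c, s, e in b for p in range(s, e)}
    union = sa | sb
    if not union:
        return None
    return len(sa & sb) / len(union)


# ------------------------------------------------------------- operations

def coverage_track(alignments, contig_lengths: dict[str, int],
                   bin_size: int = 100) -> dict[str, CoverageTrack]:
    """Per-bin mean per-base depth from aligned intervals.

    Bin value = (sum of per-base depth in the bin) / bin_size for every bin
    including a ragged last one, so sum(depths) * bin_size equals the total
    number of aligned bases (conservation).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    delta = {c: np.zeros(length + 1, dtype=np.int64)
             for c, length in contig_lengths.items()}
    for a in alignments:
        if not a.aligned:
            continue
        if a.contig not in delta:
            raise ValueError(f"alignment on unknown contig {a.contig}")
        delta[a.contig][a.position] += 1
        delta[a.contig][a.end] -= 1
    tracks = {}
    for contig, length in contig_lengths.items():
        depth = np.cumsum(delta[contig][:-1])
        n_bins = -(-length // bin_size)
        padded = np.zeros(n_bins * bin_size, dtype=np.int64)
        padded[:length] = depth
        bins = padded.reshape(n_bins, bin_size).sum(axis=1) / bin_size
        tracks[contig] = CoverageTrack(contig=contig, bin_size=bin_size,
                                       depths=bins, contig_length=length)
    return tracks


def kit_unique_regions(tracks_a: dict[str, CoverageTrack],
                       tracks_b: dict[str, CoverageTrack],
                       min_depth: float = 8.0, min_run: int = 100,
                       ) -> tuple[RegionSet, RegionSet]:
    """Maximal runs (>= min_run bases) where one kit is covered
    (depth >= min_depth) and the other is not."""
    if set(tracks_a) != set(tracks_b):
        raise ValueError("tracks cover different contigs")

    def runs(mask: np.ndarray, contig: str, bin_size: int,
             clen: int) -> list[tuple[str, int, int]]:
        out = []
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        for lo, hi in zip(edges[::2], edges[1::2]):
            start, end = int(lo) * bin_size, min(int(hi) * bin_size, clen)
            if end - start >= min_run:
                out.append((contig, start, end))
        return out

    only_a, only_b = [], []
    for contig in sorted(tracks_a):
        ta, tb = tracks_a[contig], tracks_b[contig]
        if ta.bin_size != tb.bin_size or ta.contig_length != tb.contig_length:
            raise ValueError(f"incompatible binning on contig {contig}")
        a_cov = ta.depths >= min_depth
        b_cov = tb.depths >= min_depth
        only_a += runs(a_cov & ~b_cov, contig, ta.bin_size, ta.contig_length)
        only_b += runs(b_cov & ~a_cov, contig, ta.bin_size, ta.contig_length)
    return (RegionSet(label="unique_to_A", intervals=tuple(only_a)),
            RegionSet(label="unique_to_B", intervals=tuple(only_b)))


def snv_density(calls, contig_lengths: dict[str, int],
                bin_size: int = 100) -> dict[str, np.ndarray]:
    """Per-bin counts of PASS calls; total equals the PASS call count."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    out = {c: np.zeros(-(-length // bin_size), dtype=np.int64)
           for c, length in contig_lengths.items()}
    for call in calls:
        if not call.is_pass:
            continue
        out[call.contig][(call.pos - 1) // bin_size] += 1
    return out


def plot_tables(outdir, tracks_by_kit: dict[str, dict[str, CoverageTrack]],
                region_sets: Sequence[RegionSet],
                densities_by_kit: dict[str, dict[str, np.ndarray]],
                ) -> pd.DataFrame:
    """Emit a ring-ordered TSV bundle (contig, start, end, value, layer) for
    any circular-plot tool; rows are deterministic.  Returns the combined
    table."""
    rows = []
    for rs in region_sets:
        for contig, start, end in rs.intervals:
            rows.append((contig, start, end, 1.0, f"region:{rs.label}"))
    for kit in sorted(tracks_by_kit):
        for contig in sorted(tracks_by_kit[kit]):
            t = tracks_by_kit[kit][contig]
            for i, d in enumerate(t.depths):
                s = i * t.bin_size
                rows.append((contig, s, min(s + t.bin_size, t.contig_length),
                             round(float(d), 6), f"depth:{kit}"))
    for kit in sorted(densities_by_kit):
        for contig in sorted(densities_by_kit[kit]):
            dens = densities_by_kit[kit][contig]
            bin_size = tracks_by_kit.get(kit, {}).get(contig)
            bs = bin_size.bin_size if bin_size is not None else 100
            for i, n in enumerate(dens):
                rows.append((contig, i * bs, (i + 1) * bs, int(n),
                             f"snv_density:{kit}"))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "value", "layer"])
    df = df.sort_values(["layer", "contig", "start"], kind="stable").reset_index(drop=True)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "plot_layers.tsv", sep="\t", index=False)
    return df
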