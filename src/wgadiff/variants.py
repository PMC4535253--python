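"""The unit record of all concordance arithmetic: a biallelic SNV call."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class VariantCall:
    """A single biallelic SNV call.

    Positions are 1-based (VCF convention).  ``filters`` is empty for a PASS
    call; otherwise it lists the names of every failed hard-filter predicate.
    Strand counts refer to reads supporting the alternate allele and feed the
    strand-bias filter.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    genotype: str          # "0/1" or "1/1"
    qual: float
    depth: int
    gq: int = 0
    alt_depth: int = 0
    alt_fwd: int = 0
    alt_rev: int = 0
    filters: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.contig}:{self.pos}")
        if self.qual < 0:
            raise ValueError("qual must be non-negative")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_pass(self) -> bool:
        return not self.filters

    def with_filters(self, filters: tuple[str, ...]) -> "VariantCall":
        return replace(self, filters=filters)
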