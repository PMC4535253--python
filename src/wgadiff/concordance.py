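"""Agreement between two SNV call sets.

Concordance is union-denominated: the site concordance of call sets A and B
is |A ∩ B| / |A ∪ B| over site keys (contig, pos, ref, alt).  In genotype
mode the called genotype joins the key, so a site called in both sets with
different genotypes counts as private to each — the only reading that keeps
the partition identity n_union == n_intersection + n_only_A + n_only_B.
Per-sample rates (intersection over each set's own size) are reported
alongside, since published percentages are often per-sample denominated.

Undefined ratios (empty denominators) are reported as None, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from wgadiff.variants import VariantCall

Key = tuple


def _index(calls: Sequence[VariantCall], mode: str) -> dict[Key, VariantCall]:
    if mode not in ("site", "genotype"):
        raise ValueError("mode must be 'site' or 'genotype'")
    out: dict[Key, VariantCall] = {}
    for c in calls:
        key = c.key + ((c.genotype,) if mode == "genotype" else ())
        if key in out:
            raise ValueError(
                f"duplicate call key {key}; normalize the call set first"
            )
        out[key] = c
    return out


@dataclass(frozen=True)
class ConcordanceReport:
    n_a: int
    n_b: int
    n_intersection: int
    n_only_a: int
    n_only_b: int
    mode: str

    @property
    def n_union(self) -> int:
        return self.n_intersection + self.n_only_a + self.n_only_b

    @property
    def concordance(self) -> float | None:
        """Union-denominated concordance; None if the union is empty."""
        return self.n_intersection / self.n_union if self.n_union else None

    @property
    def concordance_a(self) -> float | None:
        """Per-sample rate: shared calls over A's calls."""
        return self.n_intersection / self.n_a if self.n_a else None

    @property
    def concordance_b(self) -> float | None:
        return self.n_intersection / self.n_b if self.n_b else None

    @property
    def n_discordant(self) -> int:
        return self.n_only_a + self.n_only_b

    def to_dict(self) -> dict:
        return {
            "mode": self.mode, "n_a": self.n_a, "n_b": self.n_b,
            "n_intersection": self.n_intersection,
            "n_only_a": self.n_only_a, "n_only_b": self.n_only_b,
            "n_union": self.n_union, "n_discordant": self.n_discordant,
            "concordance": _round(self.concordance),
            "concordance_a": _round(self.concordance_a),
            "concordance_b": _round(self.concordance_b),
        }


@dataclass(frozen=True)
class DepthStratumReport:
    threshold: int
    n_positions_retained: int
    fraction_retained: float | None   # relative to the unstratified union
    concordance: float | None
    n_intersection: int
    n_only_a: int
    n_only_b: int

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_positions_retained": self.n_positions_retained,
            "fraction_retained": _round(self.fraction_retained),
            "concordance": _round(self.concordance),
            "n_intersection": self.n_intersection,
            "n_only_a": self.n_only_a, "n_only_b": self.n_only_b,
        }


def _round(x: float | None, nd: int = 6) -> float | None:
    return None if x is None else round(x, nd)


# ------------------------------------------------------------- operations

def compare_sets(calls_a: Sequence[VariantCall], calls_b: Sequence[VariantCall],
                 mode: str = "site") -> ConcordanceReport:
    """Union/intersection/unique counts and concordance rates for two call
    sets on the same reference naming."""
    ia, ib = _index(calls_a, mode), _index(calls_b, mode)
    inter = ia.keys() & ib.keys()
    return ConcordanceReport(
        n_a=len(ia), n_b=len(ib), n_intersection=len(inter),
        n_only_a=len(ia.keys() - ib.keys()),
        n_only_b=len(ib.keys() - ia.keys()),
        mode=mode,
    )


def depth_stratified(calls_a: Sequence[VariantCall],
                     calls_b: Sequence[VariantCall],
                     thresholds: Iterable[int] = (1, 10, 20, 30),
                     mode: str = "site",
                     depth_a: dict[str, np.ndarray] | None = None,
                     depth_b: dict[str, np.ndarray] | None = None,
                     ) -> list[DepthStratumReport]:
    """Concordance restricted to sites with depth >= t in both samples.

    A key present in both sets is retained when both calls carry DP >= t.
    A key private to one set is retained when the present call's DP >= t
    and — when the other sample's pileup depth array is supplied — that
    sample also reaches depth t at the position (otherwise the discordance
    is mere lack of coverage, not disagreement).
    """
    ia, ib = _index(calls_a, mode), _index(calls_b, mode)
    for d in (ia, ib):
        for key, c in d.items():
            if c.depth is None:
                raise ValueError(f"call {key} lacks DP; cannot stratify")
    base_union = len(ia.keys() | ib.keys())

    def other_depth_ok(depth, contig, pos, t) -> bool:
        if depth is None:
            return True
        arr = depth.get(contig)
        if arr is None or pos - 1 >= len(arr):
            return False
        return int(arr[pos - 1]) >= t

    reports = []
    for t in thresholds:
        keep_a, keep_b = {}, {}
        for key, c in ia.items():
            if c.depth < t:
                continue
            if key in ib:
                if ib[key].depth >= t:
                    keep_a[key] = c
            elif other_depth_ok(depth_b, c.contig, c.pos, t):
                keep_a[key] = c
        for key, c in ib.items():
            if c.depth < t:
                continue
            if key in ia:
                if ia[key].depth >= t:
                    keep_b[key] = c
            elif other_depth_ok(depth_a, c.contig, c.pos, t):
                keep_b[key] = c
        inter = keep_a.keys() & keep_b.keys()
        only_a = len(keep_a.keys() - keep_b.keys())
        only_b = len(keep_b.keys() - keep_a.keys())
        union = len(inter) + only_a + only_b
        reports.append(DepthStratumReport(
            threshold=t, n_positions_retained=union,
            fraction_retained=(union / base_union) if base_union else None,
            concordance=(len(inter) / union) if union else None,
            n_intersection=len(inter), n_only_a=only_a, n_only_b=only_b,
        ))
    return reports


def classify_novel(calls: Sequence[VariantCall],
                   known: Iterable) -> tuple[int, int, float | None]:
    """Split calls into known/novel against a known-variant panel.

    ``known`` is an iterable of site keys (contig, pos, ref, alt) or of
    VariantCall objects.  Returns (n_known, n_novel, fraction_novel);
    fraction_novel is None when there are no calls.
    """
    known_keys = {k.key if isinstance(k, VariantCall) else tuple(k)[:4]
                  for k in known}
    n_known = sum(1 for c in calls if c.key in known_keys)
    n_novel = len(calls) - n_known
    total = len(calls)
    return n_known, n_novel, (n_novel / total) if total else None


@dataclass(frozen=True)
class TruthEvaluation:
    sensitivity: float
    precision: float | None       # None when there are no calls
    n_tp: int
    false_positives: tuple
    false_negatives: tuple


def evaluate_against_truth(calls: Sequence[VariantCall], truth,
                           require_genotype: bool = False) -> TruthEvaluation:
    """Recovery of planted variants: TP = calls whose key is in the truth
    set (optionally with matching genotype)."""
    truth_gt = truth.genotype_map()
    tp, fp = [], []
    for c in calls:
        if c.key in truth_gt and (not require_genotype
                                  or c.genotype == truth_gt[c.key]):
            tp.append(c)
        else:
            fp.append(c)
    called_keys = {c.key for c in tp}
    fn = tuple(k for k in sorted(truth_gt) if k not in called_keys)
    n_truth = len(truth_gt)
    return TruthEvaluation(
        sensitivity=(len(tp) / n_truth) if n_truth else 1.0,
        precision=(len(tp) / len(calls)) if calls else None,
        n_tp=len(tp),
        false_positives=tuple(c.key for c in fp),
        false_negatives=fn,
    )
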