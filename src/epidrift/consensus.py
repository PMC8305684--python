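"""Replicate peak consensus: keep peaks seen in both replicates, or rescue
singletons with high fold enrichment, merging pairs by maximum breadth and
maximum tag density.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, replace
from typing import Iterable, Literal

from epidrift.errors import ArgumentError, InputError

MARKS = ("H3K4me3", "H3K27me3")

MergeRule = Literal["max_breadth", "union"]


@dataclass(frozen=True)
class Peak:
    """One called enrichment region (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    fold_enrichment: float
    tag_density: float
    mark: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(f"peak has start >= end: {self.chrom}:{self.start}-{self.end}")
        if self.fold_enrichment <= 0:
            raise InputError(f"fold enrichment must be positive, got {self.fold_enrichment}")
        if self.tag_density < 0:
            raise InputError(f"tag density must be nonnegative, got {self.tag_density}")

    @property
    def breadth(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ConsensusPeak:
    """A retained per-condition peak with its support evidence."""

    chrom: str
    start: int
    end: int
    fold_enrichment: float
    tag_density: float
    mark: str
    support: Literal["both_replicates", "rescue_fe"]

    @property
    def breadth(self) -> int:
        return self.end - self.start


def _overlap(a: Peak, b: Peak) -> int:
    return min(a.end, b.end) - max(a.start, b.start)


def pair_replicate_peaks(
    rep1: Iterable[Peak], rep2: Iterable[Peak]
) -> tuple[list[tuple[Peak, Peak]], list[Peak], list[Peak]]:
    """Match peaks across two replicates by genomic overlap.

    Two peaks on the same chromosome overlapping by >= 1 base are candidate
    partners.  Candidates are consumed greedily by decreasing overlap
    (ties: leftmost rep1 start, then leftmost rep2 start), and each peak
    joins at most one pair.

    Returns ``(pairs, leftover_rep1, leftover_rep2)``.
    """
    rep1 = list(rep1)
    rep2 = list(rep2)

    # index rep2 per chromosome, sorted by start, for fast overlap lookup
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, p in enumerate(rep2):
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end, j))
    for entries in by_chrom.values():
        entries.sort()

    candidates: list[tuple[int, int, int, int, int]] = []
    for i, p in enumerate(rep1):
        entries = by_chrom.get(p.chrom, ())
        if not entries:
            continue
        # peaks starting before p.end can overlap; scan from the left and
        # stop once starts pass p.end (entries sorted by start)
        lo = 0
        hi = bisect_left(entries, (p.end, -1, -1))
        for start2, end2, j in entries[lo:hi]:
            if end2 > p.start:
                ov = min(p.end, end2) - max(p.start, start2)
                candidates.append((-ov, p.start, start2, i, j))

    candidates.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    pairs: list[tuple[Peak, Peak]] = []
    for _neg_ov, _s1, _s2, i, j in candidates:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        pairs.append((rep1[i], rep2[j]))

    leftover1 = [p for i, p in enumerate(rep1) if i not in used1]
    leftover2 = [p for j, p in enumerate(rep2) if j not in used2]
    return pairs, leftover1, leftover2


def merge_replicate_peak(p1: Peak, p2: Peak, rule: MergeRule = "max_breadth") -> ConsensusPeak:
    """Merge a replicate pair into one consensus peak.

    Under ``max_breadth`` the coordinates of the broader replicate peak are
    taken (ties: larger tag density, then rep1); under ``union`` the interval
    union is taken.  Tag density and fold enrichment are the pairwise maxima.
    """
    if p1.chrom != p2.chrom or _overlap(p1, p2) < 1:
        raise ArgumentError("merge_replicate_peak requires overlapping peaks on one chromosome")
    if p1.mark != p2.mark:
        raise ArgumentError("cannot merge peaks of different marks")

    if rule == "union":
        start, end = min(p1.start, p2.start), max(p1.end, p2.end)
    elif rule == "max_breadth":
        if p1.breadth > p2.breadth:
            chosen = p1
        elif p2.breadth > p1.breadth:
            chosen = p2
        else:
            chosen = p2 if p2.tag_density > p1.tag_density else p1
        start, end = chosen.start, chosen.end
    else:
        raise ArgumentError(f"unknown merge rule: {rule!r}")

    return ConsensusPeak(
        chrom=p1.chrom,
        start=start,
        end=end,
        fold_enrichment=max(p1.fold_enrichment, p2.fold_enrichment),
        tag_density=max(p1.tag_density, p2.tag_density),
        mark=p1.mark,
        support="both_replicates",
    )


def build_summary_peaks(
    rep1: Iterable[Peak],
    rep2: Iterable[Peak],
    fe_threshold: float = 5.0,
    merge_rule: MergeRule = "max_breadth",
    rescue: bool = True,
) -> list[ConsensusPeak]:
    """Build the summarized peak list for one condition and mark.

    A peak is retained if it was detected in both replicates (the pair is
    merged) or, when ``rescue`` is on, if a singleton's fold enrichment is
    strictly greater than ``fe_threshold``.
    """
    if fe_threshold <= 0:
        raise ArgumentError(f"fe_threshold must be positive, got {fe_threshold}")
    pairs, left1, left2 = pair_replicate_peaks(rep1, rep2)
    out = [merge_replicate_peak(p1, p2, rule=merge_rule) for p1, p2 in pairs]
    if rescue:
        for p in left1 + left2:
            if p.fold_enrichment > fe_threshold:
                out.append(
                    ConsensusPeak(
                        chrom=p.chrom,
                        start=p.start,
                        end=p.end,
                        fold_enrichment=p.fold_enrichment,
                        tag_density=p.tag_density,
                        mark=p.mark,
                        support="rescue_fe",
                    )
                )
    out.sort(key=lambda c: (c.chrom, c.start, c.end))
    return out
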