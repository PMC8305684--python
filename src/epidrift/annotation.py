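"""Peak-to-gene assignment and the per-gene binary histone code.

A gene carries a mark in a sample iff some consensus peak of that mark
overlaps the union of the gene's promoter (TSS +/- flank) and gene body by
at least ``min_overlap_frac`` of the peak's breadth (default 5%, boundary
inclusive).  Genes on the sex chromosomes are excluded before coding.
The two-character code is ordered H3K4me3 then H3K27me3: "00", "10", "01",
"11".
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from epidrift.consensus import MARKS, ConsensusPeak
from epidrift.errors import ArgumentError, InputError
from epidrift.synthetic import GeneModel

STATES = ("00", "10", "01", "11")

# tolerance for the >= min_overlap_frac comparison (floating-point guard only)
_EPS = 1e-9


def promoter_region(gene: GeneModel, flank: int = 1000) -> tuple[int, int]:
    """TSS +/- flank, clipped at position 0.  Half-open."""
    if flank < 0:
        raise ArgumentError("flank must be >= 0")
    return max(0, gene.tss - flank), gene.tss + flank


def gene_body_region(gene: GeneModel) -> tuple[int, int]:
    """The full gene span (TSS to last base), strand-independent."""
    return gene.start, gene.end


def _merged_regions(gene: GeneModel, flank: int) -> list[tuple[int, int]]:
    """Union of promoter and body as disjoint intervals."""
    ivs = sorted([promoter_region(gene, flank), gene_body_region(gene)])
    merged = [ivs[0]]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _overlap_with_regions(start: int, end: int, regions: Sequence[tuple[int, int]]) -> int:
    return sum(max(0, min(end, e) - max(start, s)) for s, e in regions)


def assign_modification(
    gene: GeneModel,
    peaks: Iterable[ConsensusPeak],
    min_overlap_frac: float = 0.05,
    flank: int = 1000,
    frac_of: str = "peak",
) -> int:
    """Binary mark call for one gene from one mark's consensus peaks.

    The overlap fraction is relative to the peak's breadth (``frac_of="peak"``,
    default) or to the promoter-union-body length (``frac_of="region"``).
    """
    if not 0.0 < min_overlap_frac <= 1.0:
        raise ArgumentError("min_overlap_frac must be in (0, 1]")
    if frac_of not in ("peak", "region"):
        raise ArgumentError(f"frac_of must be 'peak' or 'region', got {frac_of!r}")
    regions = _merged_regions(gene, flank)
    region_len = sum(e - s for s, e in regions)
    for p in peaks:
        if p.chrom != gene.chrom:
            continue
        ov = _overlap_with_regions(p.start, p.end, regions)
        denom = p.breadth if frac_of == "peak" else region_len
        if ov >= min_overlap_frac * denom - _EPS:
            return 1
    return 0


class _PeakIndex:
    """Per-chromosome sorted peak index for overlap candidate lookup."""

    def __init__(self, peaks: Iterable[ConsensusPeak]):
        self._by_chrom: dict[str, tuple[list[int], list[ConsensusPeak]]] = {}
        buckets: dict[str, list[ConsensusPeak]] = {}
        for p in peaks:
            buckets.setdefault(p.chrom, []).append(p)
        for chrom, plist in buckets.items():
            plist.sort(key=lambda p: p.start)
            self._by_chrom[chrom] = ([p.start for p in plist], plist)
        self._max_breadth = {c: max(p.breadth for p in v[1]) for c, v in self._by_chrom.items()}

    def overlapping(self, chrom: str, start: int, end: int) -> list[ConsensusPeak]:
        if chrom not in self._by_chrom:
            return []
        starts, plist = self._by_chrom[chrom]
        lo = bisect_left(starts, start - self._max_breadth[chrom])
        hi = bisect_left(starts, end)
        return [p for p in plist[lo:hi] if p.end > start]


@dataclass
class CodeMatrix:
    """Genes x samples table of two-bit modification codes (strings)."""

    codes: pd.DataFrame  # values in STATES

    def __post_init__(self) -> None:
        bad = set(np.unique(self.codes.values)) - set(STATES)
        if bad:
            raise InputError(f"invalid codes in matrix: {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.codes.index

    @property
    def samples(self) -> pd.Index:
        return self.codes.columns

    def bit(self, mark: str) -> pd.DataFrame:
        """0/1 integer frame for one mark."""
        pos = {"H3K4me3": 0, "H3K27me3": 1}
        if mark not in pos:
            raise ArgumentError(f"unknown mark {mark!r}")
        return self.codes.map(lambda s: int(s[pos[mark]]))

    def to_tsv(self, path) -> None:
        self.codes.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "CodeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id", dtype=str)
        return cls(codes=df)


def build_code_matrix(
    genes: Sequence[GeneModel],
    consensus_by_sample_mark: Mapping[tuple[str, str], Sequence[ConsensusPeak]],
    min_overlap_frac: float = 0.05,
    flank: int = 1000,
    frac_of: str = "peak",
) -> CodeMatrix:
    """Code every autosomal gene in every sample from the consensus peaks.

    ``consensus_by_sample_mark`` maps (sample_id, mark) to that sample's
    consensus peak list; every sample must provide both marks.
    """
    samples = sorted({s for s, _m in consensus_by_sample_mark})
    for s in samples:
        for mark in MARKS:
            if (s, mark) not in consensus_by_sample_mark:
                raise InputError(f"sample {s!r} is missing mark {mark!r}")

    kept = [g for g in genes if not g.is_sex_chrom]
    indexes = {
        (s, mark): _PeakIndex(consensus_by_sample_mark[(s, mark)])
        if consensus_by_sample_mark[(s, mark)]
        else None
        for s in samples
        for mark in MARKS
    }

    data: dict[str, list[str]] = {s: [] for s in samples}
    for g in kept:
        regions = _merged_regions(g, flank)
        span = (regions[0][0], regions[-1][1])
        for s in samples:
            bits = []
            for mark in MARKS:
                idx = indexes[(s, mark)]
                cand = idx.overlapping(g.chrom, *span) if idx is not None else []
                bits.append(
                    str(assign_modification(g, cand, min_overlap_frac, flank, frac_of))
                )
            data[s].append(bits[0] + bits[1])

    codes = pd.DataFrame(data, index=pd.Index([g.gene_id for g in kept], name="gene_id"))
    return CodeMatrix(codes=codes)


def state_frequencies(matrix: CodeMatrix) -> pd.DataFrame:
    """Per-sample distribution over the four states (rows sum to 1 per column)."""
    if matrix.codes.empty:
        raise ArgumentError("empty code matrix")
    out = {}
    n = len(matrix.genes)
    for s in matrix.samples:
        counts = matrix.codes[s].value_counts()
        out[s] = [counts.get(state, 0) / n for state in STATES]
    return pd.DataFrame(out, index=pd.Index(STATES, name="state"))


def peak_summary(
    genes: Sequence[GeneModel],
    consensus_by_sample_mark: Mapping[tuple[str, str], Sequence[ConsensusPeak]],
    min_overlap_frac: float = 0.05,
    flank: int = 1000,
) -> pd.DataFrame:
    """Per (sample, mark): total autosomal consensus peaks and how many are
    gene-associated (would count toward >= 1 gene's code)."""
    kept = [g for g in genes if not g.is_sex_chrom]
    rows = []
    for (sample, mark), peaks in sorted(consensus_by_sample_mark.items()):
        auto = [p for p in peaks if p.chrom.lower() not in {"chrx", "chry", "x", "y"}]
        n_assoc = 0
        for p in auto:
            for g in kept:
                if g.chrom != p.chrom:
                    continue
                regions = _merged_regions(g, flank)
                ov = _overlap_with_regions(p.start, p.end, regions)
                if ov >= min_overlap_frac * p.breadth - _EPS:
                    n_assoc += 1
                    break
        rows.append({"sample": sample, "mark": mark, "total": len(auto), "gene_associated": n_assoc})
    return pd.DataFrame(rows)
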