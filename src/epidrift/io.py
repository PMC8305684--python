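"""Plain-text readers/writers: BED6+ peak lists, refGene-like gene tables,
count matrices, sample sheets and GMT gene sets.  Coordinates are 0-based
half-open on disk and in memory; declare ``one_based=True`` on read for
1-based inputs.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from epidrift.consensus import ConsensusPeak, Peak
from epidrift.errors import InputError
from epidrift.synthetic import GeneModel
from epidrift.transcription import ExpressionMatrix, GeneSet

BED_COLUMNS = ("chrom", "start", "end", "name", "fold_enrichment", "strand", "breadth", "tag_density")


def write_peaks_bed(peaks: Sequence[Peak | ConsensusPeak], path: str | Path) -> None:
    """BED6+2: chrom, start, end, name, fold_enrichment score, '.', breadth,
    tag_density."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for i, p in enumerate(peaks):
            name = getattr(p, "support", None) or getattr(p, "sample_id", "") or f"peak{i}"
            w.writerow([p.chrom, p.start, p.end, name, f"{p.fold_enrichment:.6g}", ".",
                        p.breadth, f"{p.tag_density:.6g}"])


def read_peaks_bed(
    path: str | Path, mark: str, sample_id: str = "", one_based: bool = False
) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise InputError(f"{path}:{ln}: expected >= 5 BED columns")
            try:
                start = int(fields[1]) - (1 if one_based else 0)
                end = int(fields[2])
                fe = float(fields[4])
                density = float(fields[7]) if len(fields) > 7 else 0.0
            except ValueError as exc:
                raise InputError(f"{path}:{ln}: {exc}") from exc
            peaks.append(
                Peak(chrom=fields[0], start=start, end=end, fold_enrichment=fe,
                     tag_density=density, mark=mark, sample_id=sample_id)
            )
    return peaks


def read_consensus_bed(path: str | Path, mark: str, one_based: bool = False) -> list[ConsensusPeak]:
    out = []
    for p in read_peaks_bed(path, mark=mark, one_based=one_based):
        out.append(
            ConsensusPeak(chrom=p.chrom, start=p.start, end=p.end,
                          fold_enrichment=p.fold_enrichment, tag_density=p.tag_density,
                          mark=mark, support="both_replicates")
        )
    return out


def write_genes_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "chrom", "strand", "start", "end"])
        for g in genes:
            w.writerow([g.gene_id, g.chrom, g.strand, g.start, g.end])


def read_genes_tsv(path: str | Path, one_based: bool = False) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "start", "end"}
    if not required <= set(df.columns):
        raise InputError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise InputError(f"{path}: duplicate gene_id {dup!r}")
    off = 1 if one_based else 0
    return [
        GeneModel(gene_id=r.gene_id, chrom=r.chrom, strand=r.strand,
                  start=int(r.start) - off, end=int(r.end))
        for r in df.itertuples()
    ]


def write_counts_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.counts.copy()
    df.insert(0, "length", matrix.lengths.astype(int))
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "length" not in df.columns:
        raise InputError(f"{path}: missing 'length' column")
    lengths = df.pop("length").astype(float)
    return ExpressionMatrix(counts=df.astype(int), lengths=lengths)


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w", newline="") as fh:
        for name, ids in sets.items():
            fh.write("\t".join([name, description, *sorted(set(ids))]) + "\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{ln}: GMT lines need name, description, >= 1 gene")
            sets.append(GeneSet.from_ids(fields[0], fields[2:]))
    return sets


def write_sample_sheet(rows: Sequence[Mapping[str, str]], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition_class"}
    if not required <= set(df.columns):
        raise InputError(f"{path}: sample sheet needs columns {sorted(required)}")
    return df


def sample_classes(sheet: pd.DataFrame) -> dict[str, str]:
    return dict(zip(sheet["sample_id"], sheet["condition_class"]))
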