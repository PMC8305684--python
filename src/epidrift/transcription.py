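"""RNA-seq normalization (RPM/RPKM) and expression statistics: group log-ratio
Delta-log(T), pooled Welch tests per cluster, gene-set Z-scores, and
hypergeometric over-representation with Benjamini-Hochberg correction.

Conventions declared here (the knobs are explicit arguments): log base 10
everywhere; pseudocount 0.1 RPKM before every log transform; the gene-set
Z-score of a sample is the mean of the member genes' across-sample z-scores
(of log RPKM) multiplied by sqrt(set size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from epidrift.errors import ArgumentError, InputError

DEFAULT_PSEUDOCOUNT = 0.1


@dataclass
class ExpressionMatrix:
    """Genes x samples raw counts plus gene lengths (bases)."""

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise InputError("counts must be nonnegative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][:5].tolist()
            raise InputError(f"missing gene lengths, e.g. {missing}")
        if (self.lengths <= 0).any():
            raise InputError("gene lengths must be positive")

    def rpm(self) -> pd.DataFrame:
        return rpm(self.counts)

    def rpkm(self) -> pd.DataFrame:
        return rpkm(self.rpm(), self.lengths)


def rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to reads per million."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise InputError(f"zero-total sample columns: {zero.index.tolist()}")
    return counts * 1e6 / totals


def rpkm(rpm_matrix: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Normalize an RPM matrix by gene length in kilobases."""
    lengths = lengths.reindex(rpm_matrix.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:5].tolist()
        raise InputError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise InputError("gene lengths must be positive")
    return rpm_matrix.mul(1e3 / lengths, axis=0)


def delta_log_T(
    rpkm_matrix: pd.DataFrame,
    gene: str,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """log10 ratio of mean expression, group_b over group_a (positive =
    activated in b)."""
    if not len(group_a) or not len(group_b):
        raise ArgumentError("both groups must be non-empty")
    row = rpkm_matrix.loc[gene]
    mean_a = float(row[list(group_a)].mean())
    mean_b = float(row[list(group_b)].mean())
    return float(np.log10(mean_b + pseudocount) - np.log10(mean_a + pseudocount))


@dataclass(frozen=True)
class ExpressionTestResult:
    statistic: float
    pvalue: float
    n_genes: int
    degenerate: bool = False  # zero pooled variance; statistic/p not meaningful


def cluster_expression_test(
    rpkm_matrix: pd.DataFrame,
    cluster_genes: Iterable[str],
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ExpressionTestResult:
    """Welch two-sample t-test comparing a cluster's expression between groups.

    Each cluster gene contributes one observation per group: its mean log10
    RPKM over the group's samples.  The statistic is positive when group_b is
    higher.
    """
    genes = [g for g in cluster_genes if g in rpkm_matrix.index]
    if len(genes) < 2:
        raise ArgumentError("need >= 2 cluster genes present in the matrix")
    if not len(group_a) or not len(group_b):
        raise ArgumentError("both groups must be non-empty")
    log_x = np.log10(rpkm_matrix.loc[genes] + pseudocount)
    a = log_x[list(group_a)].mean(axis=1).to_numpy()
    b = log_x[list(group_b)].mean(axis=1).to_numpy()
    if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
        return ExpressionTestResult(statistic=0.0, pvalue=1.0, n_genes=len(genes), degenerate=True)
    res = stats.ttest_ind(b, a, equal_var=False)
    return ExpressionTestResult(statistic=float(res.statistic), pvalue=float(res.pvalue), n_genes=len(genes))


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ArgumentError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_ids(cls, name: str, ids: Iterable[str]) -> "GeneSet":
        return cls(name=name, gene_ids=frozenset(ids))


def gsz_score(
    gene_set: GeneSet,
    sample: str,
    rpkm_matrix: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float | None:
    """Gene-set Z-score of one sample.

    Each gene's log10 RPKM is z-scored across samples; the score is the set
    mean of these z-scores times sqrt(set size).  Genes absent from the matrix
    are skipped; a fully absent set yields ``None``.
    """
    if sample not in rpkm_matrix.columns:
        raise ArgumentError(f"unknown sample {sample!r}")
    present = sorted(gene_set.gene_ids & set(rpkm_matrix.index))
    if not present:
        return None
    log_x = np.log10(rpkm_matrix + pseudocount)
    mu = log_x.mean(axis=1)
    sd = log_x.std(axis=1, ddof=1)
    z = (log_x.sub(mu, axis=0)).div(sd.where(sd > 0, np.inf), axis=0)
    return float(z.loc[present, sample].mean() * np.sqrt(len(present)))


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    cluster_size: int
    set_size: int
    universe_size: int
    expected: float
    fold_enrichment: float  # NaN when expected overlap is 0
    pvalue: float


def enrichment_test(
    cluster_genes: Iterable[str], gene_set: GeneSet, universe: Iterable[str]
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation of ``gene_set`` in the cluster."""
    universe = set(universe)
    if not universe:
        raise ArgumentError("universe must be non-empty")
    cluster = set(cluster_genes)
    if not cluster <= universe:
        raise ArgumentError("cluster genes must be a subset of the universe")
    in_set = gene_set.gene_ids & universe
    if not in_set:
        raise ArgumentError(f"gene set {gene_set.name!r} does not intersect the universe")
    k = len(cluster & in_set)
    N, K, n = len(universe), len(in_set), len(cluster)
    pvalue = float(stats.hypergeom.sf(k - 1, N, K, n))
    expected = n * K / N
    fold = k / expected if expected > 0 else float("nan")
    return EnrichmentResult(
        set_name=gene_set.name,
        overlap=k,
        cluster_size=n,
        set_size=K,
        universe_size=N,
        expected=expected,
        fold_enrichment=fold,
        pvalue=pvalue,
    )


def enrichment_table(
    cluster_genes: Iterable[str], gene_sets: Sequence[GeneSet], universe: Iterable[str]
) -> pd.DataFrame:
    """Run :func:`enrichment_test` for each set and BH-adjust across sets."""
    cluster = set(cluster_genes)
    universe = set(universe)
    rows = [enrichment_test(cluster, s, universe) for s in gene_sets]
    df = pd.DataFrame(
        {
            "set_name": [r.set_name for r in rows],
            "overlap": [r.overlap for r in rows],
            "expected": [r.expected for r in rows],
            "fold_enrichment": [r.fold_enrichment for r in rows],
            "p": [r.pvalue for r in rows],
        }
    )
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1] if len(df) else []
    return df


def reliable_genes(rpkm_matrix: pd.DataFrame, min_mean_rpkm: float = 1.0) -> pd.Index:
    """Genes measured with sufficient reliability: mean RPKM over all samples
    at or above the cutoff."""
    return rpkm_matrix.index[rpkm_matrix.mean(axis=1) >= min_mean_rpkm]
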