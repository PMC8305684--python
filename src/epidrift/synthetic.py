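"""Synthetic genomes, planted modification states, noisy replicate peak calls
and state-coupled RNA counts.

Every emitter draws from a named substream of one root seed, so regenerating
one artifact never perturbs the others, and the dropout decision for a given
(gene, replicate) consumes the same uniform draw regardless of the dropout
probability (raising the probability can only remove peaks).

Planted cluster patterns (state per condition class, code order K4-K27):

=======  ========  ==========  =========
label    tissue    short-term  long-term
=======  ========  ==========  =========
a        10        10          10
b        01        01          01
c        10        00          00
d        00        01          01
e        11        01          01
f        11        10          10
g        11        11          10
h        00        00          10
=======  ========  ==========  =========

Unlabelled ("none") genes receive random per-condition states,
rejection-sampled so that no unlabelled gene accidentally satisfies one of
the eight patterns above.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from epidrift.consensus import MARKS, Peak
from epidrift.errors import ArgumentError
from epidrift.transcription import ExpressionMatrix

STATES = ("00", "10", "01", "11")
CONDITION_CLASSES = ("tissue", "short_term", "long_term")

#: label -> state per condition class (tissue, short_term, long_term)
CLUSTER_PATTERNS: dict[str, tuple[str, str, str]] = {
    "a": ("10", "10", "10"),
    "b": ("01", "01", "01"),
    "c": ("10", "00", "00"),
    "d": ("00", "01", "01"),
    "e": ("11", "01", "01"),
    "f": ("11", "10", "10"),
    "g": ("11", "11", "10"),
    "h": ("00", "00", "10"),
}

#: default mean expression per modification state (active > bivalent > repressed)
DEFAULT_STATE_EXPRESSION: dict[str, float] = {"10": 100.0, "11": 30.0, "01": 5.0, "00": 2.0}

SEX_CHROMS = frozenset({"chrx", "chry", "x", "y"})


@dataclass(frozen=True)
class GeneModel:
    """One gene: chromosome, strand, 0-based half-open span."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ArgumentError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ArgumentError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def is_sex_chrom(self) -> bool:
        return self.chrom.lower() in SEX_CHROMS


@dataclass(frozen=True)
class PlantedTruth:
    gene_id: str
    state_by_condition: Mapping[str, str]
    cluster_label: str  # one of a-h or "none"
    expression_mean_by_condition: Mapping[str, float]


@dataclass(frozen=True)
class NoiseParams:
    """Variability of the emitted replicate peak calls."""

    peak_dropout_prob: float = 0.0
    fe_median: float = 8.0  # lognormal median of fold enrichment
    fe_sigma: float = 0.5
    breadth_range: tuple[int, int] = (600, 2400)
    breadth_jitter: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.peak_dropout_prob <= 1.0:
            raise ArgumentError("peak_dropout_prob must be in [0, 1]")
        if self.breadth_jitter < 0:
            raise ArgumentError("breadth_jitter must be >= 0")
        if self.fe_median <= 0 or self.fe_sigma < 0:
            raise ArgumentError("fold-enrichment distribution parameters out of range")
        if self.breadth_range[0] < 2 or self.breadth_range[0] > self.breadth_range[1]:
            raise ArgumentError("invalid breadth_range")


def _substream(seed: int, *names: str) -> np.random.Generator:
    """Independent, reproducible generator keyed by (seed, names)."""
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng([int(seed) & 0xFFFFFFFF, *keys])


def generate_genome(
    n_genes: int,
    n_autosomes: int = 19,
    include_sex_chroms: bool = False,
    seed: int = 0,
    sex_fraction: float = 0.1,
    length_range: tuple[int, int] = (2000, 20000),
    gap_range: tuple[int, int] = (6000, 50000),
) -> list[GeneModel]:
    """Place ``n_genes`` non-overlapping genes on ``chr1..chrN`` (+ chrX/chrY).

    Genes are laid out left to right with random lengths and inter-gene gaps;
    ``sex_fraction`` of the genes go to the sex chromosomes when requested.
    Deterministic for a fixed seed.
    """
    if n_genes < 1 or n_autosomes < 1:
        raise ArgumentError("n_genes and n_autosomes must be >= 1")
    if not 0.0 <= sex_fraction <= 1.0:
        raise ArgumentError("sex_fraction must be in [0, 1]")

    rng = _substream(seed, "genome")
    n_sex = round(n_genes * sex_fraction) if include_sex_chroms else 0
    chroms = [f"chr{i}" for i in range(1, n_autosomes + 1)]

    # round-robin autosomal assignment; sex genes split between chrX / chrY
    assignment = [chroms[i % n_autosomes] for i in range(n_genes - n_sex)]
    assignment += ["chrX" if i % 2 == 0 else "chrY" for i in range(n_sex)]

    cursor: dict[str, int] = {}
    genes: list[GeneModel] = []
    for i, chrom in enumerate(assignment):
        gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        start = cursor.get(chrom, 0) + gap
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(gene_id=f"gene{i:05d}", chrom=chrom, strand=strand, start=start, end=start + length)
        )
        cursor[chrom] = start + length
    return genes


def _condition_classes(
    conditions: Sequence[str], condition_classes: Mapping[str, str] | None
) -> dict[str, str]:
    if condition_classes is None:
        condition_classes = {}
        for c in conditions:
            low = c.lower()
            if "tissue" in low:
                condition_classes[c] = "tissue"
            elif "short" in low:
                condition_classes[c] = "short_term"
            elif "long" in low:
                condition_classes[c] = "long_term"
            else:
                raise ArgumentError(
                    f"cannot infer condition class from name {c!r}; pass condition_classes"
                )
    out = {c: condition_classes[c] for c in conditions}
    for c, cls in out.items():
        if cls not in CONDITION_CLASSES:
            raise ArgumentError(f"unknown condition class {cls!r} for condition {c!r}")
    missing = set(CONDITION_CLASSES) - set(out.values())
    if missing:
        raise ArgumentError(f"conditions must cover all classes; missing {sorted(missing)}")
    return out


def _matches_any_pattern(states: Mapping[str, str], classes: Mapping[str, str]) -> bool:
    class_idx = {cls: i for i, cls in enumerate(CONDITION_CLASSES)}
    for pattern in CLUSTER_PATTERNS.values():
        if all(states[c] == pattern[class_idx[classes[c]]] for c in states):
            return True
    return False


def plant_scenario(
    genes: Sequence[GeneModel],
    conditions: Sequence[str],
    cluster_sizes: Mapping[str, int],
    seed: int = 0,
    condition_classes: Mapping[str, str] | None = None,
    state_expression: Mapping[str, float] | None = None,
) -> list[PlantedTruth]:
    """Assign each gene a cluster label, per-condition states and expression means.

    ``cluster_sizes`` maps labels a-h to gene counts; labelled genes are drawn
    from the autosomal genes only (sex-chromosome genes are excluded downstream,
    so planting them there would make the truth unrecoverable by design).
    Expression means follow the per-state coupling in
    :data:`DEFAULT_STATE_EXPRESSION`.
    """
    classes = _condition_classes(conditions, condition_classes)
    expr = dict(DEFAULT_STATE_EXPRESSION if state_expression is None else state_expression)
    unknown = set(cluster_sizes) - set(CLUSTER_PATTERNS)
    if unknown:
        raise ArgumentError(f"unknown cluster labels: {sorted(unknown)}")
    if any(n < 0 for n in cluster_sizes.values()):
        raise ArgumentError("cluster sizes must be nonnegative")

    autosomal = [g for g in genes if not g.is_sex_chrom]
    n_labelled = sum(cluster_sizes.values())
    if n_labelled > len(autosomal):
        raise ArgumentError(
            f"cluster_sizes request {n_labelled} genes but only {len(autosomal)} autosomal genes exist"
        )

    rng = _substream(seed, "scenario")
    order = rng.permutation(len(autosomal))
    label_of: dict[str, str] = {}
    pos = 0
    for label in sorted(cluster_sizes):
        for _ in range(cluster_sizes[label]):
            label_of[autosomal[order[pos]].gene_id] = label
            pos += 1

    class_idx = {cls: i for i, cls in enumerate(CONDITION_CLASSES)}
    truths: list[PlantedTruth] = []
    for g in genes:
        label = label_of.get(g.gene_id, "none")
        if label != "none":
            pattern = CLUSTER_PATTERNS[label]
            states = {c: pattern[class_idx[classes[c]]] for c in conditions}
        else:
            # rejection-sample so background genes never mimic a planted pattern
            for _ in range(1000):
                states = {c: STATES[rng.integers(0, 4)] for c in conditions}
                if not _matches_any_pattern(states, classes):
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not draw a non-pattern background state")
        means = {c: float(expr[states[c]]) for c in conditions}
        truths.append(
            PlantedTruth(
                gene_id=g.gene_id,
                state_by_condition=states,
                cluster_label=label,
                expression_mean_by_condition=means,
            )
        )
    return truths


def _mark_bit(state: str, mark: str) -> int:
    if mark == "H3K4me3":
        return int(state[0])
    if mark == "H3K27me3":
        return int(state[1])
    raise ArgumentError(f"unknown mark {mark!r}; expected one of {MARKS}")


def emit_replicate_peaks(
    truth: Sequence[PlantedTruth],
    genes: Sequence[GeneModel],
    mark: str,
    condition: str,
    noise: NoiseParams,
    flank: int = 1000,
) -> tuple[list[Peak], list[Peak]]:
    """Emit two noisy replicate peak lists for one (condition, mark).

    Each gene whose planted state carries the mark yields one promoter-centred
    peak per replicate unless that replicate's dropout draw removes it.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    missing = [t.gene_id for t in truth if t.gene_id not in gene_by_id]
    if missing:
        raise ArgumentError(f"truth references unknown genes: {missing[:5]}")
    if truth and condition not in truth[0].state_by_condition:
        raise ArgumentError(f"unknown condition {condition!r}")

    rng_drop = _substream(noise.seed, "dropout", mark, condition)
    rng_shape = _substream(noise.seed, "shape", mark, condition)

    replicates: tuple[list[Peak], list[Peak]] = ([], [])
    lo, hi = noise.breadth_range
    for t in truth:
        bit = _mark_bit(t.state_by_condition[condition], mark)
        # one shape per gene, shared by both replicates, so that zero noise
        # yields byte-identical replicate lists; draws are always consumed so
        # noise knobs act independently of each other
        breadth = int(rng_shape.integers(lo, hi + 1))
        fe = float(noise.fe_median * np.exp(noise.fe_sigma * rng_shape.standard_normal()))
        density = float(fe * (1.0 + 0.1 * rng_shape.random()))
        for rep in (0, 1):
            u = rng_drop.random()
            jitter = (
                int(rng_shape.integers(-noise.breadth_jitter, noise.breadth_jitter + 1))
                if noise.breadth_jitter
                else 0
            )
            if bit == 0 or u < noise.peak_dropout_prob:
                continue
            g = gene_by_id[t.gene_id]
            start = max(0, g.tss - breadth // 2 + jitter)
            replicates[rep].append(
                Peak(
                    chrom=g.chrom,
                    start=start,
                    end=start + breadth,
                    fold_enrichment=fe,
                    tag_density=density,
                    mark=mark,
                    sample_id=f"{condition}_rep{rep + 1}",
                )
            )
    return replicates


def emit_counts(
    truth: Sequence[PlantedTruth],
    samples: Sequence[tuple[str, int]],
    dispersion: float = 0.05,
    library_size: int = 1_000_000,
    seed: int = 0,
    genes: Sequence[GeneModel] | None = None,
) -> ExpressionMatrix:
    """Draw a negative-binomial count matrix whose means track the planted truth.

    ``samples`` is a list of (condition, replicate) pairs; columns are named
    ``{condition}_rep{replicate}``.  Per-gene means are the planted expression
    means rescaled so each column's expectation sums to ``library_size``.
    Variance is ``m + dispersion * m**2``.
    """
    if not samples:
        raise ArgumentError("samples must be non-empty")
    if dispersion <= 0:
        raise ArgumentError("dispersion must be positive")

    rng = _substream(seed, "counts")
    gene_ids = [t.gene_id for t in truth]
    cols = [f"{cond}_rep{rep}" for cond, rep in samples]
    means = np.empty((len(truth), len(samples)), dtype=float)
    for i, t in enumerate(truth):
        for j, (cond, _rep) in enumerate(samples):
            if cond not in t.expression_mean_by_condition:
                raise ArgumentError(f"condition {cond!r} missing from planted truth")
            means[i, j] = t.expression_mean_by_condition[cond]

    col_tot = means.sum(axis=0)
    col_tot[col_tot == 0] = 1.0
    m = means / col_tot * library_size

    n_param = 1.0 / dispersion
    p_param = n_param / (n_param + np.where(m > 0, m, 1.0))
    counts = np.where(m > 0, rng.negative_binomial(n_param, p_param), 0)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=cols, dtype=int)
    if genes is not None:
        lengths = pd.Series({g.gene_id: g.length for g in genes}).reindex(gene_ids)
    else:
        lengths = pd.Series(1000, index=gene_ids, dtype=float)
    return ExpressionMatrix(counts=counts_df, lengths=lengths.astype(float))
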