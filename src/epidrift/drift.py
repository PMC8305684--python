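"""Combinatorial state-transition ("drift") calling.

A gene belongs to a transition cluster iff it shows the rule's from-state in
EVERY group-A sample and its to-state in EVERY group-B sample — strict
all-sample consistency.  Constant clusters (a, b) use identical from/to
states.  This deterministic caller is the authority for cluster membership;
the SOM route is discovery/visualization.

Standard clusters (code order K4-K27):
  a: (10) everywhere            b: (01) everywhere
  c: tissue (10) -> organoid (00)   d: (00) -> (01)
  e: (11) -> (01)                   f: (11) -> (10)
  g: tissue+short-term (11) -> long-term (10)
  h: tissue+short-term (00) -> long-term (10)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from epidrift.annotation import STATES, CodeMatrix
from epidrift.errors import ArgumentError, ConfigurationError

CLUSTER_LABELS = ("a", "b", "c", "d", "e", "f", "g", "h")
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class TransitionRule:
    label: str
    from_state: str
    to_state: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.from_state not in STATES or self.to_state not in STATES:
            raise ArgumentError(f"rule {self.label}: states must be one of {STATES}")
        if not self.group_a or not self.group_b:
            raise ArgumentError(f"rule {self.label}: both groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ArgumentError(f"rule {self.label}: groups must be disjoint")


@dataclass(frozen=True)
class DriftCall:
    gene_id: str
    label: str  # a-h or "unclassified"
    code_trail: tuple[str, ...]  # per-sample codes in matrix column order


def call_transitions(matrix: CodeMatrix, rules: Sequence[TransitionRule]) -> list[DriftCall]:
    """Label every gene by the unique rule it satisfies, else unclassified.

    Raises :class:`ConfigurationError` if any gene satisfies two rules — the
    rule set, not the gene, is at fault.
    """
    samples = set(matrix.samples)
    for r in rules:
        missing = (set(r.group_a) | set(r.group_b)) - samples
        if missing:
            raise ConfigurationError(f"rule {r.label}: unknown samples {sorted(missing)}")

    codes = matrix.codes
    masks = pd.DataFrame(index=codes.index)
    for r in rules:
        m_a = (codes[list(r.group_a)] == r.from_state).all(axis=1)
        m_b = (codes[list(r.group_b)] == r.to_state).all(axis=1)
        masks[r.label] = m_a & m_b

    n_hits = masks.sum(axis=1)
    if (n_hits > 1).any():
        offenders = masks.index[n_hits > 1][:5].tolist()
        raise ConfigurationError(
            f"rules overlap: genes matching more than one rule, e.g. {offenders}"
        )

    labels = pd.Series(UNCLASSIFIED, index=codes.index)
    for r in rules:
        labels[masks[r.label]] = r.label

    trails = codes.apply(tuple, axis=1)
    return [
        DriftCall(gene_id=g, label=labels[g], code_trail=trails[g]) for g in codes.index
    ]


def calls_frame(calls: Iterable[DriftCall]) -> pd.DataFrame:
    calls = list(calls)
    return pd.DataFrame(
        {"gene_id": [c.gene_id for c in calls], "label": [c.label for c in calls]}
    ).set_index("gene_id")


def _groups_by_class(sample_classes: Mapping[str, str]) -> dict[str, tuple[str, ...]]:
    groups: dict[str, list[str]] = {"tissue": [], "short_term": [], "long_term": []}
    for sample, cls in sample_classes.items():
        if cls not in groups:
            raise ConfigurationError(f"sample {sample!r} has unknown condition class {cls!r}")
    for sample in sorted(sample_classes):
        groups[sample_classes[sample]].append(sample)
    return {k: tuple(v) for k, v in groups.items()}


def tissue_organoid_rules(sample_classes: Mapping[str, str]) -> list[TransitionRule]:
    """Rules a-f: constant states plus tissue -> organoid transitions."""
    g = _groups_by_class(sample_classes)
    tissue, organoid = g["tissue"], g["short_term"] + g["long_term"]
    if not tissue or not organoid:
        raise ConfigurationError("need tissue and organoid samples")
    spec = [("a", "10", "10"), ("b", "01", "01"), ("c", "10", "00"),
            ("d", "00", "01"), ("e", "11", "01"), ("f", "11", "10")]
    return [
        TransitionRule(label, fs, ts, group_a=tissue, group_b=organoid)
        for label, fs, ts in spec
    ]


def longterm_rules(
    sample_classes: Mapping[str, str], include_tissue: bool = True
) -> list[TransitionRule]:
    """Rules g ((11) -> (10)) and h ((00) -> (10)) into the long-term group.

    ``include_tissue`` controls whether the from-state is also required in the
    tissue samples (default) or in the short-term organoids only.
    """
    g = _groups_by_class(sample_classes)
    group_a = (g["tissue"] + g["short_term"]) if include_tissue else g["short_term"]
    group_b = g["long_term"]
    if not group_a or not group_b:
        raise ConfigurationError("need short-term (and tissue) plus long-term samples")
    return [
        TransitionRule("g", "11", "10", group_a=group_a, group_b=group_b),
        TransitionRule("h", "00", "10", group_a=group_a, group_b=group_b),
    ]


def default_rules(sample_classes: Mapping[str, str], include_tissue: bool = True) -> list[TransitionRule]:
    """The full a-h rule set for a tissue / short-term / long-term sample sheet."""
    return tissue_organoid_rules(sample_classes) + longterm_rules(sample_classes, include_tissue)


def cluster_modification_average(
    calls: Iterable[DriftCall],
    matrix: CodeMatrix,
    mark: str,
    sample: str,
    label: str,
) -> float | None:
    """Mean 0/1 level of one mark over a cluster's genes in one sample;
    ``None`` for an empty cluster."""
    genes = [c.gene_id for c in calls if c.label == label]
    if not genes:
        return None
    bits = matrix.bit(mark)
    return float(bits.loc[genes, sample].mean())
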