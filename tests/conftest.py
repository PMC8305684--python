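import numpy as np
import pandas as pd
import pytest

from epidrift import annotation, synthetic
from epidrift.consensus import MARKS, build_summary_peaks

CONDITIONS = {
    "tissue_1": "tissue",
    "tissue_2": "tissue",
    "org_short": "short_term",
    "org_long": "long_term",
}

CLUSTER_SIZES = {"a": 150, "b": 80, "c": 60, "d": 40, "e": 50, "f": 45, "g": 30, "h": 35}


@pytest.fixture(scope="session")
def conditions():
    return dict(CONDITIONS)


@pytest.fixture(scope="session")
def small_genome():
    return synthetic.generate_genome(600, n_autosomes=5, include_sex_chroms=True,
                                     sex_fraction=0.05, seed=1)


@pytest.fixture(scope="session")
def planted_truth(small_genome, conditions):
    return synthetic.plant_scenario(
        small_genome, list(conditions), CLUSTER_SIZES, seed=2,
        condition_classes=conditions,
    )


@pytest.fixture(scope="session")
def planted_by_label(planted_truth):
    out: dict[str, set[str]] = {}
    for t in planted_truth:
        out.setdefault(t.cluster_label, set()).add(t.gene_id)
    return out


def build_consensus(truth, genes, conditions, noise, rescue=True, fe_threshold=5.0):
    """Emit replicate peaks for every (condition, mark) and summarize them."""
    out = {}
    for cond in conditions:
        for mark in MARKS:
            rep1, rep2 = synthetic.emit_replicate_peaks(truth, genes, mark, cond, noise)
            out[(cond, mark)] = build_summary_peaks(
                rep1, rep2, fe_threshold=fe_threshold, rescue=rescue
            )
    return out


@pytest.fixture(scope="session")
def zero_noise_consensus(planted_truth, small_genome, conditions):
    return build_consensus(planted_truth, small_genome, conditions,
                           synthetic.NoiseParams(seed=3))


@pytest.fixture(scope="session")
def zero_noise_codes(small_genome, zero_noise_consensus):
    return annotation.build_code_matrix(small_genome, zero_noise_consensus)
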