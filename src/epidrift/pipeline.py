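"""End-to-end orchestration of the synthetic scenario: simulate -> consensus
-> encode -> drift -> SOM -> expression, with every intermediate written as a
plain-text artifact and a JSON manifest recording parameters, seeds and
checksums.  Stages communicate only through files, so real data can be
injected at any boundary via the stage CLI subcommands.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from epidrift import annotation, drift, io, som, synthetic, transcription
from epidrift.errors import ConfigurationError


@dataclass
class RunConfig:
    """Parameters of a full synthetic run."""

    outdir: str = "epidrift_run"
    seed: int = 0
    # scenario
    n_genes: int = 2000
    n_autosomes: int = 19
    include_sex_chroms: bool = True
    sex_fraction: float = 0.05
    conditions: dict[str, str] = field(
        default_factory=lambda: {
            "tissue": "tissue",
            "organoid_short": "short_term",
            "organoid_long": "long_term",
        }
    )
    cluster_sizes: dict[str, int] = field(
        default_factory=lambda: {"c": 60, "d": 30, "e": 50, "f": 40, "g": 25, "h": 35}
    )
    rna_replicates: int = 2
    # noise
    peak_dropout_prob: float = 0.0
    fe_median: float = 8.0
    fe_sigma: float = 0.5
    breadth_jitter: int = 0
    dispersion: float = 0.05
    library_size: int = 1_000_000
    # thresholds
    fe_threshold: float = 5.0
    rescue: bool = True
    flank: int = 1000
    min_overlap_frac: float = 0.05
    pseudocount: float = 0.1
    # SOM
    som_rows: int = 8
    som_cols: int = 8
    som_epochs: int = 30
    # optional external inputs (real mode is driven via stage subcommands)
    sample_sheet: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """Return human-readable violations without executing anything."""
    v: list[str] = []
    if config.n_genes < 1:
        v.append("n_genes must be >= 1")
    if config.n_autosomes < 1:
        v.append("n_autosomes must be >= 1")
    if not 0.0 < config.min_overlap_frac <= 1.0:
        v.append("min_overlap_frac must be in (0, 1]")
    if config.fe_threshold <= 0:
        v.append("fe_threshold must be positive")
    if config.flank < 0:
        v.append("flank must be >= 0")
    if not 0.0 <= config.peak_dropout_prob <= 1.0:
        v.append("peak_dropout_prob must be in [0, 1]")
    if config.dispersion <= 0:
        v.append("dispersion must be positive")
    if config.pseudocount <= 0:
        v.append("pseudocount must be positive")
    if config.som_rows < 1 or config.som_cols < 1 or config.som_epochs < 1:
        v.append("SOM grid dimensions and epochs must be >= 1")
    if config.rna_replicates < 1:
        v.append("rna_replicates must be >= 1")
    classes = set(config.conditions.values())
    if not {"tissue", "short_term", "long_term"} <= classes:
        v.append("conditions must cover tissue, short_term and long_term classes")
    if sum(config.cluster_sizes.values()) > config.n_genes:
        v.append("cluster_sizes oversubscribe n_genes")
    if config.sample_sheet is not None and not Path(config.sample_sheet).exists():
        v.append(f"sample sheet path does not exist: {config.sample_sheet}")
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _precision_recall(truth_labels: dict[str, str], called: dict[str, str]) -> dict[str, dict[str, float]]:
    out = {}
    for label in sorted(set(truth_labels.values()) - {"none"}):
        planted = {g for g, l in truth_labels.items() if l == label}
        predicted = {g for g, l in called.items() if l == label}
        tp = len(planted & predicted)
        out[label] = {
            "recall": tp / len(planted) if planted else float("nan"),
            "precision": tp / len(predicted) if predicted else float("nan"),
            "n_planted": len(planted),
            "n_called": len(predicted),
        }
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full synthetic pipeline; returns (and writes) the manifest."""
    violations = validate_config(config)
    if violations:
        raise ConfigurationError("; ".join(violations))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        artifacts[name] = str(path)
        return path

    # --- simulate -----------------------------------------------------------
    genes = synthetic.generate_genome(
        config.n_genes,
        config.n_autosomes,
        include_sex_chroms=config.include_sex_chroms,
        sex_fraction=config.sex_fraction,
        seed=config.seed,
    )
    conditions = list(config.conditions)
    truth = synthetic.plant_scenario(
        genes, conditions, config.cluster_sizes, seed=config.seed,
        condition_classes=config.conditions,
    )
    save("genes.tsv", lambda p: io.write_genes_tsv(genes, p))
    truth_labels = {t.gene_id: t.cluster_label for t in truth}
    save(
        "truth.tsv",
        lambda p: pd.DataFrame(
            {
                "gene_id": [t.gene_id for t in truth],
                "cluster_label": [t.cluster_label for t in truth],
                **{f"state_{c}": [t.state_by_condition[c] for t in truth] for c in conditions},
            }
        ).to_csv(p, sep="\t", index=False),
    )

    noise = synthetic.NoiseParams(
        peak_dropout_prob=config.peak_dropout_prob,
        fe_median=config.fe_median,
        fe_sigma=config.fe_sigma,
        breadth_jitter=config.breadth_jitter,
        seed=config.seed,
    )

    # --- consensus + encode -------------------------------------------------
    from epidrift.consensus import build_summary_peaks

    consensus_by_sample_mark = {}
    for cond in conditions:
        for mark in synthetic.MARKS:
            rep1, rep2 = synthetic.emit_replicate_peaks(
                truth, genes, mark, cond, noise, flank=config.flank
            )
            tag = f"{cond}.{mark}"
            save(f"peaks.{tag}.rep1.bed", lambda p, r=rep1: io.write_peaks_bed(r, p))
            save(f"peaks.{tag}.rep2.bed", lambda p, r=rep2: io.write_peaks_bed(r, p))
            cons = build_summary_peaks(
                rep1, rep2, fe_threshold=config.fe_threshold, rescue=config.rescue
            )
            save(f"consensus.{tag}.bed", lambda p, c=cons: io.write_peaks_bed(c, p))
            consensus_by_sample_mark[(cond, mark)] = cons

    matrix = annotation.build_code_matrix(
        genes, consensus_by_sample_mark,
        min_overlap_frac=config.min_overlap_frac, flank=config.flank,
    )
    save("codes.tsv", matrix.to_tsv)
    freqs = annotation.state_frequencies(matrix)
    save("state_frequencies.tsv", lambda p: freqs.to_csv(p, sep="\t"))

    # --- drift calling ------------------------------------------------------
    rules = drift.default_rules(config.conditions)
    calls = drift.call_transitions(matrix, rules)
    frame = drift.calls_frame(calls)
    save("drift_calls.tsv", lambda p: frame.to_csv(p, sep="\t"))
    cluster_sets = {
        label: [c.gene_id for c in calls if c.label == label]
        for label in drift.CLUSTER_LABELS
    }
    save("drift_clusters.gmt",
         lambda p: io.write_gmt({k: v for k, v in cluster_sets.items() if v}, p))
    metrics = _precision_recall(truth_labels, {c.gene_id: c.label for c in calls})

    # --- SOM ----------------------------------------------------------------
    profiles = som.expand_code_matrix(matrix)
    model = som.train_som(
        profiles, grid_rows=config.som_rows, grid_cols=config.som_cols,
        epochs=config.som_epochs, seed=config.seed,
    )
    save("som_units.tsv", lambda p: model.gene_to_unit.to_csv(p, sep="\t"))
    tree = som.correlation_spanning_tree(model)
    save(
        "som_tree.tsv",
        lambda p: pd.DataFrame(
            [(u, v, d["correlation"]) for u, v, d in tree.edges(data=True)],
            columns=["a", "b", "correlation"],
        ).to_csv(p, sep="\t", index=False),
    )

    # --- expression ---------------------------------------------------------
    samples = [(c, r + 1) for c in conditions for r in range(config.rna_replicates)]
    expr = synthetic.emit_counts(
        truth, samples, dispersion=config.dispersion,
        library_size=config.library_size, seed=config.seed, genes=genes,
    )
    save("counts.tsv", lambda p: io.write_counts_tsv(expr, p))
    rpkm = expr.rpkm()
    save("rpkm.tsv", lambda p: rpkm.to_csv(p, sep="\t", index_label="gene_id"))

    tissue_cols = [f"{c}_rep{r + 1}" for c in conditions for r in range(config.rna_replicates)
                   if config.conditions[c] == "tissue"]
    short_cols = [f"{c}_rep{r + 1}" for c in conditions for r in range(config.rna_replicates)
                  if config.conditions[c] == "short_term"]
    expr_tests = {}
    for label in ("c", "e"):
        gene_list = cluster_sets.get(label, [])
        if len(gene_list) >= 2 and tissue_cols and short_cols:
            res = transcription.cluster_expression_test(
                rpkm, gene_list, tissue_cols, short_cols, pseudocount=config.pseudocount
            )
            expr_tests[label] = {"statistic": res.statistic, "pvalue": res.pvalue, "n": res.n_genes}

    manifest = {
        "config": dataclasses.asdict(config),
        "artifacts": {name: _sha256(outdir / name) for name in artifacts},
        "drift_metrics": metrics,
        "expression_tests": expr_tests,
        "som_quantization_error": model.qe_history[-1] if model.qe_history else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
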