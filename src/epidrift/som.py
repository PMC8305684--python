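"""Self-organizing-map profile clustering: metagene grids, sample portraits,
correlation clusters, under-expression spots, K-means landscape partitions and
the correlation spanning tree of samples.

The trainer is a plain batch SOM (per-epoch best-matching-unit assignment, then
Gaussian-neighborhood weighted mean update) with a linearly decaying radius; an
online variant with a decaying learning rate is available.  Binary code
matrices should be expanded to one numeric column per (sample, mark) before
training — see :func:`expand_code_matrix` — so each mark stays readable as a
metagene value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from epidrift.annotation import CodeMatrix
from epidrift.errors import ArgumentError, InputError


@dataclass
class SOMModel:
    grid_rows: int
    grid_cols: int
    weights: np.ndarray  # (n_units, n_features)
    feature_names: list[str]
    gene_to_unit: pd.Series  # gene_id -> flat unit index (row-major)
    training_params: dict = field(default_factory=dict)
    qe_history: list[float] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    def unit_coords(self) -> np.ndarray:
        """(n_units, 2) row/col coordinates, row-major flat order."""
        r, c = np.divmod(np.arange(self.n_units), self.grid_cols)
        return np.column_stack([r, c])

    def genes_in_units(self, units: set[int]) -> list[str]:
        mask = self.gene_to_unit.isin(list(units))
        return self.gene_to_unit.index[mask].tolist()


@dataclass
class SpotSet:
    kind: Literal["correlation_cluster", "underexpression_spot", "kmeans_cluster"]
    spots: list[set[int]]  # unit indices per spot
    member_genes: list[list[str]]

    def __len__(self) -> int:
        return len(self.spots)


def expand_code_matrix(matrix: CodeMatrix) -> pd.DataFrame:
    """Two numeric columns per sample ("<sample>|K4", "<sample>|K27")."""
    cols = {}
    for s in matrix.samples:
        cols[f"{s}|K4"] = matrix.codes[s].str[0].astype(float)
        cols[f"{s}|K27"] = matrix.codes[s].str[1].astype(float)
    return pd.DataFrame(cols, index=matrix.genes)


def _grid_sq_dists(rows: int, cols: int) -> np.ndarray:
    r, c = np.divmod(np.arange(rows * cols), cols)
    coords = np.column_stack([r, c]).astype(float)
    return cdist(coords, coords, "sqeuclidean")


def _bmu(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    # argmin breaks distance ties toward the lowest unit index
    return np.argmin(cdist(X, W, "sqeuclidean"), axis=1)


def train_som(
    profiles: pd.DataFrame,
    grid_rows: int = 30,
    grid_cols: int = 30,
    epochs: int = 50,
    variant: Literal["batch", "online"] = "batch",
    radius_start: float | None = None,
    radius_end: float = 0.5,
    lr_start: float = 0.05,
    lr_end: float = 0.01,
    seed: int = 0,
) -> SOMModel:
    """Train a SOM on a genes x samples (or expanded-code) matrix.

    Weights are initialized uniformly within each feature's data range;
    the Gaussian neighborhood radius decays linearly from half the grid
    diagonal (default) to ``radius_end``.  Deterministic per seed.
    """
    if profiles.shape[0] < 1 or profiles.shape[1] < 2:
        raise ArgumentError("need >= 1 gene and >= 2 feature columns")
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise InputError("profiles contain non-finite values")
    if grid_rows < 1 or grid_cols < 1 or epochs < 1:
        raise ArgumentError("grid dimensions and epochs must be >= 1")

    rng = np.random.default_rng(seed)
    n_units = grid_rows * grid_cols
    lo, hi = X.min(axis=0), X.max(axis=0)
    W = rng.uniform(lo, hi, size=(n_units, X.shape[1]))

    if radius_start is None:
        radius_start = 0.5 * float(np.hypot(grid_rows - 1, grid_cols - 1))
        radius_start = max(radius_start, radius_end)
    grid_d2 = _grid_sq_dists(grid_rows, grid_cols)
    r, c = np.divmod(np.arange(n_units), grid_cols)
    coords = np.column_stack([r, c]).astype(float)

    qe_history: list[float] = []
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        radius = radius_start + frac * (radius_end - radius_start)
        h_all = np.exp(-grid_d2 / (2.0 * radius * radius))  # (unit, unit)
        if variant == "batch":
            bmu = _bmu(X, W)
            M = h_all[bmu]  # (gene, unit): influence of each gene on each unit
            denom = M.sum(axis=0)
            num = M.T @ X
            upd = denom > 1e-12
            W[upd] = num[upd] / denom[upd, None]
        elif variant == "online":
            lr = lr_start + frac * (lr_end - lr_start)
            for g in rng.permutation(X.shape[0]):
                b = int(np.argmin(((W - X[g]) ** 2).sum(axis=1)))
                W += lr * h_all[b][:, None] * (X[g] - W)
        else:
            raise ArgumentError(f"unknown variant {variant!r}")
        d = cdist(X, W)
        qe_history.append(float(d.min(axis=1).mean()))

    bmu = _bmu(X, W)
    gene_to_unit = pd.Series(bmu, index=profiles.index, name="unit")
    return SOMModel(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        weights=W,
        feature_names=list(profiles.columns),
        gene_to_unit=gene_to_unit,
        training_params={
            "epochs": epochs,
            "variant": variant,
            "radius_start": radius_start,
            "radius_end": radius_end,
            "lr_start": lr_start,
            "lr_end": lr_end,
            "seed": seed,
        },
        qe_history=qe_history,
    )


def sample_portrait(som: SOMModel, sample: str) -> np.ndarray:
    """One feature column of the weights, reshaped to the grid."""
    if sample not in som.feature_names:
        raise ArgumentError(f"unknown sample/feature {sample!r}")
    j = som.feature_names.index(sample)
    return som.weights[:, j].reshape(som.grid_rows, som.grid_cols)


def _neighbor_pairs(rows: int, cols: int) -> list[tuple[int, int]]:
    """8-neighborhood adjacent unit pairs (each once)."""
    pairs = []
    for r in range(rows):
        for c in range(cols):
            u = r * cols + c
            for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    pairs.append((u, rr * cols + cc))
    return pairs


def _profile_correlation(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _components(units: set[int], rows: int, cols: int) -> list[set[int]]:
    g = nx.Graph()
    g.add_nodes_from(units)
    for u, v in _neighbor_pairs(rows, cols):
        if u in units and v in units:
            g.add_edge(u, v)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def correlation_clusters(som: SOMModel, threshold: float = 0.95) -> SpotSet:
    """Connected groups of adjacent units whose metagenes correlate above the
    threshold.

    A unit with no qualifying edge forms its own cluster iff its (perfect)
    self-correlation of 1 exceeds the threshold, so a threshold above 1 yields
    no clusters at all.
    """
    g = nx.Graph()
    if 1.0 > threshold:
        g.add_nodes_from(range(som.n_units))
    for u, v in _neighbor_pairs(som.grid_rows, som.grid_cols):
        if _profile_correlation(som.weights[u], som.weights[v]) > threshold:
            g.add_edge(u, v)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return SpotSet(
        kind="correlation_cluster",
        spots=comps,
        member_genes=[som.genes_in_units(c) for c in comps],
    )


def underexpression_spots(
    som: SOMModel,
    low_features: Sequence[str],
    high_features: Sequence[str],
    quantile: float = 0.1,
    min_contrast: float = 0.2,
) -> SpotSet:
    """Connected unit groups depressed in one feature group but not another.

    A unit qualifies when its mean weight over ``low_features`` is at or below
    the given quantile of that mean across units AND its mean over
    ``high_features`` exceeds the low mean by at least ``min_contrast``.
    Lowering the quantile can only shrink the qualifying set.
    """
    if not 0.0 <= quantile <= 1.0:
        raise ArgumentError("quantile must be in [0, 1]")
    idx_low = [som.feature_names.index(f) for f in low_features]
    idx_high = [som.feature_names.index(f) for f in high_features]
    if not idx_low or not idx_high:
        raise ArgumentError("both feature groups must be non-empty")
    mean_low = som.weights[:, idx_low].mean(axis=1)
    mean_high = som.weights[:, idx_high].mean(axis=1)
    thresh = float(np.quantile(mean_low, quantile))
    qualifying = set(np.flatnonzero((mean_low <= thresh) & (mean_high - mean_low >= min_contrast)).tolist())
    comps = _components(qualifying, som.grid_rows, som.grid_cols)
    return SpotSet(
        kind="underexpression_spot",
        spots=comps,
        member_genes=[som.genes_in_units(c) for c in comps],
    )


def kmeans_landscape(som: SOMModel, k: int, seed: int = 0) -> SpotSet:
    """Partition the metagene landscape into k K-means clusters of units."""
    if k < 1:
        raise ArgumentError("k must be >= 1")
    if k > som.n_units:
        raise ArgumentError(f"k={k} exceeds the number of units ({som.n_units})")
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(som.weights)
    spots = [set(np.flatnonzero(labels == i).tolist()) for i in range(k)]
    return SpotSet(
        kind="kmeans_cluster",
        spots=spots,
        member_genes=[som.genes_in_units(s) for s in spots],
    )


def correlation_spanning_tree(som: SOMModel) -> nx.Graph:
    """Maximum-correlation spanning tree of the samples (features).

    Equivalent to the minimum spanning tree on 1 - Pearson correlation of the
    sample portraits.  Edge attributes: ``correlation`` and ``weight``.
    """
    names = som.feature_names
    if len(names) < 2:
        raise ArgumentError("need >= 2 samples")
    g = nx.Graph()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            corr = _profile_correlation(som.weights[:, i], som.weights[:, j])
            g.add_edge(names[i], names[j], weight=1.0 - corr, correlation=corr)
    return nx.minimum_spanning_tree(g, weight="weight")
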