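import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from epidrift import som
from epidrift.errors import ArgumentError, InputError
from epidrift.som import (
    correlation_clusters,
    correlation_spanning_tree,
    expand_code_matrix,
    kmeans_landscape,
    sample_portrait,
    train_som,
    underexpression_spots,
)


@pytest.fixture(scope="module")
def random_profiles():
    rng = np.random.default_rng(0)
    return pd.DataFrame(rng.normal(size=(300, 6)),
                        index=[f"g{i}" for i in range(300)],
                        columns=[f"s{i}" for i in range(6)])


@pytest.fixture(scope="module")
def trained(random_profiles):
    return train_som(random_profiles, 6, 6, epochs=30, seed=1)


@pytest.fixture(scope="module")
def planted_som(zero_noise_codes):
    profiles = expand_code_matrix(zero_noise_codes)
    return train_som(profiles, 12, 12, epochs=40, seed=5)


def naive_kmeans_assign(X, W0, iters):
    """Independent Lloyd iteration oracle (empty clusters keep their center)."""
    W = W0.copy()
    for _ in range(iters):
        d = ((X[:, None, :] - W[None]) ** 2).sum(-1)
        a = d.argmin(1)
        for k in range(W.shape[0]):
            if (a == k).any():
                W[k] = X[a == k].mean(0)
    return ((X[:, None, :] - W[None]) ** 2).sum(-1).argmin(1)


class TestTraining:
    def test_identical_profiles_same_unit(self, trained, random_profiles):
        dup = pd.concat([random_profiles.iloc[[0]], random_profiles.iloc[[0]]])
        dup.index = ["a", "b"]
        m = train_som(pd.concat([random_profiles, dup]), 6, 6, epochs=20, seed=1)
        assert m.gene_to_unit["a"] == m.gene_to_unit["b"]

    def test_1x1_grid_converges_to_mean(self, random_profiles):
        m = train_som(random_profiles, 1, 1, epochs=20, seed=0)
        np.testing.assert_allclose(m.weights[0], random_profiles.mean().values, atol=1e-6)

    def test_zero_neighborhood_matches_reference_kmeans(self, random_profiles):
        rows = cols = 3
        epochs = 15
        seed = 3
        m = train_som(random_profiles, rows, cols, epochs=epochs,
                      radius_start=1e-4, radius_end=1e-4, seed=seed)
        X = random_profiles.to_numpy()
        rng = np.random.default_rng(seed)
        W0 = rng.uniform(X.min(0), X.max(0), size=(rows * cols, X.shape[1]))
        ref = naive_kmeans_assign(X, W0, epochs)
        assert (m.gene_to_unit.to_numpy() == ref).all()

    def test_quantization_error_non_increasing(self, trained):
        qe = np.array(trained.qe_history)
        assert (np.diff(qe) <= 1e-9).all()

    def test_determinism(self, random_profiles):
        a = train_som(random_profiles, 4, 4, epochs=10, seed=7)
        b = train_som(random_profiles, 4, 4, epochs=10, seed=7)
        assert np.array_equal(a.weights, b.weights)
        assert a.gene_to_unit.equals(b.gene_to_unit)

    def test_online_variant_runs(self, random_profiles):
        m = train_som(random_profiles.iloc[:50], 3, 3, epochs=5,
                      variant="online", seed=2)
        assert np.isfinite(m.weights).all()

    def test_non_finite_rejected(self):
        bad = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(InputError):
            train_som(bad, 2, 2)

    def test_every_gene_mapped(self, trained, random_profiles):
        assert len(trained.gene_to_unit) == len(random_profiles)
        assert trained.gene_to_unit.between(0, trained.n_units - 1).all()


class TestPortraits:
    def test_constant_matrix_flat_portrait(self):
        flat = pd.DataFrame(np.full((50, 4), 2.5), columns=list("abcd"))
        m = train_som(flat, 3, 3, epochs=10, seed=0)
        portrait = sample_portrait(m, "a")
        np.testing.assert_allclose(portrait, 2.5, atol=1e-9)

    def test_duplicated_sample_identical_portraits(self, random_profiles):
        dup = random_profiles.copy()
        dup["s_dup"] = dup["s0"]
        m = train_som(dup, 4, 4, epochs=15, seed=1)
        np.testing.assert_allclose(sample_portrait(m, "s0"), sample_portrait(m, "s_dup"))

    def test_unknown_sample(self, trained):
        with pytest.raises(ArgumentError):
            sample_portrait(trained, "nope")

    def test_planted_genes_spatially_clustered(self, planted_som, planted_by_label):
        # cluster-g genes land on fewer units than a size-matched random draw
        units = planted_som.gene_to_unit
        g_units = set(units[units.index.isin(planted_by_label["g"])])
        rng = np.random.default_rng(0)
        n = (units.index.isin(planted_by_label["g"])).sum()
        null = [
            len(set(rng.choice(units.to_numpy(), size=n, replace=False)))
            for _ in range(1000)
        ]
        assert len(g_units) < np.percentile(null, 5)


class TestCorrelationClusters:
    def test_identical_metagenes_single_cluster(self):
        flat = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (60, 1)), columns=list("abc"))
        m = train_som(flat, 3, 3, epochs=10, seed=0)
        spots = correlation_clusters(m, threshold=0.9)
        assert len(spots.spots) == 1 and len(spots.spots[0]) == m.n_units

    def test_threshold_above_one_no_clusters(self, trained):
        assert len(correlation_clusters(trained, threshold=1.01).spots) == 0

    def test_partitions_disjoint(self, planted_som):
        spots = correlation_clusters(planted_som, threshold=0.95)
        seen: set[int] = set()
        for s in spots.spots:
            assert not (s & seen)
            seen |= s

    def test_planted_labels_recovered(self, planted_som, planted_by_label):
        spots = correlation_clusters(planted_som, threshold=0.995)
        for label in "abcdef":
            planted = planted_by_label[label]
            best = max(
                len(planted & set(m)) / len(planted | set(m))
                for m in spots.member_genes if m
            )
            assert best >= 0.9, f"cluster {label}: best Jaccard {best:.2f}"

    def test_planted_labels_in_distinct_spots(self, planted_som, planted_by_label):
        spots = correlation_clusters(planted_som, threshold=0.995)
        best_spot = {}
        for label in "abcdef":
            planted = planted_by_label[label]
            scores = [len(planted & set(m)) for m in spots.member_genes]
            best_spot[label] = int(np.argmax(scores))
        assert len(set(best_spot.values())) == 6


class TestUnderexpressionSpots:
    LOW_G = ["org_long|K27"]
    HIGH_G = ["tissue_1|K27", "tissue_2|K27", "org_short|K27"]

    def test_constant_matrix_empty(self):
        flat = pd.DataFrame(np.full((40, 4), 1.0), columns=list("abcd"))
        m = train_som(flat, 3, 3, epochs=5, seed=0)
        spots = underexpression_spots(m, ["a"], ["b"], quantile=0.5)
        assert len(spots.spots) == 0

    def test_planted_g_h_recovery(self, planted_som, planted_by_label):
        spots_g = underexpression_spots(planted_som, self.LOW_G, self.HIGH_G,
                                        quantile=0.3, min_contrast=0.5)
        rec = max(len(planted_by_label["g"] & set(m)) / len(planted_by_label["g"])
                  for m in spots_g.member_genes)
        assert rec >= 0.9
        low_h = ["tissue_1|K4", "tissue_2|K4", "org_short|K4"]
        spots_h = underexpression_spots(planted_som, low_h, ["org_long|K4"],
                                        quantile=0.3, min_contrast=0.5)
        rec = max(len(planted_by_label["h"] & set(m)) / len(planted_by_label["h"])
                  for m in spots_h.member_genes)
        assert rec >= 0.9

    def test_quantile_monotonicity(self, planted_som):
        prev: set[int] | None = None
        for q in (0.5, 0.3, 0.1, 0.05):
            spots = underexpression_spots(planted_som, self.LOW_G, self.HIGH_G,
                                          quantile=q, min_contrast=0.5)
            units = set().union(*spots.spots) if spots.spots else set()
            if prev is not None:
                assert units <= prev
            prev = units


class TestKmeansLandscape:
    def test_k1_covers_grid(self, trained):
        spots = kmeans_landscape(trained, 1, seed=0)
        assert len(spots.spots) == 1 and len(spots.spots[0]) == trained.n_units

    def test_k_equals_units_singletons(self, trained):
        # random-data SOM units are pairwise distinct
        assert len(np.unique(trained.weights, axis=0)) == trained.n_units
        spots = kmeans_landscape(trained, trained.n_units, seed=0)
        assert sorted(len(s) for s in spots.spots) == [1] * trained.n_units

    def test_seed_determinism(self, trained):
        a = kmeans_landscape(trained, 5, seed=3)
        b = kmeans_landscape(trained, 5, seed=3)
        assert a.spots == b.spots

    def test_every_unit_assigned(self, trained):
        spots = kmeans_landscape(trained, 4, seed=0)
        assert set().union(*spots.spots) == set(range(trained.n_units))

    def test_k_too_large(self, trained):
        with pytest.raises(ArgumentError):
            kmeans_landscape(trained, trained.n_units + 1)


class TestSpanningTree:
    def test_two_samples_single_edge(self):
        rng = np.random.default_rng(1)
        prof = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        m = train_som(prof, 3, 3, epochs=10, seed=0)
        tree = correlation_spanning_tree(m)
        assert set(tree.edges) == {("a", "b")}

    def test_triples_match_enumeration(self):
        # oracle: best of the 3 possible spanning trees on 3 nodes
        rng = np.random.default_rng(5)
        for trial in range(20):
            prof = pd.DataFrame(rng.normal(size=(60, 3)), columns=["A", "B", "C"])
            m = train_som(prof, 4, 4, epochs=15, seed=trial)
            corr = {}
            for i, j in itertools.combinations(range(3), 2):
                c = np.corrcoef(m.weights[:, i], m.weights[:, j])[0, 1]
                corr[frozenset(["ABC"[i], "ABC"[j]])] = c
            trees = [
                [frozenset("AB"), frozenset("AC")],
                [frozenset("AB"), frozenset("BC")],
                [frozenset("AC"), frozenset("BC")],
            ]
            best = max(trees, key=lambda t: sum(corr[e] for e in t))
            got = {frozenset(e) for e in correlation_spanning_tree(m).edges}
            assert got == set(best)

    def test_fewer_than_two_samples(self, random_profiles):
        m = train_som(random_profiles[["s0", "s1"]], 3, 3, epochs=5, seed=0)
        m.feature_names = ["s0"]
        m.weights = m.weights[:, :1]
        with pytest.raises(ArgumentError):
            correlation_spanning_tree(m)

    def test_planted_three_groups_recovered(self):
        # 3 expression groups; cutting the 2 longest tree edges separates them
        rng = np.random.default_rng(9)
        groups = {"G1": 3, "G2": 3, "G3": 3}
        base = {g: rng.normal(scale=3.0, size=200) for g in groups}
        cols, data = [], []
        for g, n in groups.items():
            for r in range(n):
                cols.append(f"{g}_r{r}")
                data.append(base[g] + rng.normal(scale=0.3, size=200))
        prof = pd.DataFrame(np.array(data).T, columns=cols)
        m = train_som(prof, 6, 6, epochs=25, seed=2)
        tree = correlation_spanning_tree(m)
        edges = sorted(tree.edges(data=True), key=lambda e: e[2]["weight"])
        cut = tree.copy()
        cut.remove_edges_from([(u, v) for u, v, _ in edges[-2:]])
        comps = [frozenset(c) for c in nx.connected_components(cut)]
        expected = {frozenset(c for c in cols if c.startswith(g)) for g in groups}
        assert set(comps) == expected


def test_expand_code_matrix(zero_noise_codes):
    prof = expand_code_matrix(zero_noise_codes)
    assert prof.shape == (len(zero_noise_codes.genes), 2 * len(zero_noise_codes.samples))
    assert set(np.unique(prof.values)) <= {0.0, 1.0}
    g = zero_noise_codes.genes[0]
    s = zero_noise_codes.samples[0]
    assert prof.loc[g, f"{s}|K4"] == float(zero_noise_codes.codes.loc[g, s][0])
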