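import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from meanet.network import (
    classify_links,
    device_average_synchrony,
    louvain_partition,
    synchrony_distribution,
    synchrony_graph,
)
from meanet.synchrony import SynchronyMatrix

from oracles import best_partition_exhaustive, modularity_reference


def planted_matrix(block_sizes, within, between, rng):
    """Complete synchrony matrix with planted community blocks."""
    n = sum(block_sizes)
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    vals = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        base = within if labels[i] == labels[j] else between
        v = float(np.clip(base + rng.normal(0, 0.03), 0.0, 1.0))
        vals[i, j] = vals[j, i] = v
    return SynchronyMatrix(list(range(n)), vals), labels


class TestLouvain:
    def test_two_block_recovery(self):
        rng = np.random.default_rng(0)
        m, labels = planted_matrix([5, 5], 0.9, 0.05, rng)
        part = louvain_partition(synchrony_graph(m), seed=0)
        assert part.n_communities == 2
        found = [part.communities[i] for i in range(10)]
        assert adjusted_rand_score(labels, found) == 1.0

    def test_single_node(self):
        g = nx.Graph()
        g.add_node(0)
        part = louvain_partition(g)
        assert part.communities == {0: 0}
        assert part.modularity == 0.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain_partition(nx.Graph())

    def test_recovery_rate_across_seeds(self):
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            m, labels = planted_matrix([5, 5], 0.8, 0.4, rng)  # gap 0.4
            part = louvain_partition(synchrony_graph(m), seed=rep)
            found = [part.communities[i] for i in range(10)]
            if adjusted_rand_score(labels, found) >= 0.9:
                hits += 1
        assert hits / n_rep >= 0.9

    def test_reported_q_matches_reference_formula(self):
        rng = np.random.default_rng(2)
        m, _ = planted_matrix([4, 4], 0.9, 0.1, rng)
        g = synchrony_graph(m)
        part = louvain_partition(g, seed=0)
        labels = [part.communities[i] for i in range(8)]
        w = m.values.copy()
        np.fill_diagonal(w, 0.0)
        assert part.modularity == pytest.approx(
            modularity_reference(w, labels), abs=1e-12)

    def test_matches_exhaustive_optimum_on_small_graphs(self):
        for rep in range(5):
            rng = np.random.default_rng(50 + rep)
            m, _ = planted_matrix([4, 3], 0.9, 0.05, rng)
            g = synchrony_graph(m)
            part = louvain_partition(g, seed=0)
            w = m.values.copy()
            np.fill_diagonal(w, 0.0)
            best_q, _ = best_partition_exhaustive(w)
            assert part.modularity <= best_q + 1e-12
            # well-separated planted case: Louvain attains the optimum
            assert part.modularity == pytest.approx(best_q, abs=1e-9)

    def test_beats_singleton_partition(self):
        rng = np.random.default_rng(3)
        m, _ = planted_matrix([5, 5], 0.7, 0.3, rng)
        g = synchrony_graph(m)
        part = louvain_partition(g, seed=0)
        w = m.values.copy()
        np.fill_diagonal(w, 0.0)
        q_singletons = modularity_reference(w, list(range(10)))
        assert part.modularity >= q_singletons

    def test_stable_under_relabeling(self):
        rng = np.random.default_rng(4)
        m, _ = planted_matrix([5, 5], 0.9, 0.05, rng)
        part1 = louvain_partition(synchrony_graph(m), seed=0)
        perm = list(np.random.default_rng(1).permutation(10))
        vals = m.values[np.ix_(perm, perm)]
        m2 = SynchronyMatrix(list(range(10)), vals)
        part2 = louvain_partition(synchrony_graph(m2), seed=0)
        lab1 = [part1.communities[perm[i]] for i in range(10)]
        lab2 = [part2.communities[i] for i in range(10)]
        assert adjusted_rand_score(lab1, lab2) == 1.0


class TestClassifyLinks:
    def test_strict_threshold_boundary(self):
        vals = np.eye(3)
        trio = [0.69, 0.70, 0.71]
        vals[0, 1] = vals[1, 0] = trio[0]
        vals[0, 2] = vals[2, 0] = trio[1]
        vals[1, 2] = vals[2, 1] = trio[2]
        edges = classify_links(SynchronyMatrix([0, 1, 2], vals))
        assert list(edges.sort_values("synchrony")["label"]) == [
            "weak", "weak", "strong"]

    def test_all_one_matrix_all_strong(self):
        vals = np.ones((3, 3))
        edges = classify_links(SynchronyMatrix([0, 1, 2], vals))
        assert (edges["label"] == "strong").all()

    def test_zero_threshold_all_nonzero_strong(self):
        vals = np.eye(2)
        vals[0, 1] = vals[1, 0] = 0.2
        edges = classify_links(SynchronyMatrix([0, 1], vals), strong_threshold=0.0)
        assert (edges["label"] == "strong").all()


class TestSynchronyDistribution:
    def test_bimodal_mixture_detected(self):
        rng = np.random.default_rng(5)
        low = np.clip(rng.normal(0.4, 0.06, 500), 0, 1)
        high = np.clip(rng.normal(0.95, 0.03, 500), 0, 1)
        summ = synchrony_distribution(np.concatenate([low, high]))
        assert summ.is_bimodal
        assert any(0.3 <= p <= 0.5 for p in summ.peaks)
        assert any(0.9 <= p <= 1.0 for p in summ.peaks)

    def test_constant_values_single_peak(self):
        summ = synchrony_distribution(np.full(100, 0.6))
        assert summ.peaks == [pytest.approx(0.6)]

    def test_mean_is_arithmetic_mean(self):
        v = np.array([0.1, 0.5, 0.9])
        assert synchrony_distribution(v).mean == pytest.approx(v.mean())

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            summ = synchrony_distribution(np.array([]))
        assert np.isnan(summ.mean) and summ.peaks == []


class TestDeviceAverage:
    def test_three_link_mean(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.2
        vals[0, 2] = vals[2, 0] = 0.4
        vals[1, 2] = vals[2, 1] = 0.9
        assert device_average_synchrony(
            SynchronyMatrix([0, 1, 2], vals)) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(6)
        n = 8
        vals = np.eye(n)
        acc = []
        for i, j in itertools.combinations(range(n), 2):
            v = rng.uniform()
            vals[i, j] = vals[j, i] = v
            acc.append(v)
        assert device_average_synchrony(
            SynchronyMatrix(list(range(n)), vals)) == pytest.approx(np.mean(acc))

    def test_no_links_undefined(self):
        with pytest.warns(UserWarning):
            out = device_average_synchrony(SynchronyMatrix([0], np.ones((1, 1))))
        assert np.isnan(out)
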