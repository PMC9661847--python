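"""Co-occurrence networks: SparCC, significance, robustness, NESH."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pneumotyper.containers import CountTable, SampleMetadata
from pneumotyper.networks import (
    MicrobialNetwork,
    attack_robustness,
    build_network,
    core_taxa_filter,
    cross_site_network,
    edge_significance,
    neighbor_shift,
    sparcc,
)
from pneumotyper.validate import _lognormal_counts, sparcc_calibration


def _table(rows, prefix="s"):
    rows = np.asarray(rows)
    return CountTable(
        pd.DataFrame(
            rows,
            index=[f"{prefix}{i}" for i in range(rows.shape[0])],
            columns=[f"t{j}" for j in range(rows.shape[1])],
        )
    )


class TestCoreFilter:
    def test_threshold_is_strict(self, rng):
        counts = rng.integers(150, 300, size=(10, 12))  # totals comfortably > 1000
        counts[:, 0] = 100  # total 1000 exactly -> excluded (strict inequality)
        counts[:, 1] = 101  # total 1010 -> kept
        table = _table(counts)
        filtered = core_taxa_filter(table, min_reads=1000)
        assert "t0" not in filtered.taxon_ids
        assert "t1" in filtered.taxon_ids

    def test_zero_threshold_is_identity(self, rng):
        table = _table(rng.integers(1, 10, size=(5, 12)))
        assert core_taxa_filter(table, min_reads=0).taxon_ids == table.taxon_ids

    def test_everything_filtered_raises(self, rng):
        table = _table(rng.integers(1, 3, size=(4, 12)))
        with pytest.raises(ValueError, match="too few"):
            core_taxa_filter(table, min_reads=10_000)


class TestSparcc:
    def test_matrix_contract(self, rng):
        table = _table(rng.integers(0, 200, size=(25, 12)) + 1)
        rho = sparcc(table)
        v = rho.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert np.nanmax(np.abs(v)) <= 1.0

    def test_planted_pair_recovered(self, rng):
        table = _lognormal_counts(rng, 300, 30, planted_rho=0.8)
        rho = sparcc(table)
        assert abs(rho.iloc[0, 1] - 0.8) <= 0.15

    def test_independent_taxa_stay_weak(self, rng):
        table = _lognormal_counts(rng, 500, 30, planted_rho=None)
        rho = sparcc(table).to_numpy()
        np.fill_diagonal(rho, 0.0)
        assert np.nanmax(np.abs(rho)) <= 0.3

    def test_minimum_size_contract(self, rng):
        small = _table(rng.integers(1, 50, size=(25, 5)))
        with pytest.raises(ValueError, match="10 taxa"):
            sparcc(small)
        thin = _table(rng.integers(1, 50, size=(10, 12)))
        with pytest.raises(ValueError, match="20 samples"):
            sparcc(thin)


class TestEdgeSignificance:
    def test_p_bounds_and_planted_minimum(self, rng):
        table = _lognormal_counts(rng, 200, 15, planted_rho=0.9)
        rho = sparcc(table)
        p = edge_significance(table, rho, n_iter=199, seed=0)
        v = p.to_numpy()[np.triu_indices(15, 1)]
        assert (v >= 1.0 / 200.0 - 1e-12).all() and (v <= 1.0).all()
        assert p.iloc[0, 1] == pytest.approx(1.0 / 200.0)

    def test_null_calibrated(self):
        out = sparcc_calibration(seed=5)
        assert abs(out["false_positive_rate"] - 0.05) <= 0.02


class TestBuildNetwork:
    def toy_matrices(self):
        taxa = ["a", "b", "c"]
        rho = pd.DataFrame(
            [[1.0, 0.6, -0.5], [0.6, 1.0, 0.1], [-0.5, 0.1, 1.0]],
            index=taxa,
            columns=taxa,
        )
        p = pd.DataFrame(
            [[1.0, 0.01, 0.02], [0.01, 1.0, 0.01], [0.02, 0.01, 1.0]],
            index=taxa,
            columns=taxa,
        )
        return rho, p

    def test_exact_edge_set_by_enumeration(self):
        rho, p = self.toy_matrices()
        net = build_network(rho, p, rho_threshold=0.4, p_threshold=0.05)
        assert set(map(frozenset, net.graph.edges)) == {
            frozenset({"a", "b"}),
            frozenset({"a", "c"}),
        }
        pos, neg = net.edge_sign_ratio()
        assert (pos, neg) == (1, 1)

    def test_weak_correlations_give_empty_network(self):
        rho, p = self.toy_matrices()
        net = build_network(rho * 0.3, p, rho_threshold=0.4)
        assert net.n_edges == 0
        assert np.isnan(net.stats()["average_path_length"])

    def test_significance_gate(self):
        rho, p = self.toy_matrices()
        net = build_network(rho, p * 10, rho_threshold=0.4, p_threshold=0.05)
        assert net.n_edges == 0


def _lcc_flood_fill(edges, nodes):
    """Brute-force largest component size via stack-based flood fill."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        if u in adj and v in adj:
            adj[u].add(v)
            adj[v].add(u)
    seen, best = set(), 0
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        best = max(best, len(comp))
    return best


def _robustness_oracle(graph):
    """Recompute the attack curve with flood-fill LCC sizes."""
    n = graph.number_of_nodes()
    deg = dict(graph.degree())
    order = sorted(graph.nodes, key=lambda v: (-deg[v], 0.0, v))
    nodes = list(graph.nodes)
    edges = list(graph.edges)
    xs, ys = [0.0], [_lcc_flood_fill(edges, nodes) / n]
    removed = set()
    for k, v in enumerate(order, 1):
        removed.add(v)
        rest = [u for u in nodes if u not in removed]
        live = [(a, b) for a, b in edges if a not in removed and b not in removed]
        xs.append(k / n)
        ys.append(_lcc_flood_fill(live, rest) / n if rest else 0.0)
    return np.array(xs), np.array(ys), np.trapezoid(ys, xs)


class TestAttackRobustness:
    def test_complete_graph_exact(self):
        g = nx.relabel_nodes(nx.complete_graph(10), str)
        curve = attack_robustness(MicrobialNetwork(g))
        assert np.allclose(curve.removal_fraction, np.arange(11) / 10)
        assert np.allclose(curve.lcc_fraction, (10 - np.arange(11)) / 10)
        assert curve.auc == pytest.approx(0.5, abs=1e-12)

    def test_star_collapses_fast(self):
        g = nx.relabel_nodes(nx.star_graph(10), str)
        assert attack_robustness(MicrobialNetwork(g)).auc < 0.2

    def test_matches_flood_fill_oracle_on_random_graphs(self, rng):
        for trial in range(50):
            n = int(rng.integers(3, 16))
            g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.7), seed=int(rng.integers(1e6)))
            g = nx.relabel_nodes(g, lambda v: f"n{v:02d}")
            curve = attack_robustness(MicrobialNetwork(g))
            xs, ys, auc = _robustness_oracle(g)
            assert np.allclose(curve.removal_fraction, xs)
            assert np.allclose(curve.lcc_fraction, ys)
            assert curve.auc == pytest.approx(auc, abs=1e-12)

    def test_removing_edges_never_raises_auc_under_fixed_order(self, rng):
        for trial in range(20):
            g = nx.gnp_random_graph(10, 0.4, seed=trial)
            g = nx.relabel_nodes(g, lambda v: f"n{v:02d}")
            if g.number_of_edges() < 2:
                continue
            full = attack_robustness(MicrobialNetwork(g))
            g2 = g.copy()
            edge = list(g2.edges)[int(rng.integers(g2.number_of_edges()))]
            g2.remove_edge(*edge)
            # same removal order as the full graph (fixed-order contract)
            deg = dict(g.degree())
            order = sorted(g.nodes, key=lambda v: (-deg[v], 0.0, v))
            n = g2.number_of_nodes()
            xs, ys = [0.0], [len(max(nx.connected_components(g2), key=len)) / n]
            h = g2.copy()
            for k, v in enumerate(order, 1):
                h.remove_node(v)
                xs.append(k / n)
                ys.append(
                    len(max(nx.connected_components(h), key=len)) / n
                    if h.number_of_nodes()
                    else 0.0
                )
            auc_sub = np.trapezoid(ys, xs)
            assert auc_sub <= full.auc + 1e-12


class TestNeighborShift:
    def _net(self, edges):
        g = nx.Graph()
        g.add_edges_from(edges)
        return MicrobialNetwork(g)

    def test_identical_networks_all_zero(self):
        net = self._net([("a", "b"), ("b", "c")])
        out = neighbor_shift(net, net)
        assert (out["nesh"] == 0).all()
        assert not out["driver"].any()

    def test_half_overlap_neighborhood(self):
        net_a = self._net([("v", "a"), ("v", "b"), ("v", "c")])
        net_b = self._net([("v", "b"), ("v", "c"), ("v", "d")])
        out = neighbor_shift(net_a, net_b)
        assert out.loc["v", "nesh"] == pytest.approx(0.5)

    def test_disjoint_neighborhoods_score_one(self):
        net_a = self._net([("v", "a"), ("v", "b")])
        net_b = self._net([("v", "x"), ("v", "y")])
        out = neighbor_shift(net_a, net_b)
        assert out.loc["v", "nesh"] == 1.0

    def test_no_common_nodes_empty(self):
        out = neighbor_shift(self._net([("a", "b")]), self._net([("x", "y")]))
        assert out.empty

    def test_driver_needs_degree_gain(self):
        net_a = self._net([("v", "a"), ("v", "b"), ("u", "a")])
        net_b = self._net([("v", "x"), ("v", "y"), ("v", "z"), ("u", "a")])
        out = neighbor_shift(net_a, net_b)
        assert bool(out.loc["v", "driver"])
        assert not bool(out.loc["u", "driver"])


class TestCrossSite:
    def _paired_cohort(self, rng, n_subjects=30, n_taxa=12):
        factor = rng.normal(size=n_subjects)
        rows_a, rows_b, meta_rows = [], [], []
        for i in range(n_subjects):
            base_a = np.exp(rng.normal(0, 0.4, n_taxa))
            base_b = np.exp(rng.normal(0, 0.4, n_taxa))
            base_a[2] *= np.exp(1.2 * factor[i])  # planted: saliva t2
            base_b[7] *= np.exp(1.2 * factor[i])  # linked to BAL t7
            rows_a.append(rng.multinomial(4000, base_a / base_a.sum()))
            rows_b.append(rng.multinomial(4000, base_b / base_b.sum()))
            meta_rows += [
                {"sample_id": f"p{i}_sal", "subject_id": f"p{i}", "site": "saliva"},
                {"sample_id": f"p{i}_bal", "subject_id": f"p{i}", "site": "BAL"},
            ]
        taxa = [f"t{j}" for j in range(n_taxa)]
        sal = CountTable(
            pd.DataFrame(rows_a, index=[f"p{i}_sal" for i in range(n_subjects)], columns=taxa),
            {f"p{i}_sal": "saliva" for i in range(n_subjects)},
        )
        bal = CountTable(
            pd.DataFrame(rows_b, index=[f"p{i}_bal" for i in range(n_subjects)], columns=taxa),
            {f"p{i}_bal": "BAL" for i in range(n_subjects)},
        )
        return sal, bal, SampleMetadata(pd.DataFrame(meta_rows))

    def test_planted_cross_site_edge_retained(self, rng):
        sal, bal, meta = self._paired_cohort(rng)
        net, summary = cross_site_network(
            sal, bal, meta, n_iter=199, seed=0, min_reads=100
        )
        assert all("@" in v for v in net.nodes)
        assert net.graph.has_edge("t2@saliva", "t7@BAL")
        assert summary.loc["t2@saliva", "edges_cross_site"] >= 1

    def test_unpaired_subjects_dropped(self, rng):
        sal, bal, meta = self._paired_cohort(rng, n_subjects=25)
        bal_sub = bal.select_samples(bal.sample_ids[:22])  # 3 subjects lose BAL
        net, _ = cross_site_network(
            sal, bal_sub, meta, n_iter=99, seed=0, min_reads=100
        )
        assert net.graph.number_of_nodes() > 0

    def test_too_few_pairs_rejected(self, rng):
        sal, bal, meta = self._paired_cohort(rng, n_subjects=10)
        with pytest.raises(ValueError, match="both sites"):
            cross_site_network(sal, bal, meta, min_pairs=20)
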