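"""Compositional co-occurrence networks and their comparison.

SparCC-style basis correlations are inferred from log-ratio variances: with
``T_ij = Var(log(x_i/x_j))`` over samples (pseudocount-1 fractions) and the
sparsity assumption that most pairs are uncorrelated, the basis variances
``w`` solve the linear system ``t_i = (D-2) w_i + sum_j w_j`` and

    rho_ij = (w_i + w_j - T_ij) / (2 sqrt(w_i w_j))

Strongly correlated pairs violate the sparsity assumption, so the single
strongest pair above an exclusion threshold is removed from the system and
the variances re-solved, for a fixed number of rounds.  Significance comes
from a per-taxon permutation null; networks retain edges with |rho| above a
magnitude threshold and p below a significance threshold.

Network-level summaries: degree-targeted attack robustness (largest
connected component fraction versus nodes removed, with its AUC) and a
neighbor-shift (NESH) score — the Jaccard dissimilarity of a node's
neighborhoods in two networks — used to flag candidate driver taxa.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import derive_rng
from .containers import CountTable, SampleMetadata

log = logging.getLogger("pneumotyper")


def core_taxa_filter(table: CountTable, min_reads: int = 1000) -> CountTable:
    """Keep taxa whose cohort-total reads strictly exceed ``min_reads``."""
    totals = table.counts.sum(axis=0)
    keep = totals.index[totals > min_reads].tolist()
    if len(keep) < 10:
        raise ValueError(
            f"only {len(keep)} taxa exceed {min_reads} reads; too few for SparCC"
        )
    return table.select_taxa(keep)


def _log_fractions(counts: np.ndarray) -> np.ndarray:
    frac = (counts + 1.0) / (counts + 1.0).sum(axis=1, keepdims=True)
    return np.log(frac)


def _variation_matrix(logf: np.ndarray) -> np.ndarray:
    """T_ij = Var(log(x_i/x_j)) via the covariance of log fractions."""
    cov = np.cov(logf, rowvar=False)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _solve_basis(t_mat: np.ndarray, excluded: np.ndarray) -> np.ndarray:
    """Basis variances from the sparse approximation, honouring exclusions."""
    d = t_mat.shape[0]
    allowed = ~excluded
    np.fill_diagonal(allowed, False)
    a = allowed.astype(float)
    a[np.diag_indices(d)] = allowed.sum(axis=1)
    t_i = (t_mat * allowed).sum(axis=1)
    try:
        omega = np.linalg.solve(a, t_i)
    except np.linalg.LinAlgError:
        omega = np.linalg.lstsq(a, t_i, rcond=None)[0]
    return omega


def sparcc(
    table: CountTable,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
) -> pd.DataFrame:
    """Basis correlation matrix (symmetric, unit diagonal, clamped to [-1,1]).

    Taxa whose basis variance turns non-positive are dropped with a warning
    (their rows/columns are NaN in the returned frame).
    """
    if table.n_taxa < 10:
        raise ValueError("SparCC needs at least 10 taxa")
    if table.n_samples < 20:
        raise ValueError("SparCC needs at least 20 samples")
    t_mat = _variation_matrix(_log_fractions(table.counts.to_numpy(dtype=float)))
    rho = _sparcc_from_variation(t_mat, n_exclusion_iter, exclusion_threshold)
    return pd.DataFrame(rho, index=table.taxon_ids, columns=table.taxon_ids)


def _sparcc_from_variation(
    t_mat: np.ndarray, n_exclusion_iter: int, exclusion_threshold: float
) -> np.ndarray:
    d = t_mat.shape[0]
    excluded = np.zeros((d, d), dtype=bool)
    rho = None
    for _ in range(n_exclusion_iter + 1):
        omega = _solve_basis(t_mat, excluded)
        bad = omega <= 0
        if bad.any():
            log.warning("SparCC: %d taxa with non-positive basis variance", bad.sum())
            omega = np.where(bad, np.nan, omega)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        with np.errstate(invalid="ignore"):
            rho = np.clip((omega[:, None] + omega[None, :] - t_mat) / denom, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        # exclude the single strongest off-diagonal pair above threshold
        masked = np.abs(np.where(excluded, 0.0, rho))
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(np.nanargmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
    return rho


def edge_significance(
    table: CountTable,
    rho_obs: pd.DataFrame,
    n_iter: int = 1000,
    seed: int = 0,
    *,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
    mode: str = "permutation",
) -> pd.DataFrame:
    """Two-sided pseudo p values for SparCC correlations.

    The null shuffles each taxon's counts independently across samples
    (``mode='bootstrap'`` resamples each taxon's counts with replacement
    instead); p = (1 + #{|rho_null| >= |rho_obs|}) / (n_iter + 1).
    """
    if n_iter < 99:
        log.warning("edge_significance: n_iter=%d gives coarse p resolution", n_iter)
    counts = table.counts.to_numpy(dtype=float)
    n, d = counts.shape
    obs = np.abs(rho_obs.to_numpy())
    rng = derive_rng(seed, "edge_significance")
    exceed = np.zeros((d, d), dtype=np.int64)
    for _ in range(n_iter):
        if mode == "permutation":
            null_counts = np.empty_like(counts)
            for j in range(d):
                null_counts[:, j] = counts[rng.permutation(n), j]
        elif mode == "bootstrap":
            null_counts = np.empty_like(counts)
            for j in range(d):
                null_counts[:, j] = counts[rng.integers(0, n, size=n), j]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        t_null = _variation_matrix(_log_fractions(null_counts))
        rho_null = _sparcc_from_variation(t_null, n_exclusion_iter, exclusion_threshold)
        exceed += np.abs(rho_null) >= obs
    p = (1.0 + exceed) / (n_iter + 1.0)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=rho_obs.index, columns=rho_obs.columns)


@dataclass
class MicrobialNetwork:
    """Undirected signed co-occurrence network over taxa.

    Node attributes: ``site`` (cross-site mode), ``mean_abundance``,
    optional ``phylum``.  Edge attributes: ``rho``, ``p``, ``sign``.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def edge_sign_ratio(self) -> tuple[int, int]:
        """(positive, negative) edge counts."""
        signs = [d["sign"] for _, _, d in self.graph.edges(data=True)]
        return signs.count(1), signs.count(-1)

    def average_path_length(self) -> float:
        """Average shortest path length on the largest connected component."""
        if self.graph.number_of_nodes() == 0 or self.n_edges == 0:
            return float("nan")
        lcc = max(nx.connected_components(self.graph), key=len)
        if len(lcc) < 2:
            return float("nan")
        return nx.average_shortest_path_length(self.graph.subgraph(lcc))

    def stats(self) -> dict:
        pos, neg = self.edge_sign_ratio()
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.n_edges,
            "positive_edges": pos,
            "negative_edges": neg,
            "pos_neg_ratio": (pos / neg) if neg else float("inf"),
            "average_path_length": self.average_path_length(),
        }


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    rho_threshold: float = 0.4,
    p_threshold: float = 0.05,
    node_annotations: pd.DataFrame | None = None,
) -> MicrobialNetwork:
    """Retain edges with |rho| >= rho_threshold and p < p_threshold."""
    if list(rho.index) != list(p.index) or list(rho.columns) != list(p.columns):
        raise ValueError("rho and p matrices must share their taxon labels")
    graph = nx.Graph()
    for node in rho.index:
        attrs = {}
        if node_annotations is not None and node in node_annotations.index:
            attrs = node_annotations.loc[node].dropna().to_dict()
        graph.add_node(str(node), **attrs)
    taxa = list(rho.index)
    rv, pv = rho.to_numpy(), p.to_numpy()
    for i, j in itertools.combinations(range(len(taxa)), 2):
        r = rv[i, j]
        if np.isnan(r):
            continue
        if abs(r) >= rho_threshold and pv[i, j] < p_threshold:
            graph.add_edge(
                str(taxa[i]),
                str(taxa[j]),
                rho=float(r),
                p=float(pv[i, j]),
                sign=1 if r > 0 else -1,
            )
    net = MicrobialNetwork(graph)
    if net.n_edges == 0:
        log.info("build_network: no edges passed the thresholds")
    return net


@dataclass
class RobustnessCurve:
    """LCC fraction versus fraction of nodes removed, and its AUC."""

    removal_fraction: np.ndarray
    lcc_fraction: np.ndarray
    auc: float


def _removal_order(net: MicrobialNetwork) -> list[str]:
    """Descending initial degree; ties by higher mean abundance, then name."""
    deg = net.degrees()

    def key(node: str):
        abund = net.graph.nodes[node].get("mean_abundance", 0.0) or 0.0
        return (-deg[node], -float(abund), node)

    return sorted(net.nodes, key=key)


def attack_robustness(net: MicrobialNetwork) -> RobustnessCurve:
    """Degree-targeted attack: remove nodes in fixed initial-degree order,
    tracking largest-connected-component size relative to the start."""
    n = net.graph.number_of_nodes()
    if n < 2:
        raise ValueError("attack robustness needs at least 2 nodes")
    order = _removal_order(net)
    g = net.graph.copy()
    x = [0.0]
    y = [len(max(nx.connected_components(g), key=len)) / n]
    for k, node in enumerate(order, start=1):
        g.remove_node(node)
        x.append(k / n)
        if g.number_of_nodes():
            y.append(len(max(nx.connected_components(g), key=len)) / n)
        else:
            y.append(0.0)
    x, y = np.array(x), np.array(y)
    return RobustnessCurve(x, y, float(np.trapezoid(y, x)))


@dataclass
class DriverScore:
    node: str
    neighbors_a: frozenset
    neighbors_b: frozenset
    nesh: float
    degree_change: int
    driver: bool = False


def neighbor_shift(net_a: MicrobialNetwork, net_b: MicrobialNetwork) -> pd.DataFrame:
    """NESH score per common node: Jaccard dissimilarity of neighborhoods.

    ``nesh = 1 - |N_A ∩ N_B| / |N_A ∪ N_B|`` (0 when both neighborhoods are
    empty).  Drivers are common nodes in the top NESH quartile whose degree
    increased in ``net_b``.
    """
    common = sorted(set(net_a.nodes) & set(net_b.nodes))
    if not common:
        log.warning("neighbor_shift: no common nodes")
        return pd.DataFrame(
            columns=["nesh", "degree_a", "degree_b", "degree_change", "driver"]
        )
    rows = {}
    for v in common:
        na = frozenset(net_a.graph.neighbors(v))
        nb = frozenset(net_b.graph.neighbors(v))
        union = na | nb
        nesh = (1.0 - len(na & nb) / len(union)) if union else 0.0
        rows[v] = {
            "nesh": nesh,
            "degree_a": len(na),
            "degree_b": len(nb),
            "degree_change": len(nb) - len(na),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    q3 = out["nesh"].quantile(0.75)
    out["driver"] = (out["nesh"] >= q3) & (out["nesh"] > 0) & (out["degree_change"] > 0)
    return out


def cross_site_network(
    site_a: CountTable,
    site_b: CountTable,
    meta: SampleMetadata,
    *,
    label_a: str = "saliva",
    label_b: str = "BAL",
    min_pairs: int = 20,
    rho_threshold: float = 0.4,
    p_threshold: float = 0.05,
    n_iter: int = 1000,
    seed: int = 0,
    min_reads: int = 1000,
) -> tuple[MicrobialNetwork, pd.DataFrame]:
    """Joint network over site-tagged taxa of two paired body sites.

    Per subject sampled at both sites, the feature vector concatenates the
    two sites' taxon counts (taxa tagged ``<taxon>@<site>``); SparCC,
    permutation significance and thresholding proceed as within one site.
    Returns the network and a per-node edge summary (total and cross-site
    edge counts).
    """
    pairs = meta.paired_samples(label_a, label_b)
    pairs = [
        (s, a, b)
        for s, a, b in pairs
        if a in set(site_a.sample_ids) and b in set(site_b.sample_ids)
    ]
    if len(pairs) < min_pairs:
        raise ValueError(f"only {len(pairs)} subjects with both sites; need {min_pairs}")
    a_counts = site_a.counts.loc[[a for _, a, _ in pairs]]
    b_counts = site_b.counts.loc[[b for _, _, b in pairs]]
    a_counts.index = [s for s, _, _ in pairs]
    b_counts.index = [s for s, _, _ in pairs]
    a_counts.columns = [f"{t}@{label_a}" for t in a_counts.columns]
    b_counts.columns = [f"{t}@{label_b}" for t in b_counts.columns]
    joint = CountTable(pd.concat([a_counts, b_counts], axis=1), drop_empty=True)
    joint = core_taxa_filter(joint, min_reads=min_reads)

    rho = sparcc(joint)
    p = edge_significance(joint, rho, n_iter=n_iter, seed=seed)
    ann = pd.DataFrame(
        {
            "site": [c.rsplit("@", 1)[1] for c in joint.taxon_ids],
            "mean_abundance": joint.relative_abundance().mean(axis=0).to_numpy(),
        },
        index=joint.taxon_ids,
    )
    net = build_network(rho, p, rho_threshold, p_threshold, node_annotations=ann)

    rows = {}
    for v in net.nodes:
        site_v = net.graph.nodes[v].get("site")
        total = net.graph.degree(v)
        cross = sum(
            1 for u in net.graph.neighbors(v) if net.graph.nodes[u].get("site") != site_v
        )
        rows[v] = {"site": site_v, "edges_total": total, "edges_cross_site": cross}
    summary = (
        pd.DataFrame.from_dict(rows, orient="index")
        .sort_values("edges_total", ascending=False)
    )
    return net, summary
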