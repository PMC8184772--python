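"""Immune-feature correlation network: edges, communities, layout.

Nodes are (subset, marker) response features; edges connect feature pairs
whose Spearman correlation over all samples (both gravity conditions
pooled) stays significant after Bonferroni adjustment over all C(n, 2)
pairs at the 0.05 family level. Communities come from greedy modularity
maximization on |rho|-weighted edges; each community is annotated by its
most frequent functional marker. The 2-D layout embeds nodes by t-SNE on
the 1 - |rho| distance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

BONFERRONI_ALPHA = 0.05


@dataclass
class CorrelationNetwork:
    nodes: list  # feature ids (tuples or strings)
    rho: np.ndarray  # symmetric correlation matrix
    p: np.ndarray  # symmetric raw p-value matrix
    adjacency: np.ndarray  # boolean, Bonferroni-significant edges
    excluded: list = field(default_factory=list)  # constant features, dropped
    community: dict = field(default_factory=dict)  # node -> int label
    layout: dict = field(default_factory=dict)  # node -> (x, y)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, node in enumerate(self.nodes):
            name = node if isinstance(node, str) else "|".join(map(str, node))
            g.add_node(
                name,
                community=int(self.community.get(node, -1)),
                x=float(self.layout.get(node, (0.0, 0.0))[0]),
                y=float(self.layout.get(node, (0.0, 0.0))[1]),
            )
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                if self.adjacency[i, j]:
                    ni = self.nodes[i] if isinstance(self.nodes[i], str) else "|".join(map(str, self.nodes[i]))
                    nj = self.nodes[j] if isinstance(self.nodes[j], str) else "|".join(map(str, self.nodes[j]))
                    g.add_edge(ni, nj, rho=float(self.rho[i, j]), p=float(self.p[i, j]))
        return g

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                rows.append(
                    {
                        "node1": _node_name(self.nodes[i]),
                        "node2": _node_name(self.nodes[j]),
                        "rho": float(self.rho[i, j]),
                        "p": float(self.p[i, j]),
                        "significant": bool(self.adjacency[i, j]),
                    }
                )
        return pd.DataFrame(rows, columns=["node1", "node2", "rho", "p", "significant"])


def _node_name(node) -> str:
    return node if isinstance(node, str) else "|".join(map(str, node))


def _spearman_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman rho and two-sided p-values for all column pairs.

    Midranks throughout. For tie-free column pairs at sample sizes with
    an exact S-distribution available, the p-value is the exact
    permutation tail (see :mod:`cytogravity.spearman_exact`); the t
    approximation is the fallback. The exact tail keeps the Bonferroni
    edge criterion honest: the t approximation is ~2x liberal at
    family-wise thresholds for n around 16.
    """
    from .spearman_exact import s_null_pmf

    n = X.shape[0]
    ranks = np.apply_along_axis(sps.rankdata, 0, X)
    rho = np.corrcoef(ranks, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)

    pmf = s_null_pmf(n)
    if pmf is not None:
        tie_free = np.array([np.unique(col).size == n for col in ranks.T])
        if tie_free.any():
            idx = np.flatnonzero(tie_free)
            R = ranks[:, idx]
            c = n * (n + 1) * (2 * n + 1) // 6  # sum of squared ranks
            S = 2.0 * c - 2.0 * (R.T @ R)  # S_ij = sum((r_i - r_j)^2)
            k = np.clip(np.rint(S / 2.0).astype(int), 0, pmf.size - 1)
            cdf = np.cumsum(pmf)
            p_le = cdf[k]
            p_ge = 1.0 - np.where(k > 0, cdf[np.maximum(k - 1, 0)], 0.0)
            p_exact = np.minimum(1.0, 2.0 * np.minimum(p_le, p_ge))
            p[np.ix_(idx, idx)] = p_exact
    np.fill_diagonal(p, 1.0)
    return rho, p


def build_network(features) -> CorrelationNetwork:
    """Construct the Bonferroni-thresholded Spearman correlation network.

    ``features`` is a :class:`~cytogravity.features.FeatureMatrix` or a
    DataFrame (rows = samples, columns = features). Constant or
    incomplete columns are excluded with a record. The edge criterion is
    raw p * C(n_nodes, 2) < 0.05.
    """
    df = features.data if hasattr(features, "data") else pd.DataFrame(features)
    if df.shape[0] < 4:
        raise ValueError("need at least 4 sample rows")
    keep, excluded = [], []
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        if np.isnan(v).any() or np.ptp(v) == 0:
            excluded.append(col)
        else:
            keep.append(col)
    if len(keep) < 2:
        raise ValueError("need at least 2 usable feature columns")
    X = df[keep].to_numpy(dtype=float)
    rho, p = _spearman_matrix(X)
    n_nodes = len(keep)
    m_pairs = n_nodes * (n_nodes - 1) // 2
    adjacency = (p * m_pairs) < BONFERRONI_ALPHA
    np.fill_diagonal(adjacency, False)
    adjacency &= adjacency.T
    return CorrelationNetwork(
        nodes=list(keep), rho=rho, p=p, adjacency=adjacency, excluded=excluded
    )


def detect_communities(net: CorrelationNetwork, seed: int = 0) -> dict:
    """Modularity-maximizing communities of the significant-edge graph.

    Edges are weighted by |rho|; isolated nodes receive singleton labels.
    Greedy modularity maximization is deterministic, so ``seed`` is
    recorded for interface stability but consumes no randomness.
    """
    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    for i in range(net.n_nodes):
        for j in range(i + 1, net.n_nodes):
            if net.adjacency[i, j]:
                g.add_edge(i, j, weight=abs(float(net.rho[i, j])))

    labels: dict = {}
    connected = [n for n in g.nodes if g.degree(n) > 0]
    next_label = 0
    if connected:
        sub = g.subgraph(connected)
        comms = nx.algorithms.community.greedy_modularity_communities(sub, weight="weight")
        comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c))
        for members in comms:
            for i in members:
                labels[net.nodes[i]] = next_label
            next_label += 1
    for i in range(net.n_nodes):
        if net.nodes[i] not in labels:
            labels[net.nodes[i]] = next_label
            next_label += 1
    net.community = labels
    return labels


def annotate_communities(labels: dict, marker_of=None) -> dict:
    """Name each community by its most frequent functional marker.

    ``marker_of`` maps a feature id to its marker; by default the second
    element of a (subset, marker, ...) tuple, or the second ``|``-field
    of a string id. Ties are broken alphabetically and flagged.
    """
    if marker_of is None:
        def marker_of(node):
            if isinstance(node, str):
                parts = node.split("|")
                return parts[1] if len(parts) > 1 else node
            return node[1]

    groups: dict[int, list] = {}
    for node, lab in labels.items():
        groups.setdefault(lab, []).append(marker_of(node))
    out = {}
    for lab, markers in groups.items():
        counts = Counter(markers)
        top = max(counts.values())
        winners = sorted(m for m, c in counts.items() if c == top)
        out[lab] = {"attribute": winners[0], "tie": len(winners) > 1, "size": len(markers)}
    return out


def layout_2d(net: CorrelationNetwork, seed: int = 0, perplexity: float | None = None) -> dict:
    """t-SNE embedding of the nodes using the 1 - |rho| distance."""
    n = net.n_nodes
    if n == 1:
        net.layout = {net.nodes[0]: (0.0, 0.0)}
        return net.layout
    dist = 1.0 - np.abs(net.rho)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    perplexity = max(1.0, min(perplexity, (n - 1) / 1.01))

    from sklearn.manifold import TSNE

    emb = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        random_state=seed,
        perplexity=perplexity,
    ).fit_transform(dist)
    if not np.isfinite(emb).all():
        raise RuntimeError("t-SNE produced non-finite coordinates")
    net.layout = {node: (float(x), float(y)) for node, (x, y) in zip(net.nodes, emb)}
    return net.layout
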