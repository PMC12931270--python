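"""Per-group co-occurrence network construction, topology profiling, keystones.

Networks retain an edge (i, j) iff ``|r_ij|`` strictly exceeds the correlation
threshold AND the edge's resampling p-value is below alpha; isolated nodes are
dropped, so the node count is the number of connected ASVs.  Topology metrics
follow the usual whole-graph summaries (density, transitivity, Louvain
modularity, Freeman centralizations normalised by the star-graph maximum);
path-based metrics average over connected pairs only and can use either hop
counts or dissimilarity weights ``1 - |r|``.

Keystone taxa are scored by a weighted composite of within-network z-scores:
high degree, high closeness, high local transitivity, and *low* betweenness;
the top 10% by composite are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np
import pandas as pd

from .io import GROUP_LEVELS, CoNetwork, CountTable, SampleMetadata
from .sparcc import CorrelationResult


@dataclass
class TopologyReport:
    """Whole-network metric vector for one group's co-occurrence network."""

    nodes: int = 0
    edges: int = 0
    average_degree: float = math.nan
    average_path_length: float = math.nan
    diameter: float = math.nan
    density: float = math.nan
    clustering_coefficient: float = math.nan        # global transitivity
    clustering_coefficient_local: float = math.nan  # mean local clustering
    modularity: float = math.nan
    betweenness_centralization: float = math.nan
    closeness_centralization: float = math.nan
    eigenvector_centralization: float = math.nan
    degree_assortativity: float = math.nan
    average_nearest_neighbor_degree: float = math.nan

    def to_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})


def downsample_groups(table: CountTable, metadata: SampleMetadata,
                      target_n: int | None = None, seed: int = 0) -> dict:
    """Reduce every group to ``target_n`` samples (default: the smallest
    group's size) by seeded sampling without replacement.

    Returns ``{group: CountTable}``.  Groups already at ``target_n`` keep their
    full sample set.
    """
    rng = np.random.default_rng(seed)
    sizes = {g: n for g, n in metadata.group_sizes().items() if n > 0}
    if target_n is None:
        target_n = min(sizes.values())
    out = {}
    for g in GROUP_LEVELS:
        if g not in sizes:
            continue
        members = [s for s in metadata.samples_in_group(g) if s in table.sample_ids]
        if target_n > len(members):
            raise ValueError(
                f"target_n={target_n} exceeds group {g!r} size {len(members)}"
            )
        if len(members) == target_n:
            chosen = members
        else:
            chosen = sorted(rng.choice(members, size=target_n, replace=False))
        out[g] = table.select_samples(chosen)
    return out


def build_network(cor: CorrelationResult, threshold: float = 0.3,
                  alpha: float = 0.05, abundance: dict | None = None,
                  group: str = "") -> CoNetwork:
    """Threshold a correlation result into a co-occurrence network.

    Edge rule: ``|r| > threshold`` (strict) AND ``p < alpha``; when the result
    carries no p matrix only the correlation clause applies.  Isolated nodes
    are dropped.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    g = nx.Graph()
    r, p = cor.r, cor.p
    ids = cor.taxon_ids
    d = len(ids)
    iu = np.triu_indices(d, 1)
    keep = np.abs(r[iu]) > threshold
    if p is not None:
        keep &= p[iu] < alpha
    for i, j, rv in zip(iu[0][keep], iu[1][keep], r[iu][keep]):
        g.add_edge(ids[i], ids[j], r=float(rv))
    abundance = abundance or {}
    for node in g.nodes:
        g.nodes[node]["relative_abundance"] = float(abundance.get(node, 0.0))
    return CoNetwork(g, threshold=threshold, group=group)


def mean_relative_abundance(table: CountTable) -> dict:
    """Per-taxon mean of per-sample relative abundance (node-size attribute)."""
    depths = table.depths.astype(float)
    fractions = table.counts / depths[:, None]
    return dict(zip(table.taxon_ids, fractions.mean(axis=0)))


def _freeman_centralization(values: dict, measure: str, g: nx.Graph) -> float:
    """Freeman centralization: sum(c_max - c_i) over the star-graph maximum.

    The normaliser is obtained by evaluating the same centrality on the star
    K_{1, n-1} with the same node count, which is the maximiser in Freeman's
    formulation; graphs where the star sum is 0 (n <= 2) yield NaN.
    """
    n = g.number_of_nodes()
    if n < 3:
        return math.nan
    vals = np.array(list(values.values()), dtype=float)
    numer = (vals.max() - vals).sum()
    star = nx.star_graph(n - 1)
    star_vals = np.array(list(_centrality(star, measure).values()))
    denom = (star_vals.max() - star_vals).sum()
    return float(numer / denom) if denom > 0 else math.nan


def _centrality(g: nx.Graph, measure: str) -> dict:
    if measure == "degree":
        return nx.degree_centrality(g)
    if measure == "betweenness":
        return nx.betweenness_centrality(g, normalized=True)
    if measure == "closeness":
        return nx.closeness_centrality(g)
    if measure == "eigenvector":
        # dense symmetric eigendecomposition: deterministic, unlike the
        # ARPACK route with its random start vector
        nodes = list(g.nodes)
        if not nodes:
            return {}
        a = nx.to_numpy_array(g, nodelist=nodes)
        vals, vecs = np.linalg.eigh(a)
        lead = np.abs(vecs[:, -1])
        norm = np.linalg.norm(lead)
        lead = lead / norm if norm > 0 else lead
        return dict(zip(nodes, lead))
    raise ValueError(f"unknown centrality {measure!r}")


def _path_metrics(g: nx.Graph, mode: str) -> tuple:
    """(average path length, diameter) over connected pairs only."""
    if mode == "dissimilarity_weighted":
        h = g.copy()
        for u, v, d in h.edges(data=True):
            d["length"] = 1.0 - abs(d["r"])
        lengths = dict(nx.all_pairs_dijkstra_path_length(h, weight="length"))
    else:
        lengths = dict(nx.all_pairs_shortest_path_length(g))
    dists = [d for u, row in lengths.items() for v, d in row.items() if u != v]
    if not dists:
        return math.nan, math.nan
    return float(np.mean(dists)), float(np.max(dists))


def topology(net: CoNetwork, mode: str = "unweighted", seed: int = 0,
             metrics=None) -> TopologyReport:
    """Compute the topology profile of one network.

    ``mode`` controls path-based metrics only: ``unweighted`` hop counts or
    ``dissimilarity_weighted`` shortest paths with edge length ``1 - |r|``.
    ``metrics`` optionally restricts computation to the named report fields
    (node/edge counts are always filled); the expensive path and centrality
    summaries are skipped when not requested.
    """
    if mode not in ("unweighted", "dissimilarity_weighted"):
        raise ValueError(f"unknown mode {mode!r}")

    def want(name: str) -> bool:
        return metrics is None or name in metrics

    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    rep = TopologyReport(nodes=n, edges=e)
    if n == 0:
        return rep
    rep.average_degree = 2.0 * e / n
    rep.density = e / (n * (n - 1) / 2.0) if n > 1 else math.nan
    if want("average_path_length") or want("diameter"):
        rep.average_path_length, rep.diameter = _path_metrics(g, mode)
    if want("clustering_coefficient"):
        rep.clustering_coefficient = nx.transitivity(g)
    if want("clustering_coefficient_local"):
        rep.clustering_coefficient_local = nx.average_clustering(g)
    if want("modularity") and e > 0:
        communities = nx.community.louvain_communities(g, seed=seed)
        rep.modularity = nx.community.modularity(g, communities)
    for measure in ("betweenness", "closeness", "eigenvector"):
        field_name = f"{measure}_centralization"
        if want(field_name):
            setattr(rep, field_name, _freeman_centralization(
                _centrality(g, measure), measure, g))
    if want("degree_assortativity"):
        with np.errstate(invalid="ignore", divide="ignore"):
            try:
                rep.degree_assortativity = float(
                    nx.degree_assortativity_coefficient(g))
            except Exception:
                rep.degree_assortativity = math.nan
    if want("average_nearest_neighbor_degree"):
        annd = nx.average_neighbor_degree(g)
        rep.average_nearest_neighbor_degree = float(np.mean(list(annd.values())))
    return rep


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def keystone_scores(net: CoNetwork,
                    weights: tuple = (0.25, 0.25, 0.25, 0.25)) -> pd.DataFrame:
    """Composite keystone score per node and the top-10% keystone flag.

    ``weights = (w_deg, w_close, w_trans, w_betw)``, all non-negative:
    composite = w_deg z(degree) + w_close z(closeness) + w_trans z(local
    transitivity) - w_betw z(betweenness).  Exactly ``ceil(0.10 N)`` nodes are
    flagged; ties break by higher degree, then lexicographic id.
    """
    w_deg, w_close, w_trans, w_betw = weights
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    if sum(weights) == 0:
        raise ValueError("at least one weight must be positive")
    g = net.graph
    nodes = sorted(g.nodes)
    if not nodes:
        return pd.DataFrame(columns=["degree", "betweenness", "closeness",
                                     "eigenvector", "local_transitivity",
                                     "keystone_composite", "keystone_flag"])
    deg = dict(g.degree())
    betw = nx.betweenness_centrality(g, normalized=True)
    close = nx.closeness_centrality(g)
    eig = _centrality(g, "eigenvector")
    trans = nx.clustering(g)
    df = pd.DataFrame({
        "degree": [deg[v] for v in nodes],
        "betweenness": [betw[v] for v in nodes],
        "closeness": [close[v] for v in nodes],
        "eigenvector": [eig[v] for v in nodes],
        "local_transitivity": [trans[v] for v in nodes],
    }, index=nodes)
    df["keystone_composite"] = (
        w_deg * _zscore(df["degree"].to_numpy())
        + w_close * _zscore(df["closeness"].to_numpy())
        + w_trans * _zscore(df["local_transitivity"].to_numpy())
        - w_betw * _zscore(df["betweenness"].to_numpy())
    )
    k = math.ceil(0.10 * len(nodes))
    order = df.sort_values(
        by=["keystone_composite", "degree"], ascending=[False, False],
        kind="mergesort",
    )
    flagged = set(order.index[:k])
    df["keystone_flag"] = [v in flagged for v in df.index]
    return df


def jaccard(a: set, b: set) -> float:
    union = set(a) | set(b)
    if not union:
        return math.nan
    return len(set(a) & set(b)) / len(union)


def threshold_sensitivity(cor: CorrelationResult,
                          thresholds: tuple = (0.2, 0.3, 0.4),
                          alpha: float = 0.05, mode: str = "unweighted",
                          weights: tuple = (0.25, 0.25, 0.25, 0.25),
                          seed: int = 0) -> dict:
    """Topology and keystone stability across correlation thresholds.

    Returns ``{"topology": DataFrame, "keystones": {thr: set},
    "keystone_jaccard": DataFrame}`` with pairwise Jaccard similarity of the
    keystone sets across thresholds.
    """
    thresholds = sorted(thresholds)
    if len(thresholds) < 2:
        raise ValueError("need >= 2 thresholds")
    topo_rows, keys = {}, {}
    for thr in thresholds:
        net = build_network(cor, threshold=thr, alpha=alpha)
        topo_rows[thr] = topology(net, mode=mode, seed=seed).to_series()
        scores = keystone_scores(net, weights)
        keys[thr] = set(scores.index[scores["keystone_flag"]]) if len(scores) else set()
    jac = pd.DataFrame(
        [[jaccard(keys[a], keys[b]) for b in thresholds] for a in thresholds],
        index=thresholds, columns=thresholds,
    )
    return {"topology": pd.DataFrame(topo_rows).T, "keystones": keys,
            "keystone_jaccard": jac}
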