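"""Pairwise comparison of group co-occurrence networks.

Four complementary comparisons:

* ``permute_compare`` — permutation test on any topology metric: the null
  pools the two groups' samples, re-splits them at the original sizes, and
  re-runs the whole inference pipeline per permutation (at reduced SparCC
  fidelity by default, so a thousand permutations stay desk-feasible).
* ``jaccard_central`` — Jaccard similarity of each network's most-central
  node sets (above an empirical quantile), with hypergeometric tail
  probabilities for the overlap.
* ``network_dissimilarity`` — a D-measure in [0, 1] combining the
  Jensen-Shannon divergence of the networks' node-distance distributions,
  the difference in network node dispersion, and an alpha-centrality profile
  divergence of the graphs and their complements.
* ``method_agreement`` — edge counts and edge-set Jaccard for two correlation
  methods thresholded identically (SparCC vs Spearman).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import jensenshannon

from .io import CoNetwork, CountTable
from .netbuild import build_network, mean_relative_abundance, topology
from .sparcc import (CorrelationResult, edge_significance, sparcc_correlation)

DEFAULT_METRICS = ("edges", "density", "average_degree", "modularity",
                   "clustering_coefficient", "average_path_length")


@dataclass
class PipelineParams:
    """Settings for one correlation -> network inference pass."""

    n_outer: int = 20
    n_resamples: int = 100
    significance: bool = True
    threshold: float = 0.3
    alpha: float = 0.05
    prior: float = 1.0
    n_outer_null: int = 5
    path_mode: str = "unweighted"

    def reduced(self) -> "PipelineParams":
        """Reduced-fidelity settings for inside permutation nulls."""
        return PipelineParams(n_outer=5, n_resamples=20,
                              significance=self.significance,
                              threshold=self.threshold, alpha=self.alpha,
                              prior=self.prior, n_outer_null=2,
                              path_mode=self.path_mode)


@dataclass
class ComparisonResult:
    group_pair: tuple
    observed: pd.DataFrame            # columns: value_a, value_b, difference
    p_values: dict = field(default_factory=dict)
    n_perm: int = 0
    dissimilarity: float = math.nan

    def to_frame(self) -> pd.DataFrame:
        df = self.observed.copy()
        df["p"] = pd.Series(self.p_values)
        return df


def network_from_table(table: CountTable, params: PipelineParams, seed: int = 0,
                       group: str = "") -> CoNetwork:
    """Run the SparCC -> significance -> threshold pipeline on one table."""
    r = sparcc_correlation(table, n_outer=params.n_outer, seed=seed,
                           prior=params.prior)
    p = None
    if params.significance and params.n_resamples > 0:
        p = edge_significance(table, r, n_resamples=params.n_resamples,
                              seed=seed + 1, n_outer=params.n_outer_null,
                              prior=params.prior)
    cor = CorrelationResult(list(table.taxon_ids), r, p, method="sparcc",
                            n_outer_iterations=params.n_outer,
                            n_resamples=params.n_resamples if p is not None else 0,
                            resampling_mode="permutation" if p is not None else "")
    return build_network(cor, threshold=params.threshold, alpha=params.alpha,
                         abundance=mean_relative_abundance(table), group=group)


def _metric_vector(net: CoNetwork, metrics, params: PipelineParams,
                   seed: int = 0) -> pd.Series:
    rep = topology(net, mode=params.path_mode, seed=seed,
                   metrics=set(metrics)).to_series()
    return rep[list(metrics)]


#: metrics derivable from edge counts alone (no graph construction needed)
_COUNT_METRICS = {"nodes", "edges", "density", "average_degree"}


def _fast_count_vector(table: CountTable, params: PipelineParams, metrics,
                       seed: int) -> pd.Series:
    """Edge-count metrics straight from the thresholded correlation matrix."""
    r = sparcc_correlation(table, n_outer=params.n_outer, seed=seed,
                           prior=params.prior)
    d = r.shape[0]
    iu = np.triu_indices(d, 1)
    keep = np.abs(r[iu]) > params.threshold
    e = int(keep.sum())
    connected = np.zeros(d, dtype=bool)
    connected[iu[0][keep]] = True
    connected[iu[1][keep]] = True
    n = int(connected.sum())
    vals = {"nodes": n, "edges": e,
            "average_degree": 2.0 * e / n if n else math.nan,
            "density": e / (n * (n - 1) / 2.0) if n > 1 else math.nan}
    return pd.Series({m: vals[m] for m in metrics})


def permute_compare(table_a: CountTable, table_b: CountTable,
                    params: PipelineParams | None = None,
                    metrics=DEFAULT_METRICS, n_perm: int = 1000, seed: int = 0,
                    null_params: PipelineParams | None = None,
                    observed: tuple | None = None) -> ComparisonResult:
    """Permutation test of topology-metric differences between two groups.

    The null pools all samples, re-splits at the original group sizes, and
    re-runs the full pipeline for both pseudo-groups (at ``null_params``
    fidelity, by default a reduced-resampling version of ``params``).
    ``p = (1 + #{|diff_perm| >= |diff_obs|}) / (n_valid + 1)``; permutations
    where either side of a metric is undefined (NaN) are excluded for that
    metric.  Pass ``observed=(net_a, net_b)`` to reuse already-inferred group
    networks instead of re-running the observed inference.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if table_a.taxon_ids != table_b.taxon_ids:
        raise ValueError("tables must share the same taxon universe")
    params = params or PipelineParams()
    null_params = null_params or params.reduced()
    rng = np.random.default_rng(seed)

    if observed is not None:
        net_a, net_b = observed
        rng.integers(2 ** 31)  # keep the seed stream aligned with the
        rng.integers(2 ** 31)  # two observed-inference draws
    else:
        net_a = network_from_table(table_a, params, seed=int(rng.integers(2 ** 31)))
        net_b = network_from_table(table_b, params, seed=int(rng.integers(2 ** 31)))
    vec_a = _metric_vector(net_a, metrics, params)
    vec_b = _metric_vector(net_b, metrics, params)
    obs_diff = vec_a - vec_b

    pooled = np.vstack([table_a.counts, table_b.counts])
    n_a, n_total = table_a.n_samples, pooled.shape[0]
    taxa = list(table_a.taxon_ids)
    # count-only metrics under a threshold-only null skip graph construction
    fast_null = (not null_params.significance
                 and set(metrics) <= _COUNT_METRICS)

    exceed = pd.Series(0.0, index=list(metrics))
    valid = pd.Series(0, index=list(metrics))
    for _ in range(n_perm):
        order = rng.permutation(n_total)
        perm_a = CountTable([f"a{i}" for i in range(n_a)], taxa,
                            pooled[order[:n_a]])
        perm_b = CountTable([f"b{i}" for i in range(n_total - n_a)], taxa,
                            pooled[order[n_a:]])
        if fast_null:
            va = _fast_count_vector(perm_a, null_params, metrics,
                                    int(rng.integers(2 ** 31)))
            vb = _fast_count_vector(perm_b, null_params, metrics,
                                    int(rng.integers(2 ** 31)))
            diff = va - vb
        else:
            pa = network_from_table(perm_a, null_params,
                                    seed=int(rng.integers(2 ** 31)))
            pb = network_from_table(perm_b, null_params,
                                    seed=int(rng.integers(2 ** 31)))
            diff = (_metric_vector(pa, metrics, null_params)
                    - _metric_vector(pb, metrics, null_params))
        ok = diff.notna() & obs_diff.notna()
        valid[ok] += 1
        exceed[ok & (diff.abs() >= obs_diff.abs())] += 1

    p_values = {}
    for m in metrics:
        p_values[m] = ((1.0 + exceed[m]) / (valid[m] + 1.0)
                       if valid[m] > 0 and not math.isnan(obs_diff[m]) else math.nan)
    observed = pd.DataFrame({"value_a": vec_a, "value_b": vec_b,
                             "difference": obs_diff})
    return ComparisonResult((net_a.group or "A", net_b.group or "B"), observed,
                            p_values, n_perm,
                            dissimilarity=network_dissimilarity(net_a, net_b)
                            if net_a.n_nodes and net_b.n_nodes else math.nan)


# ---------------------------------------------------------------------------
# Jaccard of most-central node sets
# ---------------------------------------------------------------------------

def _top_set(net: CoNetwork, measure: str, quantile: float) -> set:
    from .netbuild import _centrality  # shared centrality conventions
    if measure == "degree":
        vals = dict(net.graph.degree())
    else:
        vals = _centrality(net.graph, measure)
    if not vals:
        return set()
    cut = np.quantile(list(vals.values()), quantile)
    return {v for v, c in vals.items() if c > cut}


def jaccard_central(net_a: CoNetwork, net_b: CoNetwork, measure: str = "degree",
                    quantile: float = 0.75):
    """Jaccard of the two networks' top-central node sets with hypergeometric
    tail probabilities ``(jaccard, p_le, p_ge)`` for the observed overlap.

    Returns NaNs when either top set is empty (flagged undefined).
    """
    if measure not in ("degree", "betweenness", "closeness", "eigenvector"):
        raise ValueError(f"unknown measure {measure!r}")
    if net_a.n_nodes == 0 or net_b.n_nodes == 0:
        raise ValueError("both networks must be non-empty")
    top_a = _top_set(net_a, measure, quantile)
    top_b = _top_set(net_b, measure, quantile)
    if not top_a or not top_b:
        return math.nan, math.nan, math.nan
    union = top_a | top_b
    j = len(top_a & top_b) / len(union)
    universe = set(net_a.graph.nodes) | set(net_b.graph.nodes)
    rv = scipy.stats.hypergeom(len(universe), len(top_a), len(top_b))
    k = len(top_a & top_b)
    return float(j), float(rv.cdf(k)), float(rv.sf(k - 1))


# ---------------------------------------------------------------------------
# D-measure network dissimilarity
# ---------------------------------------------------------------------------

def _distance_distributions(g: nx.Graph, n_bins: int) -> np.ndarray:
    """Per-node distributions over hop distances 1..n_bins-1; the last bin
    holds unreachable pairs.  Shape (n_nodes, n_bins)."""
    nodes = list(g.nodes)
    n = len(nodes)
    out = np.zeros((n, n_bins))
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    for i, u in enumerate(nodes):
        row = lengths.get(u, {u: 0})
        reached = 0
        for v, d in row.items():
            if v == u:
                continue
            out[i, min(d - 1, n_bins - 2)] += 1
            reached += 1
        out[i, n_bins - 1] = (n - 1) - reached
        if n > 1:
            out[i] /= n - 1
        else:
            out[i, n_bins - 1] = 1.0
    return out


def _nnd(dists: np.ndarray, diameter: int) -> float:
    """Network node dispersion: mean KL of node distributions to their mean,
    normalised by log(diameter + 1)."""
    mu = dists.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dists > 0, dists / np.where(mu > 0, mu, 1.0), 1.0)
        j = float(np.sum(dists * np.log(ratio)) / dists.shape[0])
    if diameter < 1:
        return 0.0
    return max(j, 0.0) / math.log(diameter + 1)


def _alpha_centrality_profile(g: nx.Graph, size: int) -> np.ndarray:
    """Sorted, normalised alpha-centrality vector padded with zeros."""
    n = g.number_of_nodes()
    if n == 0:
        return np.zeros(size)
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
    alpha = 1.0 / n
    try:
        c = np.linalg.solve(np.eye(n) - alpha * a, np.ones(n))
    except np.linalg.LinAlgError:
        c, *_ = np.linalg.lstsq(np.eye(n) - alpha * a, np.ones(n), rcond=None)
    c = np.abs(c)
    total = c.sum()
    c = c / total if total > 0 else np.full(n, 1.0 / n)
    c = np.sort(c)[::-1]
    out = np.zeros(size)
    out[:n] = c
    return out


def _graph_diameter_bound(g: nx.Graph) -> int:
    comp_diams = [nx.diameter(g.subgraph(c)) for c in nx.connected_components(g)]
    return max(comp_diams) if comp_diams else 0


def network_dissimilarity(net_a: CoNetwork, net_b: CoNetwork,
                          weights: tuple = (0.45, 0.45, 0.10)) -> float:
    """Schieber-style D-measure between two networks, in [0, 1].

    ``w1 * sqrt(JS(mu_A, mu_B) / log 2)`` on the averaged node-distance
    distributions, ``w2 * |sqrt(NND_A) - sqrt(NND_B)|`` on network node
    dispersion, and ``w3/2`` times the alpha-centrality profile divergences of
    the graphs and of their complements.  Zero on identical graphs; symmetric.
    """
    if not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
        raise ValueError("weights must sum to 1")
    w1, w2, w3 = weights
    ga, gb = net_a.graph, net_b.graph
    if ga.number_of_nodes() == 0 or gb.number_of_nodes() == 0:
        raise ValueError("both networks must be non-empty")

    n_bins = max(ga.number_of_nodes(), gb.number_of_nodes()) + 1
    da = _distance_distributions(ga, n_bins)
    db = _distance_distributions(gb, n_bins)
    mu_a, mu_b = da.mean(axis=0), db.mean(axis=0)
    term1 = float(jensenshannon(mu_a, mu_b, base=2)) if not np.allclose(mu_a, mu_b) else 0.0

    nnd_a = _nnd(da, _graph_diameter_bound(ga))
    nnd_b = _nnd(db, _graph_diameter_bound(gb))
    term2 = abs(math.sqrt(nnd_a) - math.sqrt(nnd_b))

    size = max(ga.number_of_nodes(), gb.number_of_nodes())
    pa, pb = (_alpha_centrality_profile(ga, size),
              _alpha_centrality_profile(gb, size))
    ca, cb = (_alpha_centrality_profile(nx.complement(ga), size),
              _alpha_centrality_profile(nx.complement(gb), size))
    div_g = float(jensenshannon(pa, pb, base=2)) if not np.allclose(pa, pb) else 0.0
    div_c = float(jensenshannon(ca, cb, base=2)) if not np.allclose(ca, cb) else 0.0
    term3 = 0.5 * (div_g + div_c)

    return float(np.clip(w1 * term1 + w2 * term2 + w3 * term3, 0.0, 1.0))


def topology_distance(rep_a: pd.Series, rep_b: pd.Series, metrics=None) -> float:
    """Simpler alternative dissimilarity: Euclidean distance between z-scored
    topology vectors (z-scored across the two networks jointly)."""
    metrics = metrics or [m for m in rep_a.index if m not in ("nodes", "edges")]
    a = rep_a[metrics].to_numpy(dtype=float)
    b = rep_b[metrics].to_numpy(dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    scale = np.maximum(np.abs(np.vstack([a, b])).max(axis=0), 1e-12)
    return float(np.linalg.norm((a - b) / scale))


def method_agreement(cor_a: CorrelationResult, cor_b: CorrelationResult,
                     threshold: float = 0.3, alpha: float = 0.05) -> dict:
    """Edge counts and edge-set Jaccard for two methods at identical thresholds."""
    if cor_a.taxon_ids != cor_b.taxon_ids:
        raise ValueError("correlation results must share the same taxon universe")
    net_a = build_network(cor_a, threshold=threshold, alpha=alpha)
    net_b = build_network(cor_b, threshold=threshold, alpha=alpha)
    ea, eb = net_a.edge_set(), net_b.edge_set()
    union = ea | eb
    return {
        "edges_a": len(ea),
        "edges_b": len(eb),
        "shared_edges": len(ea & eb),
        "jaccard": (len(ea & eb) / len(union)) if union else math.nan,
    }
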