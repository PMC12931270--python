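"""Sparse Correlations for Compositional Data (SparCC), from scratch.

Read counts carry only relative information: closing a sample to fractions
induces spurious negative correlation between taxa (with two taxa the closure
forces r = -1 exactly).  SparCC instead estimates correlations between the
latent *basis* abundances from the matrix of log-ratio variances

    T_ij = Var[ ln(f_i / f_j) ] = w_i + w_j - 2 rho_ij sqrt(w_i w_j),

where ``w_i`` is the basis variance of taxon i on the log scale.  Under a
sparsity assumption (most true correlations are ~0) the basis variances are
recovered by solving a linear system in the row sums of T, and strongly
correlated pairs that violate the assumption are iteratively excluded from the
row sums.  Uncertainty in the fractions themselves is integrated out by
re-drawing fractions from a per-sample Dirichlet posterior over several outer
iterations and taking the elementwise median.

Edge significance is assessed by resampling: the default permutation mode
shuffles every taxon's counts across samples independently (a proper
no-association null); a bootstrap sign-stability mode is also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .io import CountTable
from .preprocess import relative_abundance

log = logging.getLogger(__name__)

#: floor applied to non-positive basis-variance estimates
BASIS_VARIANCE_FLOOR = 1e-6

_clamp_warned = False


@dataclass
class CorrelationResult:
    """Symmetric taxon x taxon correlation estimate with edge significance."""

    taxon_ids: list
    r: np.ndarray
    p: np.ndarray | None = None
    method: str = "sparcc"
    n_outer_iterations: int = 0
    n_resamples: int = 0
    resampling_mode: str = ""
    constant_taxa: list = field(default_factory=list)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape != (len(self.taxon_ids),) * 2:
            raise ValueError("r shape inconsistent with taxon_ids")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("r must be symmetric")
        if np.nanmax(np.abs(r)) > 1 + 1e-9:
            raise ValueError("|r| must be <= 1")
        self.r = r

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


def log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """Matrix T of sample variances (ddof=1) of ``ln(f_i / f_j)``.

    ``fractions`` is samples x taxa, strictly positive, rows summing to 1.
    Computed via the log-abundance covariance: T_ij = C_ii + C_jj - 2 C_ij,
    which is invariant to any per-sample scaling of the basis.
    """
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 2 or f.shape[0] < 2:
        raise ValueError("need a 2-D fractions matrix with >= 2 samples")
    if np.any(f <= 0):
        raise ValueError("fractions must be strictly positive; add a pseudocount first")
    x = np.log(f)
    c = np.cov(x, rowvar=False, ddof=1)
    v = np.diag(c)
    t = v[:, None] + v[None, :] - 2.0 * c
    np.fill_diagonal(t, 0.0)
    return t


def basis_correlations(t_mat: np.ndarray, exclusion_threshold: float = 0.1,
                       max_exclusions: int = 10) -> np.ndarray:
    """Basis correlation matrix from a log-ratio variance matrix.

    Solves ``M w = t`` for the basis variances (``M`` with D-1 on the diagonal
    and 1 off-diagonal, ``t`` the row sums of T), then iteratively excludes the
    strongest off-diagonal pair with |rho| above ``exclusion_threshold`` from
    the row sums (decrementing the touched diagonal entries of M) and
    re-solves, up to ``max_exclusions`` rounds.  Non-positive variance
    estimates are clamped to a small floor.
    """
    t_mat = np.asarray(t_mat, dtype=float)
    d = t_mat.shape[0]
    if d < 4:
        raise ValueError("SparCC needs >= 4 taxa (sparsity approximation unidentifiable)")

    m = np.ones((d, d)) + np.diag([d - 2.0] * d)
    t_work = t_mat.copy()
    excluded: set = set()
    rho = None
    for round_idx in range(max_exclusions + 1):
        try:
            w = np.linalg.solve(m, t_work.sum(axis=1))
        except np.linalg.LinAlgError:
            # over-exclusion made the system singular (possible at small D);
            # keep the estimate from the previous round
            if rho is not None:
                break
            w, *_ = np.linalg.lstsq(m, t_work.sum(axis=1), rcond=None)
        n_bad = int((w <= 0).sum())
        if n_bad:
            global _clamp_warned
            if not _clamp_warned:  # warn once, then log quietly
                log.warning("clamping %d non-positive basis variance estimate(s) "
                            "to %g (further clamps logged at DEBUG)",
                            n_bad, BASIS_VARIANCE_FLOOR)
                _clamp_warned = True
            else:
                log.debug("clamping %d non-positive basis variance estimate(s)", n_bad)
            w = np.maximum(w, BASIS_VARIANCE_FLOOR)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = np.clip((w[:, None] + w[None, :] - t_mat) / denom, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)

        if len(excluded) >= max_exclusions:
            break
        search = np.abs(rho.copy())
        np.fill_diagonal(search, 0.0)
        for i, j in excluded:
            search[i, j] = search[j, i] = 0.0
        i, j = np.unravel_index(int(np.argmax(search)), search.shape)
        if search[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        t_work[i, j] = t_work[j, i] = 0.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
    return rho


def _dirichlet_fractions(rng: np.random.Generator, counts: np.ndarray,
                         prior: float) -> np.ndarray:
    return np.vstack([rng.dirichlet(row + prior) for row in counts])


def sparcc_correlation(table: CountTable, n_outer: int = 20, seed: int = 0,
                       prior: float = 1.0, exclusion_threshold: float = 0.1,
                       max_exclusions: int = 10) -> np.ndarray:
    """SparCC point estimate: elementwise median over ``n_outer`` outer
    iterations, each drawing per-sample fractions from Dirichlet(counts +
    ``prior``).  Deterministic under ``seed``.
    """
    if n_outer < 1:
        raise ValueError("n_outer must be >= 1")
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_outer):
        fractions = _dirichlet_fractions(rng, table.counts, prior)
        estimates.append(basis_correlations(
            log_ratio_variances(fractions), exclusion_threshold, max_exclusions))
    r = np.median(np.stack(estimates), axis=0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def _spearman_r(fractions: np.ndarray) -> tuple:
    """Spearman rank correlation matrix (mid-rank ties): Pearson correlation
    of per-column mid-ranks.  Constant columns (undefined) reported as 0."""
    ranks = scipy.stats.rankdata(fractions, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ranks, rowvar=False)
    r = np.atleast_2d(np.asarray(r, dtype=float))
    constant = [j for j in range(fractions.shape[1])
                if np.all(fractions[:, j] == fractions[0, j])]
    if constant or np.any(np.isnan(r)):
        r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0), constant


def _estimate_r(counts: np.ndarray, method: str, n_outer: int, prior: float,
                rng: np.random.Generator) -> np.ndarray:
    table = CountTable([f"s{i}" for i in range(counts.shape[0])],
                       [f"t{j}" for j in range(counts.shape[1])], counts)
    if method == "sparcc":
        return sparcc_correlation(table, n_outer=n_outer,
                                  seed=int(rng.integers(2 ** 31)), prior=prior)
    fractions = relative_abundance(table)
    return _spearman_r(fractions)[0]


def edge_significance(table: CountTable, r_obs: np.ndarray, n_resamples: int = 100,
                      mode: str = "permutation", seed: int = 0,
                      method: str = "sparcc", n_outer: int = 5,
                      prior: float = 1.0) -> np.ndarray:
    """Per-pair pseudo p-values for the observed correlations.

    permutation (default): every taxon's counts are shuffled across samples
    independently per resample and the correlation recomputed;
    ``p = (1 + #{|r_perm| >= |r_obs|}) / (n_resamples + 1)``.

    bootstrap: samples are resampled with replacement and p is the add-one
    fraction of replicates whose correlation crosses zero (sign instability).

    Resample correlations use ``n_outer`` Dirichlet iterations (fewer than the
    point estimate's 20 by default; the null only needs the location of the
    resampled distribution).  Diagonal entries are undefined (NaN).
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if mode not in ("permutation", "bootstrap"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    counts = table.counts
    n, d = counts.shape
    exceed = np.zeros((d, d))
    for _ in range(n_resamples):
        if mode == "permutation":
            resampled = np.empty_like(counts)
            for j in range(d):
                resampled[:, j] = counts[rng.permutation(n), j]
        else:
            resampled = counts[rng.integers(0, n, size=n), :]
        r_b = _estimate_r(resampled, method, n_outer, prior, rng)
        if mode == "permutation":
            exceed += np.abs(r_b) >= np.abs(r_obs)
        else:
            exceed += (r_b * r_obs) <= 0
    p = (1.0 + exceed) / (n_resamples + 1.0)
    p = np.minimum(p, p.T)  # symmetrise (estimators are symmetric already)
    np.fill_diagonal(p, np.nan)
    return p


def sparcc(table: CountTable, n_outer: int = 20, n_resamples: int = 100,
           mode: str = "permutation", seed: int = 0, prior: float = 1.0,
           n_outer_null: int = 5, fdr: bool = False) -> CorrelationResult:
    """Full SparCC run: point estimate + edge significance.

    ``fdr=True`` applies Benjamini-Hochberg adjustment across the distinct
    off-diagonal pairs (off by default).
    """
    r = sparcc_correlation(table, n_outer=n_outer, seed=seed, prior=prior)
    p = edge_significance(table, r, n_resamples=n_resamples, mode=mode,
                          seed=seed + 1, method="sparcc", n_outer=n_outer_null,
                          prior=prior)
    if fdr:
        p = _bh_adjust(p)
    return CorrelationResult(list(table.taxon_ids), r, p, method="sparcc",
                             n_outer_iterations=n_outer, n_resamples=n_resamples,
                             resampling_mode=mode)


def spearman_correlation(table: CountTable, n_resamples: int = 100, seed: int = 0,
                         significance: bool = True) -> CorrelationResult:
    """Spearman rank correlation on relative abundances, with the same
    permutation significance machinery as SparCC.  Constant taxa (undefined
    correlation) are reported as r = 0 and listed in ``constant_taxa``.
    """
    fractions = relative_abundance(table)
    r, constant_idx = _spearman_r(fractions)
    p = None
    if significance:
        p = edge_significance(table, r, n_resamples=n_resamples,
                              mode="permutation", seed=seed, method="spearman")
    return CorrelationResult(list(table.taxon_ids), r, p, method="spearman",
                             n_resamples=n_resamples if significance else 0,
                             resampling_mode="permutation" if significance else "",
                             constant_taxa=[table.taxon_ids[j] for j in constant_idx])


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    d = p.shape[0]
    iu = np.triu_indices(d, 1)
    flat = p[iu]
    order = np.argsort(flat)
    m = len(flat)
    adj = np.empty(m)
    running = 1.0
    for rank_pos in range(m - 1, -1, -1):
        idx = order[rank_pos]
        running = min(running, flat[idx] * m / (rank_pos + 1))
        adj[idx] = running
    out = np.full_like(p, np.nan)
    out[iu] = adj
    out.T[iu] = adj
    return out
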