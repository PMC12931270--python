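"""Alpha diversity and distance-based community statistics.

Alpha indices and the distance-matrix permutation tests (ANOSIM, PERMANOVA,
PERMDISP) are computed with scikit-bio; this module fixes the conventions the
pipeline uses (bias-corrected Chao1, natural-log Shannon, Simpson reported as
the 1 - D complement with raw D alongside, add-one permutation p-values) and
adds the pieces skbio does not emit (PERMANOVA R-squared, pairwise ANOSIM with
Bonferroni correction, Kruskal-Wallis effect sizes for alpha indices).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity.alpha import chao1, goods_coverage, shannon, simpson
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.distance import permdisp as _skbio_permdisp

from .io import CountTable, ValidationError


def alpha_diversity(table: CountTable, bias_corrected: bool = True) -> pd.DataFrame:
    """Per-sample alpha indices: chao1, shannon (nats), simpson (1 - D, plus
    raw dominance D), and Good's coverage.

    Chao1 uses the bias-corrected estimator S_obs + F1(F1-1)/(2(F2+1)) by
    default (defined even when no doubletons are observed); pass
    ``bias_corrected=False`` for the classical form.
    """
    if np.any(table.depths == 0):
        raise ValidationError("zero-depth sample; rarefy or drop it first")
    rows = {}
    for i, sid in enumerate(table.sample_ids):
        c = table.counts[i]
        rows[sid] = {
            "chao1": chao1(c, bias_corrected=bias_corrected),
            "shannon": shannon(c, base=math.e),
            "simpson": simpson(c),            # 1 - sum p_i^2
            "simpson_d": 1.0 - simpson(c),    # raw dominance
            "goods_coverage": goods_coverage(c),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples."""
    if table.n_samples < 2:
        raise ValidationError("need >= 2 samples for a distance matrix")
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def _as_labels(dm: DistanceMatrix, groups) -> list:
    if isinstance(groups, pd.Series):
        return [str(groups.loc[i]) for i in dm.ids]
    groups = list(groups)
    if len(groups) != len(dm.ids):
        raise ValidationError("group labels do not match distance matrix size")
    return [str(g) for g in groups]


def _check_group_sizes(labels, minimum: int = 2) -> None:
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValidationError("need >= 2 groups")
    small = counts[counts < minimum]
    if len(small):
        raise ValidationError(f"group(s) below size {minimum}: {list(small.index)}")


def anosim(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0):
    """ANOSIM R statistic and add-one permutation p-value."""
    labels = _as_labels(dm, groups)
    _check_group_sizes(labels)
    res = _skbio_anosim(dm, labels, permutations=n_perm, seed=seed)
    return float(res["test statistic"]), float(res["p-value"])


def anosim_pairwise(dm: DistanceMatrix, groups, n_perm: int = 999,
                    seed: int = 0) -> pd.DataFrame:
    """All pairwise ANOSIMs with Bonferroni-adjusted p (multiplied by the
    number of pairs, capped at 1)."""
    labels = np.array(_as_labels(dm, groups))
    uniq = sorted(set(labels))
    pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]
    rows = []
    for k, (a, b) in enumerate(pairs):
        mask = np.isin(labels, [a, b])
        ids = [i for i, m in zip(dm.ids, mask) if m]
        sub = dm.filter(ids)
        r, p = anosim(sub, labels[mask], n_perm=n_perm, seed=seed + k)
        rows.append({"group_a": a, "group_b": b, "R": r, "p": p,
                     "p_bonferroni": min(1.0, p * len(pairs))})
    return pd.DataFrame(rows)


def _sums_of_squares(dm: DistanceMatrix, labels) -> tuple:
    """(SS_between, SS_total) from squared distances (Gower decomposition)."""
    d2 = dm.data ** 2
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    labels = np.asarray(labels)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total - ss_within, ss_total


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0):
    """One-factor PERMANOVA: (pseudo-F, R2, p).

    R2 = SS_between / SS_total from the Gower-centred partition; p is the
    add-one permutation estimate.
    """
    labels = _as_labels(dm, groups)
    _check_group_sizes(labels)
    res = _skbio_permanova(dm, labels, permutations=n_perm, seed=seed)
    ss_b, ss_t = _sums_of_squares(dm, labels)
    r2 = ss_b / ss_t if ss_t > 0 else 0.0
    return float(res["test statistic"]), float(r2), float(res["p-value"])


def permanova_covariates(dm: DistanceMatrix, metadata: pd.DataFrame,
                         columns, n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Marginal single-factor PERMANOVA scan over metadata columns.

    Continuous covariates are median-split into two bins (a coarse marginal
    screen; the scan is per-covariate, not sequential partitioning).
    """
    rows = []
    for k, col in enumerate(columns):
        vals = metadata.loc[list(dm.ids), col]
        if pd.api.types.is_numeric_dtype(vals):
            labels = (vals > vals.median()).map({True: "high", False: "low"})
        else:
            labels = vals.astype(str)
        try:
            f, r2, p = permanova(dm, labels, n_perm=n_perm, seed=seed + k)
        except ValidationError:
            f, r2, p = float("nan"), float("nan"), float("nan")
        rows.append({"covariate": col, "pseudo_F": f, "R2": r2, "p": p})
    return pd.DataFrame(rows)


def permdisp(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0,
             test: str = "centroid"):
    """Homogeneity of multivariate dispersion: (F, p).

    Per-sample distances to the group centroid in principal-coordinate space
    (``test="median"`` selects the spatial-median variant).
    """
    labels = _as_labels(dm, groups)
    _check_group_sizes(labels)
    res = _skbio_permdisp(dm, labels, permutations=n_perm, seed=seed, test=test)
    return float(res["test statistic"]), float(res["p-value"])


def alpha_group_effect(values, groups) -> dict:
    """Kruskal-Wallis H across groups with both common effect sizes.

    Returns H, p, epsilon-squared ``H (n+1) / (n^2 - 1)`` and eta-squared
    ``(H - k + 1) / (n - k)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(g) for g in groups])
    uniq = np.unique(labels)
    samples = [values[labels == g] for g in uniq]
    h, p = scipy.stats.kruskal(*samples)
    n, k = len(values), len(uniq)
    return {
        "H": float(h),
        "p": float(p),
        "epsilon_squared": float(h * (n + 1) / (n ** 2 - 1)),
        "eta_squared": float((h - k + 1) / (n - k)),
    }
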