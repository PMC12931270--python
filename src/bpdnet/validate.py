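"""Calibration and recovery experiments on synthetic ground truth.

These are the package's own checks that the statistical machinery behaves as
advertised where the answer is known: SparCC recovers planted basis
correlations and stays quiet on independent data; permutation p-values are
calibrated at their nominal level; the proportional-odds fitter covers its
true coefficient.  Each experiment returns plain numbers so callers (tests,
reports) can assert or record them.
"""

from __future__ import annotations

import numpy as np
import scipy.special

from .io import CountTable
from .netcompare import PipelineParams, permute_compare
from .outcome import fit_proportional_odds
from .sparcc import edge_significance, sparcc_correlation, spearman_correlation
from .synth import generate_null_cohort


def planted_pair_table(rho: float, n_taxa: int, n_samples: int, seed: int,
                       depth: int = 30_000) -> CountTable:
    """Counts whose log-normal basis has one correlated pair (taxa 0, 1)."""
    rng = np.random.default_rng(seed)
    corr = np.eye(n_taxa)
    corr[0, 1] = corr[1, 0] = rho
    chol = np.linalg.cholesky(corr)
    x = (chol @ rng.standard_normal((n_taxa, n_samples))).T
    basis = np.exp(x)
    fractions = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, f) for f in fractions])
    return CountTable([f"s{i}" for i in range(n_samples)],
                      [f"t{j}" for j in range(n_taxa)], counts)


def sparcc_recovery(rho: float = 0.8, n_taxa: int = 30, n_samples: int = 200,
                    n_seeds: int = 20, n_outer: int = 5, seed: int = 0) -> float:
    """Median recovered correlation of a planted basis pair across seeds."""
    estimates = []
    for k in range(n_seeds):
        table = planted_pair_table(rho, n_taxa, n_samples, seed + k)
        r = sparcc_correlation(table, n_outer=n_outer, seed=seed + k)
        estimates.append(r[0, 1])
    return float(np.median(estimates))


def null_max_correlation(n_taxa: int = 50, n_samples: int = 200,
                         n_seeds: int = 3, n_outer: int = 5,
                         seed: int = 0) -> float:
    """Largest off-diagonal |r| SparCC reports on independent-basis data."""
    worst = 0.0
    for k in range(n_seeds):
        table = generate_null_cohort(n_samples, n_taxa, 30_000, seed + k)
        r = sparcc_correlation(table, n_outer=n_outer, seed=seed + k)
        off = np.abs(r - np.diag(np.diag(r)))
        worst = max(worst, float(off.max()))
    return worst


def spurious_suppression(n_taxa: int = 25, n_samples: int = 100,
                         n_seeds: int = 10, seed: int = 0) -> dict:
    """Median |r| of SparCC vs Spearman-on-fractions on dominant-taxon nulls.

    Returns per-seed medians and the number of seeds where SparCC is strictly
    smaller (the compositional spurious-correlation suppression property).
    """
    iu = np.triu_indices(n_taxa, 1)
    sparcc_meds, spearman_meds, wins = [], [], 0
    for k in range(n_seeds):
        table = generate_null_cohort(n_samples, n_taxa, 20_000, seed + k,
                                     dominant_frac=0.8)
        r_sp = sparcc_correlation(table, n_outer=5, seed=seed + k)
        r_sr = spearman_correlation(table, significance=False).r
        a, b = np.median(np.abs(r_sp[iu])), np.median(np.abs(r_sr[iu]))
        sparcc_meds.append(a)
        spearman_meds.append(b)
        wins += a < b
    return {"sparcc_median": float(np.median(sparcc_meds)),
            "spearman_median": float(np.median(spearman_meds)),
            "wins": int(wins), "n_seeds": n_seeds}


def edge_significance_type1(n_replicates: int = 100, n_perm: int = 200,
                            n_taxa: int = 10, n_samples: int = 30,
                            alpha: float = 0.05, seed: int = 0) -> dict:
    """Empirical type-I error of the permutation edge test on null cohorts.

    One fixed taxon pair is tested per replicate so the rejection count is
    binomial under the null.
    """
    rejections = 0
    for k in range(n_replicates):
        table = generate_null_cohort(n_samples, n_taxa, 5_000, seed + k)
        r = sparcc_correlation(table, n_outer=3, seed=seed + k)
        p = edge_significance(table, r, n_resamples=n_perm,
                              seed=seed + 10_000 + k, n_outer=1)
        rejections += p[0, 1] < alpha
    return {"rate": rejections / n_replicates, "rejections": int(rejections),
            "n_replicates": n_replicates}


def permute_compare_type1(n_replicates: int = 100, n_perm: int = 200,
                          n_taxa: int = 10, group_n: int = 16,
                          alpha: float = 0.05, seed: int = 0,
                          metric: str = "density") -> dict:
    """Empirical type-I error of the between-group topology permutation test
    on random halves of one null cohort."""
    params = PipelineParams(n_outer=1, n_resamples=0, significance=False)
    rejections = 0
    for k in range(n_replicates):
        table = generate_null_cohort(2 * group_n, n_taxa, 5_000, seed + k)
        half_a = table.select_samples(table.sample_ids[:group_n])
        half_b = table.select_samples(table.sample_ids[group_n:])
        res = permute_compare(half_a, half_b, params=params, metrics=(metric,),
                              n_perm=n_perm, seed=seed + 20_000 + k,
                              null_params=params)
        rejections += res.p_values[metric] < alpha
    return {"rate": rejections / n_replicates, "rejections": int(rejections),
            "n_replicates": n_replicates}


def proportional_odds_coverage(beta: float = 1.0, n: int = 500,
                               n_seeds: int = 100, seed: int = 0) -> dict:
    """95% Wald CI coverage for a single-predictor proportional-odds model."""
    theta = np.array([-1.0, 0.3, 1.4])
    covered = converged = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        x = rng.standard_normal((n, 1))
        cum = scipy.special.expit(theta[None, :] - x[:, 0][:, None] * beta)
        cum = np.hstack([cum, np.ones((n, 1))])
        y = (rng.random(n)[:, None] > cum).sum(axis=1)
        fit = fit_proportional_odds(y, x)
        if fit.converged:
            converged += 1
            lo, hi = fit.conf_int()[0]
            covered += lo <= beta <= hi
    return {"coverage": covered / max(converged, 1), "converged": converged,
            "n_seeds": n_seeds}


def planted_density_effect(beta: float = -2.0, n: int = 200,
                           n_seeds: int = 10, seed: int = 0) -> dict:
    """Directional recovery of a protective (negative) density effect:
    fraction of seeds with OR < 1 and p < 0.05, and the median OR."""
    theta = np.array([-2.0, -0.5, 1.0])
    hits, ors = 0, []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        x = rng.standard_normal((n, 1))
        cum = scipy.special.expit(theta[None, :] - x[:, 0][:, None] * beta)
        cum = np.hstack([cum, np.ones((n, 1))])
        y = (rng.random(n)[:, None] > cum).sum(axis=1)
        fit = fit_proportional_odds(y, x, predictor_names=["density"])
        s = fit.summary().loc["density"]
        ors.append(s["OR"])
        hits += (s["OR"] < 1) and (s["p"] < 0.05)
    return {"median_or": float(np.median(ors)), "hits": int(hits),
            "n_seeds": n_seeds}
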