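"""Proportional-odds ordinal regression for disease grade ~ predictors.

Parameterization: ``logit P(Y <= k) = theta_k - x beta`` with strictly
increasing cutpoints, so a positive beta (OR = exp(beta) > 1) means higher
odds of a *more severe* grade per standardized predictor unit.  The model is
fitted by damped Newton iterations on the exact log-likelihood, with Wald
standard errors from the observed information.  A reciprocal-condition-number
guard on the information matrix flags the Hessian singularities that the
forward-stepwise covariate procedure must exclude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

#: reciprocal condition number below which the information matrix is singular
RCOND_SINGULAR = 1e-10


class FitError(ValueError):
    """A model could not be fitted under its preconditions."""


def standardize(x, log_transform: bool = False) -> np.ndarray:
    """Z-score a numeric vector to mean 0, sd 1 (sample sd, n-1).

    With ``log_transform`` zeros are lifted by a pseudocount of half the
    smallest positive value before taking logs (the usual convention for
    relative-abundance predictors).  Constant vectors are an error.
    """
    x = np.asarray(x, dtype=float)
    if log_transform:
        positive = x[x > 0]
        if positive.size == 0:
            raise FitError("cannot log-transform an all-zero vector")
        x = np.log(x + 0.5 * positive.min() * (x == 0))
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise FitError("constant vector cannot be standardized (sd = 0)")
    return (x - x.mean()) / sd


@dataclass
class OrdinalFit:
    predictors: list
    beta: np.ndarray
    se: np.ndarray
    cutpoints: np.ndarray
    log_likelihood: float
    converged: bool
    singular: bool
    n_iter: int
    n_obs: int
    dropped: list = field(default_factory=list)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def wald_p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.beta / self.se
        return 2.0 * scipy.stats.norm.sf(np.abs(z))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        zcrit = scipy.stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.beta - zcrit * self.se,
                                self.beta + zcrit * self.se])

    def summary(self) -> pd.DataFrame:
        ci = np.clip(self.conf_int(), -700, 700)  # avoid exp overflow on degenerate fits
        return pd.DataFrame({
            "beta": self.beta, "se": self.se, "OR": self.odds_ratios,
            "ci_low": np.exp(ci[:, 0]), "ci_high": np.exp(ci[:, 1]),
            "p": self.wald_p(),
        }, index=self.predictors)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-observation probabilities over the outcome levels."""
        eta = np.asarray(x, dtype=float) @ self.beta
        cum = _sigmoid(self.cutpoints[None, :] - eta[:, None])
        cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
        return np.diff(cum, axis=1)


def _sigmoid(z):
    return scipy.special.expit(z)


def _prepare(y, x, names):
    y = np.asarray(pd.Categorical(y).codes if not np.issubdtype(
        np.asarray(y).dtype, np.integer) else y, dtype=int)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    levels = np.unique(y)
    if len(levels) < 2:
        raise FitError("need >= 2 observed outcome levels")
    # re-code to consecutive 0..K-1
    remap = {lv: i for i, lv in enumerate(sorted(levels))}
    y = np.array([remap[v] for v in y])
    p = x.shape[1]
    if len(y) <= p + 3:
        raise FitError(f"n={len(y)} too small for {p} predictors")
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    return y, x, list(names)


def _loglik_parts(theta, beta, y, x, k_levels):
    eta = x @ beta
    a = np.where(y < k_levels - 1, theta[np.minimum(y, k_levels - 2)] - eta, np.inf)
    b = np.where(y > 0, theta[np.maximum(y - 1, 0)] - eta, -np.inf)
    fa_cdf = _sigmoid(a)
    fb_cdf = _sigmoid(b)
    prob = np.clip(fa_cdf - fb_cdf, 1e-300, None)
    return a, b, fa_cdf, fb_cdf, prob


def _loglik(theta, beta, y, x, k_levels) -> float:
    *_, prob = _loglik_parts(theta, beta, y, x, k_levels)
    return float(np.sum(np.log(prob)))


def _grad_hess(theta, beta, y, x, k_levels):
    n, p = x.shape
    m = k_levels - 1
    a, b, fa_cdf, fb_cdf, prob = _loglik_parts(theta, beta, y, x, k_levels)
    fa = fa_cdf * (1 - fa_cdf)        # logistic density at a (0 at +/-inf)
    fb = fb_cdf * (1 - fb_cdf)
    fpa = fa * (1 - 2 * fa_cdf)       # density derivative
    fpb = fb * (1 - 2 * fb_cdf)

    ga, gb = fa / prob, -fb / prob
    h_aa = fpa / prob - (fa / prob) ** 2
    h_bb = -fpb / prob - (fb / prob) ** 2
    h_ab = fa * fb / prob ** 2

    grad = np.zeros(m + p)
    upper = y          # index of theta in 'a' (valid where y < K-1)
    lower = y - 1      # index of theta in 'b' (valid where y > 0)
    has_a = y < k_levels - 1
    has_b = y > 0
    np.add.at(grad, upper[has_a], ga[has_a])
    np.add.at(grad, lower[has_b], gb[has_b])
    grad[m:] = -x.T @ (ga + gb)

    hess = np.zeros((m + p, m + p))
    np.add.at(hess, (upper[has_a], upper[has_a]), h_aa[has_a])
    np.add.at(hess, (lower[has_b], lower[has_b]), h_bb[has_b])
    both = has_a & has_b
    np.add.at(hess, (upper[both], lower[both]), h_ab[both])
    np.add.at(hess, (lower[both], upper[both]), h_ab[both])
    # theta x beta
    coef_a = np.where(has_a, h_aa + np.where(has_b, h_ab, 0.0), 0.0)
    coef_b = np.where(has_b, h_bb + np.where(has_a, h_ab, 0.0), 0.0)
    for t_idx, coef, mask in ((upper, coef_a, has_a), (lower, coef_b, has_b)):
        contrib = -(x * coef[:, None])
        np.add.at(hess, (t_idx[mask], slice(m, m + p)), contrib[mask])
    hess[m:, :m] = hess[:m, m:].T
    # beta x beta
    wbb = h_aa + h_bb + 2 * np.where(both, h_ab, 0.0)
    hess[m:, m:] = x.T @ (x * wbb[:, None])
    return grad, hess


def fit_proportional_odds(y, x, predictor_names=None, max_iter: int = 100,
                          tol: float = 1e-8) -> OrdinalFit:
    """Fit the proportional-odds model by damped Newton iterations.

    Convergence: gradient max-norm below ``tol`` (default 1e-8) or
    ``max_iter`` iterations.  Never raises on numerical pathology: separation
    or singular information is reported through the ``converged`` /
    ``singular`` flags.
    """
    y, x, names = _prepare(y, x, predictor_names)
    k_levels = int(y.max()) + 1
    m, p = k_levels - 1, x.shape[1]

    # initial cutpoints from the empirical cumulative logits; beta = 0
    cum = np.array([(y <= k).mean() for k in range(m)])
    cum = np.clip(cum, 1e-3, 1 - 1e-3)
    theta = np.log(cum / (1 - cum))
    beta = np.zeros(p)

    ll = _loglik(theta, beta, y, x, k_levels)
    converged = singular = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, hess = _grad_hess(theta, beta, y, x, k_levels)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            singular = True
            break
        if not np.all(np.isfinite(step)):
            singular = True
            break
        # damping: halve until the likelihood does not decrease and the
        # cutpoints stay strictly increasing
        t = 1.0
        accepted = False
        for _ in range(40):
            new_theta = theta + t * step[:m]
            new_beta = beta + t * step[m:]
            if np.all(np.diff(new_theta) > 0) or m == 1:
                new_ll = _loglik(new_theta, new_beta, y, x, k_levels)
                if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                    theta, beta, ll = new_theta, new_beta, new_ll
                    accepted = True
                    break
            t /= 2.0
        if not accepted:
            break

    grad, hess = _grad_hess(theta, beta, y, x, k_levels)
    if np.max(np.abs(grad)) < tol and not singular:
        converged = True
    info = -hess
    se = np.full(p, np.nan)
    try:
        rcond = 1.0 / np.linalg.cond(info)
        if not np.isfinite(rcond) or rcond < RCOND_SINGULAR:
            singular = True
        else:
            cov = np.linalg.inv(info)
            diag = np.diag(cov)[m:]
            if np.any(diag <= 0):
                singular = True
            else:
                se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        singular = True
    if singular:
        converged = False
    # separation guard: the likelihood flattens as |beta| diverges, so a tiny
    # gradient alone is not evidence of a proper maximum
    if np.any(np.abs(beta) > 50) or np.any(se > 1e3):
        converged = False
    return OrdinalFit(names, beta, se, theta, ll, converged, singular, it, len(y))


def forward_stepwise(y, data: pd.DataFrame, base_predictors: list,
                     candidate_covariates: list,
                     significance_gate: float | None = None) -> OrdinalFit:
    """Forward stepwise covariate addition with the stability guard.

    Starts from ``base_predictors`` (columns of ``data``), then adds each
    candidate in the given order.  A candidate that makes the fit
    non-convergent or the observed information singular is recorded in
    ``dropped`` (with the reason) and skipped; otherwise it is kept.  With
    ``significance_gate`` set, a candidate must additionally reach that Wald
    p-value to be kept (off by default: the gate is stability, not
    significance).
    """
    base_fit = fit_proportional_odds(
        y, data[base_predictors].to_numpy(), predictor_names=base_predictors)
    if not base_fit.converged:
        raise FitError("base model is non-convergent")
    kept = list(base_predictors)
    dropped: list = []
    current = base_fit
    for cov in candidate_covariates:
        trial = kept + [cov]
        try:
            fit = fit_proportional_odds(y, data[trial].to_numpy(),
                                        predictor_names=trial)
        except FitError as exc:
            dropped.append((cov, str(exc)))
            continue
        if fit.singular:
            dropped.append((cov, "singular observed information"))
            continue
        if not fit.converged:
            dropped.append((cov, "non-convergence"))
            continue
        if significance_gate is not None:
            p_cov = fit.summary().loc[cov, "p"]
            if not p_cov < significance_gate:
                dropped.append((cov, f"p={p_cov:.3g} above gate"))
                continue
        kept, current = trial, fit
    current.dropped = dropped
    return current


def design_matrix(metadata: pd.DataFrame, columns: list,
                  standardize_numeric: bool = True) -> pd.DataFrame:
    """Encode covariates for the ordinal model: dummy-code categoricals
    (drop-first) and optionally z-score numeric columns."""
    parts = []
    for col in columns:
        s = metadata[col]
        if pd.api.types.is_numeric_dtype(s):
            vals = standardize(s.to_numpy()) if standardize_numeric else s.to_numpy()
            parts.append(pd.Series(vals, index=metadata.index, name=col))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True).astype(float)
            for c in dummies.columns:
                parts.append(dummies[c])
    return pd.concat(parts, axis=1)
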