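"""Binomial random-intercept model for cluster-vs-singlet abundance tests.

Implements maximum-likelihood estimation of a logistic regression with one
binary fixed effect (interaction status) and a Gaussian random intercept per
patient.  The per-patient integral over the random effect is evaluated by
Gauss-Hermite quadrature (a refinement of the Laplace approximation that is
exact in the limit of many nodes); a stratified permutation test shuffling
interaction status within patient is provided as a model-free oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = ["GLMMResult", "fit_binomial_glmm", "stratified_permutation_test"]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(25)
_GH_LOGW = np.log(_GH_WEIGHTS) - 0.5 * np.log(2 * np.pi)


@dataclass
class GLMMResult:
    """ML fit of the random-intercept logistic model."""

    beta0: float
    beta1: float  # fixed-effect log-odds of interaction status
    sigma: float  # random-intercept SD
    se_beta1: float
    z: float
    p: float
    converged: bool
    n_groups: int
    separation: bool = False  # a contrast level had 0 or all successes overall


def _aggregate(y: np.ndarray, x: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame({"y": y.astype(int), "x": x.astype(int), "g": groups})
    agg = df.groupby(["g", "x"], sort=True)["y"].agg(["sum", "count"]).reset_index()
    return agg.rename(columns={"sum": "successes", "count": "trials"})


def _negloglik(params: np.ndarray, agg: pd.DataFrame) -> float:
    b0, b1, log_sigma = params
    sigma = np.exp(log_sigma)
    total = 0.0
    for _, grp in agg.groupby("g"):
        eta = b0 + b1 * grp["x"].to_numpy()  # (J,)
        k = grp["successes"].to_numpy()
        n = grp["trials"].to_numpy()
        # log-likelihood on the quadrature grid u = sigma * t
        lin = eta[None, :] + sigma * _GH_NODES[:, None]  # (Q, J)
        ll = k[None, :] * lin - n[None, :] * np.logaddexp(0.0, lin)
        total += special.logsumexp(ll.sum(axis=1) + _GH_LOGW)
    return -total


def fit_binomial_glmm(
    y: np.ndarray, x: np.ndarray, groups: np.ndarray
) -> GLMMResult:
    """Fit P(y=1) = logit^-1(b0 + b1*x + u_g), u_g ~ N(0, sigma^2), by ML.

    ``y`` is a per-observation binary outcome (e.g. membership in a cell
    state), ``x`` the binary interaction status, ``groups`` the patient of
    origin.  Returns the fixed-effect estimate with a Wald test on b1.
    """
    y = np.asarray(y).astype(int)
    x = np.asarray(x).astype(int)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups (patients)")
    if set(np.unique(x)) - {0, 1}:
        raise ValueError("x must be binary 0/1")
    agg = _aggregate(y, x, groups)
    separation = bool(
        (agg.groupby("x")["successes"].sum() == 0).any()
        or (agg.groupby("x").apply(lambda d: (d["successes"] == d["trials"]).all(), include_groups=False)).any()
    )

    p_bar = max(min(y.mean(), 1 - 1e-6), 1e-6)
    x0 = np.array([np.log(p_bar / (1 - p_bar)), 0.0, np.log(0.3)])
    res = optimize.minimize(
        _negloglik, x0, args=(agg,), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    b0, b1, log_sigma = res.x

    # observed-information SE for beta1 via central differences on (b0,b1,ls)
    h = 1e-4
    hess = np.zeros((3, 3))
    f0 = _negloglik(res.x, agg)
    for i in range(3):
        for j in range(i, 3):
            ei = np.eye(3)[i] * h
            ej = np.eye(3)[j] * h
            fpp = _negloglik(res.x + ei + ej, agg)
            fpm = _negloglik(res.x + ei - ej, agg)
            fmp = _negloglik(res.x - ei + ej, agg)
            fmm = _negloglik(res.x - ei - ej, agg)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    try:
        cov = np.linalg.inv(hess)
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se = float("nan")
    if not np.isfinite(se) or se == 0:
        z = float("nan")
        p = float("nan")
    else:
        z = b1 / se
        p = float(2 * stats.norm.sf(abs(z)))
    return GLMMResult(
        beta0=float(b0),
        beta1=float(b1),
        sigma=float(np.exp(log_sigma)),
        se_beta1=se,
        z=float(z),
        p=p,
        converged=bool(res.success),
        n_groups=int(len(np.unique(groups))),
        separation=separation,
    )


def _mh_log_odds_ratio(y: np.ndarray, x: np.ndarray, groups: np.ndarray) -> float:
    """Mantel-Haenszel common odds ratio (log), stratified by group."""
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        m = groups == g
        a = float(((y == 1) & (x == 1) & m).sum()) + 0.5
        b = float(((y == 0) & (x == 1) & m).sum()) + 0.5
        c = float(((y == 1) & (x == 0) & m).sum()) + 0.5
        d = float(((y == 0) & (x == 0) & m).sum()) + 0.5
        n = float(m.sum())
        num += a * d / n
        den += b * c / n
    return float(np.log(num / den))


def stratified_permutation_test(
    y: np.ndarray,
    x: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation p-value for association of y with x, shuffling x within group.

    The test statistic is the Mantel-Haenszel log odds ratio; the two-sided p
    is the fraction of within-patient label permutations with |statistic| at
    least as extreme as observed (+1 correction).
    """
    y = np.asarray(y).astype(int)
    x = np.asarray(x).astype(int)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    obs = _mh_log_odds_ratio(y, x, groups)

    # Under within-group permutation of x, the 2x2 table count
    # a_g = #(y=1 & x=1) is hypergeometric with the group's margins fixed;
    # the MH statistic depends on the data only through these counts, so the
    # permutation distribution can be sampled directly from the margins.
    num = np.zeros(n_perm)
    den = np.zeros(n_perm)
    for g in np.unique(groups):
        m = groups == g
        n = int(m.sum())
        k_pos = int(y[m].sum())
        n1 = int(x[m].sum())
        a = rng.hypergeometric(k_pos, n - k_pos, n1, size=n_perm).astype(float)
        b = n1 - a
        c = k_pos - a
        d = n - k_pos - n1 + a
        num += (a + 0.5) * (d + 0.5) / n
        den += (b + 0.5) * (c + 0.5) / n
    perm_stats = np.log(num / den)
    count = int((np.abs(perm_stats) >= abs(obs)).sum())
    return {
        "statistic": obs,
        "p": (count + 1) / (n_perm + 1),
        "n_perm": n_perm,
    }
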