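"""Negative-binomial differential expression for panel counts.

Per endogenous gene g and lane j the raw count is modeled as

    Y_gj ~ NB(mean = d_j * exp(b0_g + b1_g * x_j) + lambda_j,
              var  = m + phi_g * m^2)

where d_j is the lane size derived from the control-based normalization
factors (d_j = 1 / (pos_factor_j * hk_factor_j)), lambda_j is the lane's
negative-control background mean, and x_j is the 0/1 group indicator of the
contrast. The per-gene dispersion phi_g (bounded in [1e-8, 10]) is
estimated by Cox-Reid adjusted profile likelihood — plain ML dispersion is
biased low at panel-scale lane counts and makes the test anti-conservative —
and the p-value is a likelihood-ratio test of b1 = 0 at fixed phi_g,
referred to an F(1, N - 2) distribution (N = lanes in the contrast) in the
quasi-likelihood style, which accounts for the estimated dispersion where
the chi-square(1) reference does not. log2 fold change is b1 / ln 2.

Genes whose counts never rise above the lane background in either group are
flagged ``below_background`` and assigned p = 1; non-convergent fits (after
a restart) are flagged and also assigned p = 1, never a silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln
from scipy.stats import f as f_dist

from .panel_core import CountsExperiment
from .normalization import NormalizationFactors

__all__ = ["DEResult", "fit_nb_de", "bh_adjust", "one_vs_rest"]

PHI_BOUNDS = (1e-8, 10.0)
LN2 = float(np.log(2.0))


@dataclass
class DEResult:
    """Per-gene DE table for one two-group contrast."""

    table: pd.DataFrame  # index gene; columns log2fc, p, q, dispersion, flag
    contrast: tuple[str, str]
    m: int  # total tests used for BH

    def significant(self, q_cutoff: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["q"] < q_cutoff])


def _nb_negloglik(theta: np.ndarray, y: np.ndarray, x: np.ndarray,
                  d: np.ndarray, lam: np.ndarray,
                  with_grad: bool = True):
    """Negative log likelihood (and gradient) in (b0, b1, u = log phi)."""
    b0, b1, u = theta
    phi = np.exp(u)
    r = 1.0 / phi
    eta = np.exp(b0 + b1 * x)
    mu = d * eta + lam
    # ll_j = lgam(y+r) - lgam(r) - lgam(y+1) + r ln r - (y+r) ln(r+mu) + y ln mu
    ll = (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
          + r * np.log(r) - (y + r) * np.log(r + mu)
          + np.where(y > 0, y * np.log(mu), 0.0))
    nll = -float(ll.sum())
    if not with_grad:
        return nll
    dll_dmu = np.where(y > 0, y / mu, 0.0) - (y + r) / (r + mu)
    dmu_db0 = d * eta
    g0 = float((dll_dmu * dmu_db0).sum())
    g1 = float((dll_dmu * dmu_db0 * x).sum())
    dll_dr = (digamma(y + r) - digamma(r) + np.log(r) + 1.0
              - np.log(r + mu) - (y + r) / (r + mu))
    gu = float((dll_dr * (-r)).sum())  # dr/du = -r since r = exp(-u)
    return nll, -np.array([g0, g1, gu])


def _start_values(y: np.ndarray, x: np.ndarray, d: np.ndarray,
                  lam: np.ndarray, null: bool) -> tuple[float, float, float]:
    eps = 1e-8
    adj = np.maximum((y - lam) / d, eps)
    if null:
        b0_start, b1_start = float(np.log(np.mean(adj))), 0.0
    else:
        m0 = max(np.mean(adj[x == 0]), eps)
        m1 = max(np.mean(adj[x == 1]), eps)
        b0_start, b1_start = float(np.log(m0)), float(np.log(m1 / m0))
    mu_hat = d * np.exp(b0_start + b1_start * x) + lam
    resid = (y - mu_hat) ** 2 - mu_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_mom = np.nansum(resid) / np.nansum(mu_hat**2)
    phi_start = float(np.clip(phi_mom if np.isfinite(phi_mom) else 0.1,
                              PHI_BOUNDS[0] * 10, PHI_BOUNDS[1] / 10))
    return b0_start, b1_start, phi_start


def _polish(f, res):
    """Resolve L-BFGS "ABNORMAL" line-search aborts near the optimum.

    A short derivative-free polish from the returned point decides whether
    the abort happened at (numerical) convergence: if it cannot improve the
    objective beyond rounding, the fit is accepted.
    """
    if res.success:
        return res.x, -float(res.fun), True
    nm = minimize(lambda t: f(t)[0], res.x, method="Nelder-Mead",
                  options={"fatol": 1e-9, "xatol": 1e-9, "maxiter": 400})
    if not np.isfinite(nm.fun):
        return res.x, -float(res.fun), False
    improved = res.fun - nm.fun
    best_x, best_fun = (nm.x, nm.fun) if nm.fun <= res.fun \
        else (res.x, res.fun)
    return best_x, -float(best_fun), bool(improved < 1e-4 * max(1.0, abs(nm.fun)))


def _fit_beta(y: np.ndarray, x: np.ndarray, d: np.ndarray, lam: np.ndarray,
              phi: float, b0_start: float, b1_start: float,
              null: bool) -> tuple[float, np.ndarray, bool]:
    """Maximize the NB likelihood over beta at fixed dispersion."""
    u = float(np.log(phi))
    if null:
        def f(t):
            nll, g = _nb_negloglik(np.array([t[0], 0.0, u]), y, x, d, lam)
            return nll, g[[0]]
        res = minimize(f, np.array([b0_start]), jac=True, method="L-BFGS-B")
        xx, ll, ok = _polish(f, res)
        theta = np.array([xx[0], 0.0, u])
    else:
        def f(t):
            nll, g = _nb_negloglik(np.array([t[0], t[1], u]), y, x, d, lam)
            return nll, g[[0, 1]]
        res = minimize(f, np.array([b0_start, b1_start]), jac=True,
                       method="L-BFGS-B")
        xx, ll, ok = _polish(f, res)
        theta = np.array([xx[0], xx[1], u])
    return ll, theta, ok


def _cox_reid_adjustment(theta: np.ndarray, y: np.ndarray, x: np.ndarray,
                         d: np.ndarray, lam: np.ndarray) -> float:
    """0.5 * log det(X' W X) with GLM working weights for the mean model."""
    b0, b1, u = theta
    phi = np.exp(u)
    eta = np.exp(b0 + b1 * x)
    mu = d * eta + lam
    var = mu + phi * mu * mu
    w = (d * eta) ** 2 / var
    s00, s01, s11 = float(w.sum()), float((w * x).sum()), \
        float((w * x * x).sum())
    det = max(s00 * s11 - s01 * s01, 1e-300)
    return 0.5 * float(np.log(det))


def _estimate_dispersion(y: np.ndarray, x: np.ndarray, d: np.ndarray,
                         lam: np.ndarray,
                         beta_hat: np.ndarray) -> tuple[float, bool]:
    """Cox-Reid adjusted profile-likelihood dispersion for one gene.

    One-step approximation: the adjusted profile is evaluated at the
    full-model ML coefficients ``beta_hat`` rather than refitting beta for
    every candidate dispersion (the coefficient profile is nearly flat in
    phi for this mean model).
    """
    b0, b1 = float(beta_hat[0]), float(beta_hat[1])

    def neg_apl(u: float) -> float:
        theta = np.array([b0, b1, u])
        nll = _nb_negloglik(theta, y, x, d, lam, with_grad=False)
        return nll + _cox_reid_adjustment(theta, y, x, d, lam)

    lo, hi = np.log(PHI_BOUNDS[0]), np.log(PHI_BOUNDS[1])
    grid = np.linspace(lo, hi, 13)
    vals = [neg_apl(u) for u in grid]
    i = int(np.argmin(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    inv = (np.sqrt(5.0) - 1.0) / 2.0
    c, dd = b - inv * (b - a), a + inv * (b - a)
    fc, fd = neg_apl(c), neg_apl(dd)
    for _ in range(30):
        if fc < fd:
            b, dd, fd = dd, c, fc
            c = b - inv * (b - a)
            fc = neg_apl(c)
        else:
            a, c, fc = c, dd, fd
            dd = a + inv * (b - a)
            fd = neg_apl(dd)
    u_hat = 0.5 * (a + b)
    return float(np.exp(u_hat)), bool(np.isfinite(neg_apl(u_hat)))


def _fit_gene(y: np.ndarray, x: np.ndarray, d: np.ndarray, lam: np.ndarray,
              null: bool, phi: float | None = None
              ) -> tuple[float, np.ndarray, bool]:
    """Maximize the NB likelihood; returns (loglik, theta, converged).

    With ``phi`` given, only the mean parameters are fitted (the mode used
    by the LRT); otherwise the dispersion is profiled out by plain ML.
    """
    b0_start, b1_start, phi_start = _start_values(y, x, d, lam, null)
    if phi is not None:
        return _fit_beta(y, x, d, lam, phi, b0_start, b1_start, null)

    u_bounds = (np.log(PHI_BOUNDS[0]), np.log(PHI_BOUNDS[1]))

    def solve(theta0):
        if null:
            def f(t2):
                nll, g = _nb_negloglik(
                    np.array([t2[0], 0.0, t2[1]]), y, x, d, lam)
                return nll, g[[0, 2]]
            res = minimize(f, np.array([theta0[0], theta0[2]]), jac=True,
                           method="L-BFGS-B",
                           bounds=[(None, None), u_bounds])
            xx, ll, ok = _polish(f, res)
            theta = np.array([xx[0], 0.0, np.clip(xx[1], *u_bounds)])
        else:
            def f(t):
                return _nb_negloglik(t, y, x, d, lam)
            res = minimize(f, theta0, jac=True, method="L-BFGS-B",
                           bounds=[(None, None), (None, None), u_bounds])
            xx, ll, ok = _polish(f, res)
            theta = np.array([xx[0], xx[1], np.clip(xx[2], *u_bounds)])
        return ll, theta, ok

    start = np.array([b0_start, b1_start, np.log(phi_start)])
    ll, theta, ok = solve(start)
    if not ok or not np.isfinite(ll):
        # restart from a Poisson-like dispersion
        ll2, theta2, ok2 = solve(
            np.array([b0_start, b1_start, np.log(1e-4)]))
        if np.isfinite(ll2) and (not np.isfinite(ll) or ll2 > ll):
            ll, theta, ok = ll2, theta2, ok2
    return ll, theta, ok or np.isfinite(ll)


def fit_nb_de(experiment: CountsExperiment, factors: NormalizationFactors,
              contrast: tuple[str, str]) -> DEResult:
    """Per-gene NB likelihood-ratio DE for ``contrast = (A, B)``.

    x = 1 for group A lanes, 0 for group B, so positive log2FC means higher
    expression in A. BH adjustment uses m = number of endogenous genes.
    """
    group_a, group_b = contrast
    groups = experiment.groups
    ids_a = [s for s in experiment.sample_ids if groups[s] == group_a]
    ids_b = [s for s in experiment.sample_ids if groups[s] == group_b]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("both contrast groups need >=2 lanes")
    ids = ids_b + ids_a
    x = np.array([0] * len(ids_b) + [1] * len(ids_a), dtype=float)
    d = (1.0 / (factors.pos_factor.loc[ids]
                * factors.hk_factor.loc[ids])).to_numpy()
    lam = factors.background_lambda.loc[ids].to_numpy()

    endo = experiment.panel.endogenous
    counts = experiment.counts.loc[ids, endo].to_numpy(dtype=float)

    rows = []
    for j, gene in enumerate(endo):
        y = counts[:, j]
        if np.all(y <= lam):
            rows.append((gene, 0.0, 1.0, np.nan, "below_background"))
            continue
        _, theta_ml, ml_ok = _fit_gene(y, x, d, lam, null=False)
        phi, phi_ok = _estimate_dispersion(y, x, d, lam, theta_ml[:2])
        phi_ok = phi_ok and ml_ok
        ll1, theta1, ok1 = _fit_gene(y, x, d, lam, null=False, phi=phi)
        ll0, _, ok0 = _fit_gene(y, x, d, lam, null=True, phi=phi)
        if not (phi_ok and ok1 and ok0
                and np.isfinite(ll1) and np.isfinite(ll0)):
            rows.append((gene, 0.0, 1.0, np.nan, "non_convergent"))
            continue
        stat = max(2.0 * (ll1 - ll0), 0.0)
        p = float(f_dist.sf(stat, 1, max(len(x) - 2, 1)))
        rows.append((gene, float(theta1[1] / LN2), p, phi, ""))

    table = pd.DataFrame(
        rows, columns=["gene", "log2fc", "p", "dispersion", "flag"],
    ).set_index("gene")
    m = len(endo)
    table["q"] = bh_adjust(table["p"].to_numpy(), m=m)
    table = table[["log2fc", "p", "q", "dispersion", "flag"]]
    return DEResult(table=table, contrast=contrast, m=m)


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``m`` is the total number of tests (defaults to ``len(pvalues)``); it may
    exceed the list length when only a subset of tested genes is supplied.
    q_(i) = min_{j >= i} min(1, m * p_(j) / j) over the ascending-sorted list.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"m = {m} smaller than number of p-values {n}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def one_vs_rest(experiment: CountsExperiment, factors: NormalizationFactors,
                group: str, rest_label: str = "rest") -> DEResult:
    """Convenience wrapper: contrast one group against all other lanes."""
    lanes = experiment.lanes.copy()
    lanes["group"] = np.where(lanes["group"] == group, group, rest_label)
    relabeled = CountsExperiment(panel=experiment.panel, lanes=lanes,
                                 counts=experiment.counts)
    return fit_nb_de(relabeled, factors, (group, rest_label))
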