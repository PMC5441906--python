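"""Restricted maximum likelihood for linear mixed models.

Fits y = X b + sum_i Z_i u_i + e with u_i ~ N(0, sigma2_i I) and
e ~ N(0, sigma2_e I) by profiling the residual variance and maximizing
the restricted likelihood over the log variance ratios
gamma_i = sigma2_i / sigma2_e with a derivative-free simplex search.

The restricted likelihood is evaluated through the mixed-model
equations: with W = [X, Z] and C = W'W + diag(0, G^-1),

    -2 l_R = (n - p) (log 2*pi*sigma2 + 1) + log|C| + sum_i q_i log gamma_i,

where sigma2 = y'P y / (n - p) and y'P y = y'y - theta_hat' W'y.  This
is exact for independent random-effect blocks; correlated effects
(e.g. a polygene with a kinship covariance K) are accommodated by the
caller passing Z L with K = L L'.

Variance components are constrained non-negative by bounding log gamma;
a ratio pinned at the lower bound is reported as a zero component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

__all__ = ["RemlResult", "reml_fit", "lrt_variance", "drop_collinear"]

_LOG_GAMMA_LO = -25.0
_LOG_GAMMA_HI = 25.0


@dataclass
class RemlResult:
    sigma2: dict[str, float]  # per-component variances, key "resid" always present
    gamma: np.ndarray
    loglik: float  # restricted log-likelihood (with constants)
    beta: np.ndarray  # fixed-effect estimates
    blups: list[np.ndarray]
    converged: bool
    n_obs: int
    rank_X: int

    def varcomp(self, name: str) -> float:
        return self.sigma2[name]


def drop_collinear(X: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Return a full-column-rank subset of X's columns and their indices."""
    X = np.asarray(X, dtype=float)
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * (diag[0] if diag.size else 1.0)))
    keep = np.sort(piv[:rank])
    return X[:, keep], keep


def _neg2_reml_profiled(
    log_gamma: np.ndarray,
    WtW: np.ndarray,
    Wty: np.ndarray,
    yty: float,
    block_slices: list[slice],
    n: int,
    p: int,
) -> float:
    C = WtW.copy()
    penalty = 0.0
    for lg, sl in zip(log_gamma, block_slices):
        g = np.exp(lg)
        idx = np.arange(sl.start, sl.stop)
        C[idx, idx] += 1.0 / g
        penalty += (sl.stop - sl.start) * lg
    try:
        cf = linalg.cho_factor(C, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return np.inf
    logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
    theta = linalg.cho_solve(cf, Wty, check_finite=False)
    ypy = yty - Wty @ theta
    if ypy <= 0:
        return np.inf
    return (n - p) * np.log(ypy) + logdetC + penalty


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    Z_blocks: list[np.ndarray],
    names: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 2000,
    fix_gamma: dict[int, float] | None = None,
) -> RemlResult:
    """Fit the mixed model by profiled REML.

    Parameters
    ----------
    y, X
        Response and fixed-effect design.  Collinear columns of X are
        dropped automatically (estimates returned for the kept subset).
    Z_blocks
        One design matrix per independent random-effect block.
    names
        Labels for the variance components (defaults u1, u2, ...).
    fix_gamma
        Optional {block index: ratio} to pin specific variance ratios
        (ratio 0 removes the component from the fit).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    X, _ = drop_collinear(np.asarray(X, dtype=float).reshape(n, -1))
    p = X.shape[1]
    if names is None:
        names = [f"u{i + 1}" for i in range(len(Z_blocks))]
    if len(names) != len(Z_blocks):
        raise ValueError("names and Z_blocks length mismatch")
    fix_gamma = dict(fix_gamma or {})

    # components pinned at exactly zero are simply excluded
    active = [i for i in range(len(Z_blocks)) if fix_gamma.get(i, None) != 0.0]
    Zs = [np.asarray(Z_blocks[i], dtype=float) for i in active]
    W = np.hstack([X] + Zs) if Zs else X
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)

    block_slices = []
    start = p
    for Z in Zs:
        q = Z.shape[1]
        block_slices.append(slice(start, start + q))
        start += q

    # Degenerate data: the full design interpolates y exactly, so the
    # residual profile is unbounded.  Attribute variance hierarchically
    # (fixed effects, then each random block in the order given, which the
    # callers order coarse-to-fine), matching the balanced ANOVA limit.
    sol = np.linalg.lstsq(W, y, rcond=None)[0]
    rss_full = float(np.sum((y - W @ sol) ** 2))
    if rss_full <= 1e-10 * max(yty, 1e-300):
        beta0 = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta0
        sigma2 = {"resid": 0.0}
        blups: list[np.ndarray] = []
        gamma_full = np.zeros(len(Z_blocks))
        k = 0
        for i, Z in enumerate(Z_blocks):
            Z = np.asarray(Z, dtype=float)
            if i not in active:
                sigma2[names[i]] = 0.0
                blups.append(np.zeros(Z.shape[1]))
                continue
            u = np.linalg.lstsq(Z, r, rcond=None)[0]
            r = r - Z @ u
            sigma2[names[i]] = float(np.var(u, ddof=1)) if u.size > 1 else 0.0
            gamma_full[i] = np.inf if sigma2[names[i]] > 0 else 0.0
            blups.append(u)
            k += 1
        sigma2["resid"] = float(np.sum(r**2) / max(n - p, 1))
        return RemlResult(
            sigma2=sigma2,
            gamma=gamma_full,
            loglik=np.inf,
            beta=beta0,
            blups=blups,
            converged=True,
            n_obs=n,
            rank_X=p,
        )

    free = [k for k, i in enumerate(active) if i not in fix_gamma]
    fixed_lg = {
        k: np.log(fix_gamma[i]) for k, i in enumerate(active) if i in fix_gamma
    }

    def pack(free_lg: np.ndarray) -> np.ndarray:
        lg = np.empty(len(active))
        for k in fixed_lg:
            lg[k] = fixed_lg[k]
        for j, k in enumerate(free):
            lg[k] = free_lg[j]
        return lg

    converged = True
    if free:
        obj = lambda v: _neg2_reml_profiled(pack(v), WtW, Wty, yty, block_slices, n, p)
        x0 = np.zeros(len(free))
        res = optimize.minimize(
            obj,
            x0,
            method="Nelder-Mead",
            bounds=[(_LOG_GAMMA_LO, _LOG_GAMMA_HI)] * len(free),
            options={"xatol": 1e-8, "fatol": tol, "maxiter": max_iter, "maxfev": max_iter},
        )
        # restart once from the optimum (simplex can stall on ridges)
        res2 = optimize.minimize(
            obj,
            res.x,
            method="Nelder-Mead",
            bounds=[(_LOG_GAMMA_LO, _LOG_GAMMA_HI)] * len(free),
            options={"xatol": 1e-10, "fatol": tol, "maxiter": max_iter, "maxfev": max_iter},
        )
        best = res2 if res2.fun <= res.fun else res
        if not (res.success or res2.success):
            converged = False
        lg_opt = pack(best.x)
        fval = best.fun
    else:
        lg_opt = pack(np.empty(0))
        fval = _neg2_reml_profiled(lg_opt, WtW, Wty, yty, block_slices, n, p)

    if not np.isfinite(fval):
        raise RuntimeError("REML objective not finite at optimum; model misspecified")

    # recover estimates at the optimum
    C = WtW.copy()
    for lg, sl in zip(lg_opt, block_slices):
        idx = np.arange(sl.start, sl.stop)
        C[idx, idx] += np.exp(-lg)
    cf = linalg.cho_factor(C, lower=True, check_finite=False)
    theta = linalg.cho_solve(cf, Wty, check_finite=False)
    ypy = yty - Wty @ theta
    sigma2_e = ypy / (n - p)

    gamma_full = np.zeros(len(Z_blocks))
    for k, i in enumerate(active):
        g = np.exp(lg_opt[k])
        gamma_full[i] = 0.0 if lg_opt[k] <= _LOG_GAMMA_LO + 1e-6 else g

    sigma2 = {"resid": float(sigma2_e)}
    for i, nm in enumerate(names):
        sigma2[nm] = float(gamma_full[i] * sigma2_e)

    loglik = -0.5 * (fval - (n - p) * np.log(ypy) + (n - p) * (np.log(2 * np.pi * sigma2_e) + 1.0))
    # fval = (n-p) log ypy + logdetC + penalty; replace the profiled term
    # with the full constant-bearing expression.

    blups = [theta[sl] for sl in block_slices]
    # re-insert empty blups for excluded components
    full_blups: list[np.ndarray] = []
    k = 0
    for i, Z in enumerate(Z_blocks):
        if i in active:
            full_blups.append(blups[active.index(i)])
        else:
            full_blups.append(np.zeros(np.asarray(Z).shape[1]))
    return RemlResult(
        sigma2=sigma2,
        gamma=gamma_full,
        loglik=float(loglik),
        beta=theta[:p],
        blups=full_blups,
        converged=converged,
        n_obs=n,
        rank_X=p,
    )


def lrt_variance(full_loglik: float, reduced_loglik: float, tol: float = 1e-6) -> float:
    """Boundary-corrected LRT p-value for a single variance component.

    The null (component variance = 0) lies on the boundary of the
    parameter space, so the LR statistic follows an equal mixture of a
    point mass at zero and chi-square(1); the p-value is half the
    chi-square(1) upper tail (and 0.5 at LR = 0).
    """
    lr = 2.0 * (full_loglik - reduced_loglik)
    if lr < -tol:
        raise ValueError(
            f"reduced model log-likelihood exceeds full model ({reduced_loglik} > {full_loglik})"
        )
    lr = max(lr, 0.0)
    return 0.5 * float(stats.chi2.sf(lr, df=1))
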