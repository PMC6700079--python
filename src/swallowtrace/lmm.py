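"""Gaussian linear mixed models with crossed random intercepts.

Fits y = Xβ + Σ_k Z_k u_k + ε with u_k ~ N(0, σ²_k I) for a handful of
crossed grouping factors (here: ring, colony, year) by maximum likelihood,
profiling β and σ² out of the likelihood and optimizing the variance ratios
λ_k = σ²_k / σ² on the log scale.

The implementation exploits the structure of crossed intercepts: with the
largest factor's crossproduct block being diagonal, the q×q system
(I + D Z'Z D) reduces to a diagonal block plus a small dense Schur
complement, so one objective evaluation costs O(n + m·s² + s³) with m levels
of the big factor and s levels of the rest. This is what makes the
simulation calibration suites (hundreds of fits) affordable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

_LOG_LAMBDA_BOUNDS = (-20.0, 12.0)
_ZERO_VAR_TOL = 1e-8


@dataclass
class MixedLMResult:
    """ML fit of a crossed random-intercepts LMM."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    tvalues: pd.Series
    re_var: dict  # factor -> variance of its random intercept
    resid_var: float
    loglike: float
    n: int
    df_resid: int
    fitted_fixed: np.ndarray
    resid_marginal: np.ndarray
    resid_conditional: np.ndarray
    converged: bool

    @property
    def conditional_r2(self) -> float:
        """Nakagawa-style conditional R²: (fixed + random) / total variance."""
        var_f = float(np.var(self.fitted_fixed))
        var_r = float(sum(self.re_var.values()))
        denom = var_f + var_r + self.resid_var
        return (var_f + var_r) / denom if denom > 0 else 0.0

    @property
    def marginal_r2(self) -> float:
        var_f = float(np.var(self.fitted_fixed))
        denom = var_f + float(sum(self.re_var.values())) + self.resid_var
        return var_f / denom if denom > 0 else 0.0


class _Precomputed:
    """Sufficient statistics reused across objective evaluations."""

    def __init__(self, X: np.ndarray, y: np.ndarray, codes: list[np.ndarray], sizes: list[int]):
        self.n, self.p = X.shape
        self.X, self.y = X, y
        self.codes, self.sizes = codes, sizes
        self.K = len(codes)
        # order factors so the largest is the diagonal block
        order = np.argsort(sizes)[::-1]
        self.order = list(order)
        self.big = self.order[0]
        self.small = self.order[1:]
        m = sizes[self.big]
        s = int(sum(sizes[k] for k in self.small))
        self.m, self.s = m, s
        cb = codes[self.big]
        self.counts_big = np.bincount(cb, minlength=m).astype(float)
        # Z_big' X, Z_big' y
        self.ZbX = np.zeros((m, self.p))
        for j in range(self.p):
            self.ZbX[:, j] = np.bincount(cb, weights=X[:, j], minlength=m)
        self.Zby = np.bincount(cb, weights=y, minlength=m)
        # small-factor blocks, concatenated
        offs, ZsX_rows, Zsy_rows, counts_s = [], [], [], []
        off = 0
        self.offsets = {}
        for k in self.small:
            c, sz = codes[k], sizes[k]
            self.offsets[k] = (off, off + sz)
            off += sz
            counts_s.append(np.bincount(c, minlength=sz).astype(float))
            zx = np.zeros((sz, self.p))
            for j in range(self.p):
                zx[:, j] = np.bincount(c, weights=X[:, j], minlength=sz)
            ZsX_rows.append(zx)
            Zsy_rows.append(np.bincount(c, weights=y, minlength=sz))
        self.counts_small = np.concatenate(counts_s) if s else np.zeros(0)
        self.ZsX = np.vstack(ZsX_rows) if s else np.zeros((0, self.p))
        self.Zsy = np.concatenate(Zsy_rows) if s else np.zeros(0)
        # cross-tabs big × small and small × small
        self.B0 = np.zeros((m, s))
        for k in self.small:
            lo, hi = self.offsets[k]
            np.add.at(self.B0, (cb, codes[k] + lo), 1.0)
        self.C0 = np.zeros((s, s))
        for a_i, ka in enumerate(self.small):
            la, ha = self.offsets[ka]
            for kb in self.small:
                lb, hb = self.offsets[kb]
                blk = np.zeros((sizes[ka], sizes[kb]))
                np.add.at(blk, (codes[ka], codes[kb]), 1.0)
                self.C0[la:ha, lb:hb] = blk
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)


def _solve_blocks(pre: _Precomputed, lam: np.ndarray):
    """Factor A = I + D Z'Z D in (diagonal big block, dense small block) form.

    Returns (d, B, S_chol, logdet) where d is the big diagonal, B the scaled
    big×small cross block and S_chol the Cholesky of the Schur complement.
    """
    sb = math.sqrt(lam[pre.big])
    d = 1.0 + lam[pre.big] * pre.counts_big
    ss = np.concatenate(
        [np.full(pre.sizes[k], math.sqrt(lam[k])) for k in pre.small]
    ) if pre.s else np.zeros(0)
    B = sb * pre.B0 * ss[None, :] if pre.s else np.zeros((pre.m, 0))
    C = np.eye(pre.s) + ss[:, None] * pre.C0 * ss[None, :]
    S = C - (B / d[:, None]).T @ B
    L = np.linalg.cholesky(S) if pre.s else np.zeros((0, 0))
    logdet = float(np.log(d).sum()) + 2.0 * float(np.log(np.diag(L)).sum() if pre.s else 0.0)
    return d, B, L, logdet, sb, ss


def _apply_Ainv(d, B, L, u_big, u_small):
    """Solve A [v_big; v_small] = [u_big; u_small] via the Schur complement."""
    if L.shape[0]:
        rhs = u_small - (B / d[:, None] if u_big.ndim == 1 else B / d[:, None]).T @ u_big
        w = np.linalg.solve(L, rhs)
        v_small = np.linalg.solve(L.T, w)
        v_big = (u_big - B @ v_small) / (d[:, None] if u_big.ndim > 1 else d)
    else:
        v_small = u_small
        v_big = u_big / (d[:, None] if u_big.ndim > 1 else d)
    return v_big, v_small


def _profile_objective(log_lam: np.ndarray, pre: _Precomputed):
    lam = np.exp(log_lam)
    d, B, L, logdet, sb, ss = _solve_blocks(pre, lam)
    Ub = sb * pre.ZbX
    Us = ss[:, None] * pre.ZsX if pre.s else pre.ZsX
    ub = sb * pre.Zby
    us = ss * pre.Zsy if pre.s else pre.Zsy
    Vb, Vs = _apply_Ainv(d, B, L, Ub, Us)
    vb, vs = _apply_Ainv(d, B, L, ub, us)
    XtVX = pre.XtX - (Ub.T @ Vb + Us.T @ Vs)
    XtVy = pre.Xty - (Ub.T @ vb + Us.T @ vs)
    ytVy = pre.yty - (ub @ vb + us @ vs)
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf, None
    rss = max(ytVy - beta @ XtVy, 1e-300)
    sigma2 = rss / pre.n
    neg2ll = pre.n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet
    return 0.5 * neg2ll, (beta, sigma2, XtVX, d, B, L, sb, ss)


def fit_crossed_lmm(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    factors: list[str],
    add_intercept: bool = True,
) -> MixedLMResult:
    """ML fit of ``response ~ predictors`` with crossed random intercepts.

    ``factors`` are column names of grouping variables (all fitted as
    crossed random intercepts; a factor whose variance estimate hits the
    boundary is pinned at 0 with a warning, never silently dropped).
    Fixed-effect p-values are Wald t with residual degrees of freedom
    n − p (immaterial at the sample sizes this package targets; recorded
    here so outputs are self-describing).
    """
    if not factors:
        raise ValueError("at least one random factor is required")
    cols = [response, *predictors, *factors]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"columns not in data: {missing}")
    df = data[cols].dropna()
    y = df[response].to_numpy(dtype=float)
    names = (["intercept"] if add_intercept else []) + list(predictors)
    Xcols = ([np.ones(len(df))] if add_intercept else []) + [
        df[p].to_numpy(dtype=float) for p in predictors
    ]
    X = np.column_stack(Xcols)
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than observations")
    codes, sizes = [], []
    for f in factors:
        c, uniq = pd.factorize(df[f], sort=True)
        codes.append(np.asarray(c))
        sizes.append(len(uniq))
    pre = _Precomputed(X, y, codes, sizes)

    theta0 = np.full(len(factors), -1.0)
    res = optimize.minimize(
        lambda t: _profile_objective(t, pre)[0],
        theta0,
        method="L-BFGS-B",
        bounds=[_LOG_LAMBDA_BOUNDS] * len(factors),
        options=dict(maxiter=200, ftol=1e-12, gtol=1e-8),
    )
    obj, payload = _profile_objective(res.x, pre)
    if payload is None or not np.isfinite(obj):
        raise RuntimeError(f"mixed model failed to converge: {res.message}")
    beta, sigma2, XtVX, d, B, L, sb, ss = payload
    lam = np.exp(res.x)
    re_var = {}
    for k, f in enumerate(factors):
        v = lam[k] * sigma2
        if lam[k] <= math.exp(_LOG_LAMBDA_BOUNDS[0]) * 10 or v < _ZERO_VAR_TOL * sigma2:
            if v > 0:
                warnings.warn(
                    f"random-intercept variance for '{f}' is at the boundary; pinned to 0",
                    stacklevel=2,
                )
            v = 0.0
        re_var[f] = float(v)
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    bse = np.sqrt(np.diag(cov_beta))
    tvals = beta / bse
    df_resid = n - p
    pvals = 2 * stats.t.sf(np.abs(tvals), df=df_resid)
    fitted = X @ beta
    resid_marg = y - fitted
    # BLUPs: u_hat = Λ^{1/2} A^{-1} Λ^{1/2} Z' r  (Woodbury form)
    ub = sb * np.bincount(pre.codes[pre.big], weights=resid_marg, minlength=pre.m)
    if pre.s:
        us = ss * np.concatenate(
            [
                np.bincount(pre.codes[k], weights=resid_marg, minlength=pre.sizes[k])
                for k in pre.small
            ]
        )
    else:
        us = np.zeros(0)
    vb, vs = _apply_Ainv(d, B, L, ub, us)
    zu = sb * vb[pre.codes[pre.big]]
    for k in pre.small:
        lo, hi = pre.offsets[k]
        zu = zu + (vs[lo:hi] * np.full(pre.sizes[k], math.sqrt(lam[k])))[pre.codes[k]]
    resid_cond = resid_marg - zu
    idx = pd.Index(names)
    return MixedLMResult(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(bse, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        re_var=re_var,
        resid_var=float(sigma2),
        loglike=-obj,
        n=n,
        df_resid=df_resid,
        fitted_fixed=fitted,
        resid_marginal=resid_marg,
        resid_conditional=resid_cond,
        converged=bool(res.success),
    )
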