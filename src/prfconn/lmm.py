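"""Random-intercept linear mixed models with Satterthwaite inference.

The group analyses here all take the form

    value ~ fixed factorial effects + (1 | subject)

with REML estimation, Type III F tests for the fixed effects, and
Satterthwaite's approximation for the denominator degrees of freedom.  With a
single random intercept the marginal covariance is block diagonal,
``V_i = sigma_e^2 (I + lambda J)`` per subject, so the REML criterion, its
profile over ``lambda = sigma_b^2 / sigma_e^2``, and the GLS quantities all
have closed forms; only the 1-D profile optimisation and the 2x2 information
matrix for the variance components are numerical.

Fixed-effect factors use sum-to-zero (deviation) coding, under which the Wald
test of a term's coefficient block in the full model is the Type III test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["LMMFit", "AnovaTable", "fit_lmm", "lmm_anova", "contrast_test"]

_REL_STEP = 1e-4   # relative step for variance-component derivatives


# --------------------------------------------------------------------------
# design construction (sum-to-zero factorial coding)
# --------------------------------------------------------------------------

def _sum_code(values: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(values.unique())
    k = len(levels)
    if k < 2:
        raise ValueError(f"factor needs >= 2 levels, got {levels}")
    cols = np.zeros((len(values), k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[values.values == lev, j] = 1.0
    cols[values.values == levels[-1], :] = -1.0
    return cols, levels


def _build_design(df: pd.DataFrame, factors: list[str],
                  interactions: list[tuple[str, ...]]) -> tuple[np.ndarray, dict, dict]:
    main = {}
    levels = {}
    for f in factors:
        main[f], levels[f] = _sum_code(df[f])
    blocks = [np.ones((len(df), 1))]
    slices: dict[str, slice] = {}
    pos = 1
    for f in factors:
        blocks.append(main[f])
        slices[f] = slice(pos, pos + main[f].shape[1])
        pos += main[f].shape[1]
    for combo in interactions:
        cols = main[combo[0]]
        for f in combo[1:]:
            cols = np.einsum("ni,nj->nij", cols, main[f]).reshape(len(df), -1)
        blocks.append(cols)
        slices[":".join(combo)] = slice(pos, pos + cols.shape[1])
        pos += cols.shape[1]
    return np.hstack(blocks), slices, levels


# --------------------------------------------------------------------------
# REML machinery
# --------------------------------------------------------------------------

def _group_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-group sums needed for the block-diagonal GLS algebra."""
    uniq, gi = np.unique(groups, return_inverse=True)
    n_groups = len(uniq)
    sizes = np.bincount(gi)
    p = X.shape[1]
    sx = np.zeros((n_groups, p))
    sy = np.zeros(n_groups)
    np.add.at(sx, gi, X)
    np.add.at(sy, gi, y)
    return gi, sizes, sx, sy


@dataclass
class _REMLParts:
    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    sizes: np.ndarray
    sx: np.ndarray
    sy: np.ndarray
    n: int
    p: int

    def whitened(self, lam: float):
        """X'V*X, X'V*y, y'V*y for V* = sigma_e^2 V^{-1} (Woodbury)."""
        c = lam / (1.0 + lam * self.sizes)          # per-group shrinkage
        A = self.XtX - (self.sx * c[:, None]).T @ self.sx
        b = self.Xty - (self.sx * c[:, None]).T @ self.sy
        q = self.yty - float(c @ (self.sy ** 2))
        return A, b, q

    def minus2_reml(self, lam: float, sigma2_e: float | None = None):
        A, b, q = self.whitened(lam)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, None, None
        beta = np.linalg.solve(A, b)
        resid = q - float(b @ beta)
        if resid <= 0:
            resid = 1e-12
        if sigma2_e is None:
            sigma2_e = resid / (self.n - self.p)
        val = ((self.n - self.p) * np.log(sigma2_e)
               + float(np.sum(np.log1p(lam * self.sizes)))
               + logdet_A
               + resid / sigma2_e)
        return val, beta, sigma2_e


@dataclass
class LMMFit:
    """Fitted random-intercept LMM."""

    beta: np.ndarray
    sigma2_b: float                    # random-intercept variance
    sigma2_e: float                    # residual variance
    term_slices: dict
    factor_levels: dict
    n_obs: int
    n_groups: int
    singular: bool
    theta_cov: np.ndarray              # asymptotic cov of (sigma2_b, sigma2_e)
    _parts: _REMLParts = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return len(self.beta)

    def cov_beta(self, theta: tuple[float, float] | None = None) -> np.ndarray:
        """Covariance of the fixed effects at variance components ``theta``."""
        s2b, s2e = theta if theta is not None else (self.sigma2_b, self.sigma2_e)
        lam = s2b / s2e
        A, _, _ = self._parts.whitened(lam)
        return s2e * np.linalg.inv(A)

    # -- Satterthwaite df for a single contrast row ------------------------
    def satterthwaite_df(self, l: np.ndarray) -> float:
        theta = np.array([self.sigma2_b, self.sigma2_e])

        def f(th):
            return float(l @ self.cov_beta((max(th[0], 0.0), th[1])) @ l)

        grad = np.zeros(2)
        for i in range(2):
            h = _REL_STEP * max(theta[i], self.sigma2_e)
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] = max(tm[i] - h, 0.0 if i == 0 else h)
            grad[i] = (f(tp) - f(tm)) / (tp[i] - tm[i])
        denom = float(grad @ self.theta_cov @ grad)
        fval = f(theta)
        if denom <= 0:
            return float(self.n_obs - self.n_params)
        return 2.0 * fval * fval / denom


def fit_lmm(df: pd.DataFrame, response: str, factors: list[str],
            group: str = "subject",
            interactions: list[tuple[str, ...]] | str = "full") -> LMMFit:
    """Fit ``response ~ factorial(factors) + (1 | group)`` by REML.

    ``interactions='full'`` includes every interaction among the factors;
    pass an explicit list of factor tuples for a custom model.
    """
    df = df.dropna(subset=[response]).reset_index(drop=True)
    if interactions == "full":
        from itertools import combinations
        interactions = [c for r in range(2, len(factors) + 1)
                        for c in combinations(factors, r)]
    X, slices, levels = _build_design(df, factors, list(interactions))
    y = df[response].to_numpy(dtype=float)
    groups = df[group].to_numpy()
    n, p = X.shape
    gi, sizes, sx, sy = _group_stats(X, y, groups)
    parts = _REMLParts(XtX=X.T @ X, Xty=X.T @ y, yty=float(y @ y),
                       sizes=sizes, sx=sx, sy=sy, n=n, p=p)

    def crit(log_lam):
        return parts.minus2_reml(np.exp(log_lam))[0]

    res = optimize.minimize_scalar(crit, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    val0, _, _ = parts.minus2_reml(1e-12)
    singular = False
    if val0 <= res.fun + 1e-9:          # boundary fit: no subject variance
        lam = 1e-12
        singular = True
    _, beta, sigma2_e = parts.minus2_reml(lam)
    sigma2_b = lam * sigma2_e

    # observed information of the REML criterion in (sigma2_b, sigma2_e)
    theta = np.array([sigma2_b, sigma2_e])

    def m2(th):
        s2b = max(th[0], 0.0)
        return parts.minus2_reml(s2b / th[1], sigma2_e=th[1])[0]

    h = np.maximum(np.array([_REL_STEP * max(theta[0], sigma2_e),
                             _REL_STEP * sigma2_e]), 1e-12)

    def hess(fun, x0, steps):
        """Central-difference Hessian, falling back to forward differences in
        a direction when sigma2_b would go negative."""
        Hm = np.zeros((2, 2))
        ok_minus = [x0[i] - 2 * steps[i] >= 0 for i in range(2)]
        for i in range(2):
            ei = np.eye(2)[i] * steps[i]
            if ok_minus[i]:
                Hm[i, i] = (fun(x0 + ei) - 2 * fun(x0) + fun(x0 - ei)) / steps[i] ** 2
            else:
                Hm[i, i] = (fun(x0 + 2 * ei) - 2 * fun(x0 + ei) + fun(x0)) / steps[i] ** 2
        ei = np.eye(2)[0] * steps[0]
        ej = np.eye(2)[1] * steps[1]
        if ok_minus[0]:
            Hm[0, 1] = (fun(x0 + ei + ej) - fun(x0 + ei - ej)
                        - fun(x0 - ei + ej) + fun(x0 - ei - ej)) / (4 * steps[0] * steps[1])
        else:
            Hm[0, 1] = (fun(x0 + ei + ej) - fun(x0 + ei) - fun(x0 + ej) + fun(x0)) / (steps[0] * steps[1])
        Hm[1, 0] = Hm[0, 1]
        return Hm

    H = hess(m2, theta, h)
    info = H / 2.0                       # -2logLik -> information scale
    try:
        theta_cov = np.linalg.inv(info)
        if not np.all(np.isfinite(theta_cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        theta_cov = np.diag([sigma2_e ** 2, sigma2_e ** 2])
        singular = True

    return LMMFit(beta=beta, sigma2_b=sigma2_b, sigma2_e=sigma2_e,
                  term_slices=slices, factor_levels=levels, n_obs=n,
                  n_groups=len(sizes), singular=singular,
                  theta_cov=theta_cov, _parts=parts)


# --------------------------------------------------------------------------
# Type III F tests
# --------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Type III F tests with Satterthwaite denominator dfs."""

    rows: pd.DataFrame                 # effect, F, df1, df2, p, partial_eta_sq
    fit: LMMFit

    def effect(self, name: str) -> pd.Series:
        return self.rows.set_index("effect").loc[name]


def _f_test(fit: LMMFit, L: np.ndarray) -> tuple[float, float, float]:
    """lmerTest-style multi-df F with aggregated Satterthwaite ddf."""
    C = fit.cov_beta()
    VC = L @ C @ L.T
    q = L.shape[0]
    evals, evecs = np.linalg.eigh(VC)
    keep = evals > max(evals.max(), 1e-300) * 1e-10
    evals, evecs = evals[keep], evecs[:, keep]
    qeff = int(keep.sum())
    t2 = []
    dfs = []
    for i in range(qeff):
        l = evecs[:, i] @ L
        est = float(l @ fit.beta)
        t2.append(est * est / evals[i])
        dfs.append(fit.satterthwaite_df(l))
    F = float(np.sum(t2) / qeff)
    dfs = np.asarray(dfs)
    ok = dfs > 2
    if ok.any():
        E = float(np.sum(dfs[ok] / (dfs[ok] - 2)))
        df2 = 2 * E / (E - qeff) if E > qeff else float(np.min(dfs))
    else:
        df2 = float(np.min(dfs))
    return F, float(qeff), df2


def lmm_anova(df: pd.DataFrame, response: str, factors: list[str],
              group: str = "subject",
              interactions: list[tuple[str, ...]] | str = "full") -> AnovaTable:
    """Type III LMM ANOVA with Satterthwaite dfs and partial eta squared."""
    fit = fit_lmm(df, response, factors, group=group, interactions=interactions)
    rows = []
    for term, sl in fit.term_slices.items():
        L = np.zeros((sl.stop - sl.start, fit.n_params))
        for i, j in enumerate(range(sl.start, sl.stop)):
            L[i, j] = 1.0
        F, df1, df2 = _f_test(fit, L)
        p = float(stats.f.sf(F, df1, df2))
        eta = F * df1 / (F * df1 + df2)
        rows.append({"effect": term, "F": F, "df1": df1, "df2": df2,
                     "p": p, "partial_eta_sq": eta})
    return AnovaTable(rows=pd.DataFrame(rows), fit=fit)


def contrast_test(fit: LMMFit, l: np.ndarray) -> tuple[float, float, float, float]:
    """(estimate, SE, t, Satterthwaite df) for a single contrast row."""
    l = np.asarray(l, dtype=float)
    est = float(l @ fit.beta)
    se = float(np.sqrt(l @ fit.cov_beta() @ l))
    df = fit.satterthwaite_df(l)
    return est, se, est / se if se > 0 else np.inf, df
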