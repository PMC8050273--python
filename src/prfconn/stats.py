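"""Group-level statistics: repeated-measures LMM ANOVAs, Tukey HSD post-hocs,
paired stream comparisons, and effect sizes.

Input is a long table with one value per (subject, [hemisphere,] roi/stream,
band) cell; missing cells are permitted — the mixed model tolerates them,
which is why an LMM rather than a classical repeated-measures ANOVA is the
primary engine.  Proportions are analyzed on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lmm import AnovaTable, LMMFit, contrast_test, fit_lmm, lmm_anova

__all__ = ["band_by_stream_anova", "band_by_roi_hemisphere_anova",
           "tukey_posthoc", "paired_stream_test", "PairedTestResult",
           "cohens_d_paired", "cohens_d_pooled", "partial_eta_squared"]

REQUIRED_COLS = ("subject", "stream", "band", "value")


def band_by_stream_anova(table: pd.DataFrame) -> AnovaTable:
    """Type III LMM ANOVA: value ~ band * stream + (1 | subject).

    F tests use Satterthwaite denominator dfs; partial eta squared is
    reported per effect.  Requires >= 2 subjects, >= 2 bands, both streams.
    """
    for c in REQUIRED_COLS:
        if c not in table.columns:
            raise ValueError(f"long table must have a {c!r} column")
    if table["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if table["band"].nunique() < 2 or table["stream"].nunique() < 2:
        raise ValueError("need >= 2 bands and both streams")
    return lmm_anova(table, "value", ["band", "stream"], group="subject")


def band_by_roi_hemisphere_anova(table: pd.DataFrame) -> AnovaTable:
    """The 3-way lateralization model:
    value ~ band * roi * hemisphere + (1 | subject)."""
    return lmm_anova(table, "value", ["band", "roi", "hemisphere"],
                     group="subject")


def _marginal_row(fit: LMMFit, factor: str, level) -> np.ndarray:
    """Coefficient-space row giving the marginal (least-squares) mean of one
    factor level; with sum coding, other factors and interactions average
    to zero."""
    levels = fit.factor_levels[factor]
    sl = fit.term_slices[factor]
    row = np.zeros(fit.n_params)
    row[0] = 1.0
    j = levels.index(level)
    if j < len(levels) - 1:
        row[sl.start + j] = 1.0
    else:
        row[sl.start: sl.stop] = -1.0
    return row


def tukey_posthoc(anova: AnovaTable, factor: str) -> pd.DataFrame:
    """All pairwise level contrasts of ``factor`` with Tukey-HSD-adjusted
    p-values (family-wise confidence 0.95).

    p_adj uses the studentized range on the Satterthwaite df of each
    contrast; p_adj_classical repeats the adjustment with the residual df
    (the two coincide asymptotically and collapse to the plain t-test when
    the factor has two levels).
    """
    fit = anova.fit
    levels = fit.factor_levels[factor]
    k = len(levels)
    df_classical = fit.n_obs - fit.n_params
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            l = _marginal_row(fit, factor, levels[i]) - _marginal_row(fit, factor, levels[j])
            est, se, t, df = contrast_test(fit, l)
            q = abs(t) * np.sqrt(2.0)
            p_adj = float(sps.studentized_range.sf(q, k, df))
            p_cls = float(sps.studentized_range.sf(q, k, df_classical))
            rows.append({"level_a": levels[i], "level_b": levels[j],
                         "estimate": est, "se": se, "t": t, "df": df,
                         "p_adj": min(p_adj, 1.0),
                         "df_classical": float(df_classical),
                         "p_adj_classical": min(p_cls, 1.0)})
    return pd.DataFrame(rows)


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    mean_diff: float
    n_pairs: int
    degenerate: bool = False


def paired_stream_test(pairs: np.ndarray | list[tuple[float, float]]) -> PairedTestResult:
    """Paired t-test on per-subject (ventral, lateral) summaries.

    Incomplete pairs (NaN in either entry) are dropped; at least 3 complete
    pairs are required.  Cohen's d is mean(diff) / sd(diff).  A zero-variance
    difference is flagged degenerate.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    arr = arr[~np.isnan(arr).any(axis=1)]
    n = len(arr)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    diff = arr[:, 0] - arr[:, 1]
    sd = diff.std(ddof=1)
    if sd == 0:
        # constant difference: t is 0/0; identical pairs report a clean null,
        # a non-zero constant shift is flagged with no finite t
        zero = diff.mean() == 0
        return PairedTestResult(t=0.0 if zero else np.nan, df=n - 1,
                                p=1.0 if zero else np.nan,
                                cohens_d=0.0 if zero else np.nan,
                                mean_diff=float(diff.mean()),
                                n_pairs=n, degenerate=True)
    t, p = sps.ttest_rel(arr[:, 0], arr[:, 1])
    return PairedTestResult(t=float(t), df=n - 1, p=float(p),
                            cohens_d=float(diff.mean() / sd),
                            mean_diff=float(diff.mean()), n_pairs=n)


def cohens_d_paired(diff: np.ndarray) -> float:
    """d for paired data: mean difference over SD of differences."""
    diff = np.asarray(diff, dtype=float)
    sd = diff.std(ddof=1)
    return float(diff.mean() / sd) if sd > 0 else 0.0 if diff.mean() == 0 else np.inf


def cohens_d_pooled(a: np.ndarray, b: np.ndarray) -> float:
    """d for two independent groups with pooled SD."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if sp == 0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return float((a.mean() - b.mean()) / sp)


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """F-based partial eta squared: F*df1 / (F*df1 + df2)."""
    return float(F * df1 / (F * df1 + df2))
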