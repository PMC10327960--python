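"""Group-level repeated-measures ANOVA and stepwise post hoc tests.

The window measures produced by the FRP stage form a fully within-subject
design (every participant contributes every cell: fixation category, and
for the late window also region and hemisphere).  Each effect — main effect
or interaction — is tested with the classical univariate repeated-measures
F statistic, computed via orthonormal contrasts: for an effect with
contrast matrix M (rows orthonormal, spanning the effect space of the cell
means), the per-subject scores Z = Y Mᵀ give

    F = [n ||z̄||² / q] / [ Σᵢ ||zᵢ − z̄||² / ((n−1) q) ],  q = effect df.

Sphericity of Z's covariance is not assumed: the Greenhouse–Geisser epsilon
is estimated from the sample covariance of Z and sharpened into the
Huynh–Feldt epsilon (capped at 1), which multiplies both degrees of freedom
of the F reference distribution.  Following common practice the correction
is applied only to effects with two or more numerator degrees of freedom —
a two-level effect is sphericity-trivial and its epsilon is exactly 1.

Post hoc comparisons use the Newman–Keuls stepwise studentized-range
procedure on ranked cell means: the extremes of each subrange are compared
against a span-dependent critical range, and a non-significant range gates
(declares non-significant) every comparison nested inside it.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k matrix with orthonormal rows, each orthogonal to the mean."""
    c = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(c.T)
    return q[:, : k - 1].T


def _effect_label(effect: tuple[str, ...]) -> str:
    return ":".join(effect)


def rm_anova(data: pd.DataFrame, dv: str, within: list[str],
             subject: str = "participant") -> pd.DataFrame:
    """Repeated-measures ANOVA over 1-3 within-subject factors.

    ``data`` is long format with one row per subject x cell.  Returns one
    row per effect with columns ``effect, F, df_num, df_den, eps_hf,
    p_uncorrected, p_corrected, ms_error, n_subjects`` (the last two feed
    :func:`newman_keuls`).  Incomplete or unbalanced designs are rejected.
    """
    if not 1 <= len(within) <= 3:
        raise ValueError("1 to 3 within-subject factors supported")
    counts = data.groupby([subject] + within, observed=True).size()
    if (counts != 1).any():
        raise ValueError("duplicate subject x cell observations")
    levels = [sorted(data[f].unique()) for f in within]
    n_cells = int(np.prod([len(l) for l in levels]))
    wide = data.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any() or wide.shape[1] != n_cells:
        raise ValueError("missing cells: design must be complete and balanced")
    # order cell columns factor-major so Kronecker-structured contrasts align
    if len(within) == 1:
        wide = wide.reindex(columns=levels[0])
    else:
        wide = wide.reindex(columns=pd.MultiIndex.from_product(levels))
    Y = wide.to_numpy(float)
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")

    rows = []
    effects = [e for size in range(1, len(within) + 1)
               for e in combinations(within, size)]
    for effect in effects:
        mats = []
        for f, lev in zip(within, levels):
            k = len(lev)
            mats.append(_orthonormal_contrasts(k) if f in effect
                        else np.full((1, k), 1.0 / np.sqrt(k)))
        M = mats[0]
        for m in mats[1:]:
            M = np.kron(M, m)
        q = M.shape[0]
        Z = Y @ M.T
        zbar = Z.mean(axis=0)
        ss_eff = n * float(zbar @ zbar)
        resid = Z - zbar
        ss_err = float((resid ** 2).sum())
        df1, df2 = q, (n - 1) * q
        ms_err = ss_err / df2
        F = (ss_eff / df1) / ms_err
        p_unc = float(f_dist.sf(F, df1, df2))
        if q >= 2:
            S = np.cov(Z, rowvar=False)
            tr = np.trace(S)
            gg = tr ** 2 / (q * float(np.sum(S * S)))
            hf = (n * q * gg - 2) / (q * (n - 1 - q * gg))
            eps = float(min(1.0, max(hf, 1.0 / q)))
            p_corr = float(f_dist.sf(F, df1 * eps, df2 * eps))
        else:
            eps, p_corr = 1.0, p_unc
        rows.append({"effect": _effect_label(effect), "F": F,
                     "df_num": df1, "df_den": df2, "eps_hf": eps,
                     "p_uncorrected": p_unc, "p_corrected": p_corr,
                     "ms_error": ms_err, "n_subjects": n})
    return pd.DataFrame(rows)


def newman_keuls(means: dict[str, float] | pd.Series, ms_error: float,
                 df_error: float, n: int, alpha: float = 0.05) -> pd.DataFrame:
    """Newman-Keuls stepwise studentized-range test on cell means.

    ``ms_error`` and ``df_error`` come from the ANOVA effect the means
    belong to; ``n`` is the number of observations behind each mean.
    Returns one row per pair with the mean difference, span, studentized
    range statistic, critical range at ``alpha``, raw p, and a
    ``significant`` flag that honours the stepwise gating rule.
    """
    if n < 2:
        raise ValueError("need n >= 2 observations per mean")
    means = pd.Series(means).sort_values()
    labels = list(means.index)
    k = len(labels)
    se = np.sqrt(ms_error / n)

    sig: dict[tuple[int, int], bool] = {}
    rows = []
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            diff = float(means.iloc[j] - means.iloc[i])
            q_stat = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
            p = float(studentized_range.sf(q_stat, span, df_error)) \
                if np.isfinite(q_stat) else 0.0
            crit = float(studentized_range.ppf(1 - alpha, span, df_error)) * se
            gated = any(not sig[(a, b)]
                        for (a, b) in sig if a <= i and b >= j)
            significant = (p < alpha) and not gated
            sig[(i, j)] = significant
            rows.append({"level_a": labels[i], "level_b": labels[j],
                         "mean_difference": diff, "span": span,
                         "q": q_stat, "critical_range": crit, "p": p,
                         "significant": significant})
    return pd.DataFrame(rows)


def newman_keuls_factor(data: pd.DataFrame, dv: str, within: list[str],
                        factor: str, subject: str = "participant",
                        alpha: float = 0.05) -> pd.DataFrame:
    """Post hoc comparisons of one factor's marginal means.

    Convenience wrapper: runs the ANOVA, takes the factor's main-effect
    error term, and compares the factor's marginal means (each averaging
    n_subjects x levels-of-other-factors observations).
    """
    table = rm_anova(data, dv, within, subject)
    row = table[table["effect"] == factor].iloc[0]
    marginal = data.groupby(factor, observed=True)[dv].mean()
    n_other = len(data) / (len(marginal) * row["n_subjects"])
    n = int(round(row["n_subjects"] * n_other))
    return newman_keuls(marginal, row["ms_error"], row["df_den"], n, alpha)
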