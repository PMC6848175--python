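"""General-linear-model group statistics with permutation inference.

Edge-wise and feature-wise group effects are tested with a partial F
statistic for the group factor given nuisance covariates (gender, and
optionally intracranial volume); with no covariates this reduces to the
one-way ANOVA F.  Significance comes from Monte-Carlo permutation of the
group labels — covariate values stay attached to their subjects — with the
false discovery rate controlled by Benjamini-Hochberg across the tested
family.  Summary-statistic versions of the F and t tests are provided so
published group means/SDs/sizes can be checked directly.
"""

from __future__ import annotations

from itertools import permutations as _iter_permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# -- design construction -------------------------------------------------


def _group_codes(groups: np.ndarray) -> tuple[np.ndarray, list[str]]:
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    codes = np.array([levels.index(g) for g in groups])
    return codes, levels


def _design_matrices(
    codes: np.ndarray, n_levels: int, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Full (intercept + group dummies + covariates) and reduced designs."""
    n = codes.size
    cols = [np.ones(n)]
    for level in range(1, n_levels):
        cols.append((codes == level).astype(float))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariates are not aligned with subjects")
        cols.extend(cov.T)
    full = np.column_stack(cols)
    n_cov = full.shape[1] - n_levels
    reduced = np.column_stack([full[:, :1], full[:, n_levels:]])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("rank-deficient design (collinear group/covariate columns)")
    del n_cov
    return full, reduced


def _rss(q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of y projected off the column span of Q."""
    total = np.einsum("ij,ij->j", y, y)
    fitted = q.T @ y
    return total - np.einsum("ij,ij->j", fitted, fitted)


def f_statistics(
    y: np.ndarray, groups: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[np.ndarray, int, int]:
    """Partial F for the group factor, vectorized over columns of ``y``.

    Returns ``(F, df1, df2)`` where ``F`` has one entry per column of ``y``.
    """
    y = np.asarray(y, dtype=float)
    y2d = y[:, None] if y.ndim == 1 else y
    y2d = y2d - y2d.mean(axis=0)  # intercept absorbs the shift; better conditioning
    codes, levels = _group_codes(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs at least two subjects")
    full, reduced = _design_matrices(codes, len(levels), covariates)
    q_full, _ = np.linalg.qr(full)
    q_red, _ = np.linalg.qr(reduced)
    rss_full = _rss(q_full, y2d)
    rss_red = _rss(q_red, y2d)
    df1 = len(levels) - 1
    df2 = y2d.shape[0] - full.shape[1]
    if df2 <= 0:
        raise ValueError("not enough subjects for the design")
    denom = rss_full / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(denom > 0, (rss_red - rss_full) / df1 / denom, 0.0)
    f = np.maximum(f, 0.0)  # guard tiny negative round-off
    return (f[0] if y.ndim == 1 else f), df1, df2


def glm_f(
    y: np.ndarray, groups: np.ndarray, covariates: np.ndarray | None = None
) -> float:
    """Partial F statistic for group membership given covariates (scalar y)."""
    f, _, _ = f_statistics(np.asarray(y, dtype=float), groups, covariates)
    return float(f)


# -- summary-statistic oracles -------------------------------------------


def anova_f_from_summary(means, sds, ns) -> float:
    """One-way ANOVA F from per-group means, SDs (ddof=1) and sizes."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    k = means.size
    if k < 2:
        raise ValueError("need at least two groups")
    if (ns < 2).any():
        raise ValueError("every group needs at least two subjects")
    n_total = ns.sum()
    grand = float(np.sum(ns * means) / n_total)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds**2))
    if ss_within <= 0:
        raise ValueError("zero pooled within-group variance; F undefined")
    return (ss_between / (k - 1)) / (ss_within / (n_total - k))


def two_sample_t_from_summary(m1, s1, n1, m2, s2, n2) -> float:
    """Pooled-variance two-sample t from group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two subjects per group")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance; t undefined")
    return float((m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2)))


def two_sample_t(y1: np.ndarray, y2: np.ndarray) -> float:
    """Pooled-variance two-sample t from raw samples."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    return two_sample_t_from_summary(
        y1.mean(), y1.std(ddof=1), y1.size, y2.mean(), y2.std(ddof=1), y2.size
    )


# -- permutation inference -----------------------------------------------


def permutation_p(
    y: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    stat_fn=None,
    n_permutations: int = 10000,
    seed: int | None = None,
    tail: str = "upper",
    method: str = "montecarlo",
) -> tuple[float, float]:
    """Permutation p-value for a group statistic on one outcome vector.

    Group labels are shuffled while covariate values stay attached to their
    subjects.  ``stat_fn(y, groups, covariates) -> float`` defaults to the
    partial F (upper tail); pass ``tail="two"`` for signed statistics, where
    exceedance is measured in absolute value.

    ``method="montecarlo"`` draws ``n_permutations`` random relabelings and
    returns ``p = (b + 1) / (m + 1)``, which can never be zero.
    ``method="exact"`` enumerates all label permutations (small n only) and
    returns the exact exceedance proportion, the identity included.

    Returns ``(observed_statistic, p)``.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if stat_fn is None:
        stat_fn = glm_f
    observed = float(stat_fn(y, groups, covariates))
    reference = abs(observed) if tail == "two" else observed

    def exceeds(value: float) -> bool:
        v = abs(value) if tail == "two" else value
        return v >= reference - 1e-12

    if method == "exact":
        n = groups.size
        if factorial(n) > 50000:
            raise ValueError("exact enumeration is limited to small samples")
        b = 0
        m = 0
        for perm in _iter_permutations(range(n)):
            m += 1
            if exceeds(float(stat_fn(y, groups[list(perm)], covariates))):
                b += 1
        return observed, b / m
    if method != "montecarlo":
        raise ValueError(f"unknown method {method!r}")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        shuffled = groups[rng.permutation(groups.size)]
        if exceeds(float(stat_fn(y, shuffled, covariates))):
            b += 1
    return observed, (b + 1) / (n_permutations + 1)


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        raise ValueError("empty p-value vector")
    if ((pvalues <= 0) | (pvalues > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject, p_adj


def spearman_assoc(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected) and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; rank correlation undefined")
    result = stats.spearmanr(x, y)
    return float(result.statistic), float(result.pvalue)


# -- pairwise post-hoc contrasts -----------------------------------------


def _contrast_t(
    y: np.ndarray, indicator: np.ndarray, covariates: np.ndarray | None
) -> np.ndarray:
    """t statistic of the group-indicator coefficient, per column of ``y``.

    Model: y ~ 1 + indicator (+ covariates); positive t means the indicated
    group has the larger adjusted mean.
    """
    n = indicator.size
    cols = [np.ones(n), indicator.astype(float)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    x = np.column_stack(cols)
    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    df = n - np.linalg.matrix_rank(x)
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    return beta[1] / se


def pairwise_posthoc(
    values: np.ndarray,
    groups: np.ndarray,
    gender: np.ndarray | None,
    names: list[str],
    pairs: tuple[tuple[str, str], ...] = (("HC", "PD"), ("HC", "MSA"), ("PD", "MSA")),
    n_permutations: int = 10000,
    seed: int | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Pairwise group contrasts on pre-selected edges or features.

    For each pair (a, b) and each column of ``values``, fits the GLM t for
    the indicator of group b adjusted for gender, derives a two-tailed
    permutation p by shuffling the pair's group labels, and controls FDR
    across the whole pair-by-column family.  A negative t means group b has
    the smaller adjusted mean.

    Returns a tidy frame with one row per pair and column.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    groups = np.asarray(groups)
    if len(names) != values.shape[1]:
        raise ValueError("names are not aligned with value columns")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        mask = np.isin(groups, (a, b))
        if not (groups == a).any() or not (groups == b).any():
            raise ValueError(f"group missing from pair {a}-{b}")
        y = values[mask]
        indicator = (groups[mask] == b).astype(float)
        cov = None if gender is None else np.asarray(gender, dtype=float)[mask]
        t_obs = _contrast_t(y, indicator, cov)
        exceed = np.zeros(y.shape[1], dtype=int)
        for _ in range(n_permutations):
            shuffled = indicator[rng.permutation(indicator.size)]
            t_null = _contrast_t(y, shuffled, cov)
            exceed += np.abs(t_null) >= np.abs(t_obs) - 1e-12
        p_perm = (exceed + 1) / (n_permutations + 1)
        df = y.shape[0] - (2 if cov is None else 2 + np.atleast_2d(cov).shape[0])
        for j, name in enumerate(names):
            rows.append(
                {
                    "pair": f"{a}-{b}",
                    "name": name,
                    "t": float(t_obs[j]),
                    "df": int(df),
                    "p_perm": float(p_perm[j]),
                }
            )
    frame = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(frame["p_perm"].to_numpy(), q=q)
    frame["p_fdr"] = p_adj
    frame["significant"] = reject
    frame["direction"] = np.where(frame["t"] < 0, "second<first", "second>first")
    return frame
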