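"""Statistical layer: repeated-measures ANOVA with sphericity handling,
within-subject Tukey HSD, Bonferroni thresholds, permutation testing of
metric-vs-density curves, and per-density paired contrasts.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats as sstats

__all__ = [
    "RMAnovaResult",
    "FDAResult",
    "rm_anova",
    "tukey_hsd_within",
    "bonferroni_threshold",
    "fda_curve_test",
    "prepost_density_ttests",
]


@dataclasses.dataclass
class RMAnovaResult:
    f_stat: float
    df_num: int
    df_den: int
    ms_error: float
    gg_epsilon: float
    mauchly_w: float
    mauchly_p: float
    p_uncorrected: float
    p_gg: float


@dataclasses.dataclass
class FDAResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    dropped_grid_points: int = 0


def _check_matrix(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a subject x level matrix")
    if np.any(~np.isfinite(values)):
        raise ValueError("missing or non-finite cells are not supported")
    return values


def _rm_decomposition(values: np.ndarray) -> tuple[float, float, int, int]:
    """Within-subject one-way SS decomposition -> (MS_level, MS_error, dfn, dfe)."""
    n, k = values.shape
    grand = values.mean()
    level_means = values.mean(axis=0)
    subject_means = values.mean(axis=1)
    ss_level = n * np.sum((level_means - grand) ** 2)
    residual = values - level_means[None, :] - subject_means[:, None] + grand
    ss_error = np.sum(residual**2)
    dfn = k - 1
    dfe = (n - 1) * (k - 1)
    return ss_level / dfn, ss_error / dfe, dfn, dfe


def rm_anova(values: np.ndarray) -> RMAnovaResult:
    """One-way within-subject ANOVA with Mauchly's test and GG correction.

    ``values`` is subjects x levels with no missing cells.  The
    Greenhouse-Geisser epsilon comes from the double-centered covariance of
    the levels; the corrected p-value uses (eps * dfn, eps * dfe).
    """
    values = _check_matrix(values)
    n, k = values.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 levels")
    ms_level, ms_error, dfn, dfe = _rm_decomposition(values)
    f = ms_level / ms_error if ms_error > 0 else (0.0 if ms_level == 0 else np.inf)
    p_unc = float(sstats.f.sf(f, dfn, dfe)) if np.isfinite(f) else 0.0

    # Greenhouse-Geisser epsilon from the double-centered level covariance
    cov = np.cov(values, rowvar=False, ddof=1)
    centered = cov - cov.mean(axis=0)[None, :] - cov.mean(axis=1)[:, None] + cov.mean()
    tr = np.trace(centered)
    denom = dfn * np.sum(centered**2)
    eps = float(tr**2 / denom) if denom > 0 else 1.0
    eps = min(max(eps, 1.0 / dfn), 1.0)

    # Mauchly's sphericity test on orthonormal contrasts
    contrasts = np.linalg.qr(
        np.eye(k) - np.full((k, k), 1.0 / k), mode="complete"
    )[0][:, : k - 1]
    s = contrasts.T @ cov @ contrasts
    sign, logdet = np.linalg.slogdet(s)
    trace_s = np.trace(s)
    if sign <= 0 or trace_s <= 0:
        w_stat, p_mauchly = 0.0, 0.0
    else:
        log_w = logdet - dfn * np.log(trace_s / dfn)
        w_stat = float(np.exp(log_w))
        d = dfn
        factor = (n - 1) - (2 * d**2 + d + 2) / (6.0 * d)
        chi2 = -factor * log_w
        df_chi = d * (d + 1) // 2 - 1
        p_mauchly = float(sstats.chi2.sf(chi2, df_chi)) if df_chi > 0 else 1.0

    p_gg = (
        float(sstats.f.sf(f, eps * dfn, eps * dfe)) if np.isfinite(f) else 0.0
    )
    return RMAnovaResult(
        f_stat=float(f),
        df_num=dfn,
        df_den=dfe,
        ms_error=float(ms_error),
        gg_epsilon=eps,
        mauchly_w=w_stat,
        mauchly_p=p_mauchly,
        p_uncorrected=p_unc,
        p_gg=p_gg,
    )


def tukey_hsd_within(values: np.ndarray) -> np.ndarray:
    """Pairwise studentized-range p-values using the within-subject error MS.

    Returns a symmetric k x k matrix with a unit diagonal.
    """
    values = _check_matrix(values)
    n, k = values.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 levels")
    _, ms_error, _, dfe = _rm_decomposition(values)
    means = values.mean(axis=0)
    p = np.ones((k, k))
    if ms_error == 0:
        diff = np.abs(means[:, None] - means[None, :]) > 0
        p[diff] = 0.0
        return p
    se = np.sqrt(ms_error / n)
    q = np.abs(means[:, None] - means[None, :]) / se
    off = ~np.eye(k, dtype=bool)
    p[off] = sstats.studentized_range.sf(q[off], k, dfe)
    return p


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Per-comparison threshold alpha / m; returns (exact, 4-decimal display)."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    exact = alpha / m
    return exact, round(exact, 4)


def _pointwise_t_paired(diff: np.ndarray) -> np.ndarray:
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    return mean / (sd / np.sqrt(n))


def _pointwise_t_unpaired(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    pooled[pooled == 0] = np.inf
    return (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(pooled * (1 / na + 1 / nb))


def _integrate(t: np.ndarray, grid: np.ndarray, statistic: str) -> float:
    if statistic == "integrated_t":
        return float(np.trapezoid(t**2, grid))
    if statistic == "max_t":
        return float(np.max(np.abs(t)))
    raise ValueError(f"unknown statistic {statistic!r}")


def fda_curve_test(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    paired: bool = True,
    grid: np.ndarray | None = None,
    statistic: str = "integrated_t",
) -> FDAResult:
    """Permutation test comparing two families of metric-vs-density curves.

    The observed statistic integrates the squared pointwise t statistic over
    the density grid (trapezoidal weights; ``statistic='max_t'`` selects the
    maximum-|t| alternative).  The null permutes condition labels — paired:
    per-subject sign flips of the difference curves; unpaired: group-label
    shuffles.  p = (1 + #{null >= observed}) / (1 + n_perm), so it is never 0.
    """
    a = _check_matrix(curves_a)
    b = _check_matrix(curves_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("curve families must share the density grid")
    if paired and a.shape[0] != b.shape[0]:
        raise ValueError("paired test requires equal subject counts")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is coarse")
    if grid is None:
        grid = np.arange(a.shape[1], dtype=float)
    grid = np.asarray(grid, dtype=float)

    dropped = 0
    if paired:
        diff = a - b
        keep = diff.std(axis=0, ddof=1) > 0
    else:
        keep = np.concatenate([a, b]).std(axis=0, ddof=1) > 0
    if not np.all(keep):
        dropped = int((~keep).sum())
        warnings.warn(f"dropping {dropped} zero-variance grid points")
        a, b, grid = a[:, keep], b[:, keep], grid[keep]
        if grid.size == 0:
            return FDAResult(0.0, np.zeros(n_perm), 1.0, n_perm, seed, dropped)

    rng = np.random.default_rng(seed)
    if paired:
        diff = a - b
        observed = _integrate(_pointwise_t_paired(diff), grid, statistic)
        n = diff.shape[0]
        null = np.empty(n_perm)
        for p_i in range(n_perm):
            signs = rng.choice((-1.0, 1.0), size=n)
            null[p_i] = _integrate(
                _pointwise_t_paired(diff * signs[:, None]), grid, statistic
            )
    else:
        observed = _integrate(_pointwise_t_unpaired(a, b), grid, statistic)
        pooled = np.concatenate([a, b], axis=0)
        na = a.shape[0]
        null = np.empty(n_perm)
        for p_i in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            null[p_i] = _integrate(
                _pointwise_t_unpaired(pooled[perm[:na]], pooled[perm[na:]]),
                grid,
                statistic,
            )
    p_value = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return FDAResult(
        observed_stat=float(observed),
        null_stats=null,
        p_value=float(p_value),
        n_perm=n_perm,
        seed=seed,
        dropped_grid_points=dropped,
    )


def prepost_density_ttests(
    pre_curves: np.ndarray,
    post_curves: np.ndarray,
    alpha: float = 0.05,
    m: int = 23,
) -> dict:
    """Paired t-test per density level with a Bonferroni significance mask.

    Returns a dict with per-density ``t``, ``p`` and the boolean
    ``significant`` mask at threshold alpha / m.
    """
    pre = _check_matrix(pre_curves)
    post = _check_matrix(post_curves)
    if pre.shape != post.shape:
        raise ValueError("pre and post curves must have identical shape")
    if pre.shape[0] < 3:
        raise ValueError("need at least 3 subject pairs")
    t, p = sstats.ttest_rel(post, pre, axis=0)
    threshold, display = bonferroni_threshold(alpha, m)
    return {
        "t": np.asarray(t),
        "p": np.asarray(p),
        "significant": np.asarray(p) < threshold,
        "threshold": threshold,
        "threshold_display": display,
    }
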