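"""Resampling and rank-based inference used by every analysis stage.

Group comparisons are normality-gated: Shapiro-Wilk at alpha = 0.05 per
group decides between parametric (t-test family) and rank-based
(Wilcoxon / Mann-Whitney / Kruskal-Wallis) branches.  Key comparisons
additionally use a two-sided permutation test with 10,000 label
shuffles, and plotted aggregates carry bootstrap 95% confidence
intervals of the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_resamples: int | None = None
    tails: str = "two_sided"


def permutation_test(
    group_a,
    group_b,
    statistic: str,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Two-sided permutation test on the difference of group means or medians.

    Labels are shuffled ``n_resamples`` times; the p-value uses the
    add-the-observed correction ``p = (1 + #{|T*| >= |T|}) / (n + 1)``,
    which guarantees ``p >= 1/(n+1)`` and a valid test.  ``statistic``
    must be ``"mean"`` or ``"median"`` (never a silent default).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if statistic == "mean":
        fn = np.mean
    elif statistic == "median":
        fn = np.median
    else:
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    obs = fn(a) - fn(b)
    na, n = a.size, pooled.size
    # all permutations at once: each row an independent shuffle of labels
    idx = np.argsort(rng.random((n_resamples, n)), axis=1)
    perm = pooled[idx]
    null = fn(perm[:, :na], axis=1) - fn(perm[:, na:], axis=1)
    p = (1 + int(np.sum(np.abs(null) >= abs(obs) - 1e-12))) / (n_resamples + 1)
    return TestResult(float(obs), float(p), f"permutation_{statistic}", n_resamples)


def bootstrap_ci(
    values,
    level: float = 0.95,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_resamples, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)


def normality_gated_test(*groups, paired: bool = False) -> TestResult:
    """Group comparison with a Shapiro-Wilk gate (alpha = 0.05 per group).

    If every group looks Gaussian the parametric branch runs (paired or
    independent t-test, one-way ANOVA for 3+ groups); otherwise the
    rank-based branch (Wilcoxon signed-rank, Mann-Whitney U,
    Kruskal-Wallis).  The chosen method is recorded in the result.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 3 for g in gs):
        raise ValueError("each group needs n >= 3 for the normality gate")
    if paired and len(gs) != 2:
        raise ValueError("paired comparisons take exactly two groups")
    if paired and gs[0].size != gs[1].size:
        raise ValueError("paired groups must have equal length")

    def _shapiro_ok(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:  # constant sample: trivially non-normal branch
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sps.shapiro(x).pvalue >= 0.05

    gate_samples = [gs[0] - gs[1]] if paired else gs
    normal = all(_shapiro_ok(g) for g in gate_samples)

    if paired:
        diff = gs[0] - gs[1]
        if np.ptp(diff) == 0 and np.all(diff == 0):
            return TestResult(0.0, 1.0, "paired_identical", None)
        if normal:
            r = sps.ttest_rel(gs[0], gs[1])
            return TestResult(float(r.statistic), float(r.pvalue), "paired_t")
        r = sps.wilcoxon(gs[0], gs[1])
        return TestResult(float(r.statistic), float(r.pvalue), "wilcoxon_signed_rank")

    if len(gs) == 2:
        if normal:
            r = sps.ttest_ind(gs[0], gs[1])
            return TestResult(float(r.statistic), float(r.pvalue), "t_ind")
        r = sps.mannwhitneyu(gs[0], gs[1], alternative="two-sided")
        return TestResult(float(r.statistic), float(r.pvalue), "mann_whitney_u")

    if normal:
        r = sps.f_oneway(*gs)
        return TestResult(float(r.statistic), float(r.pvalue), "anova_oneway")
    r = sps.kruskal(*gs)
    return TestResult(float(r.statistic), float(r.pvalue), "kruskal_wallis")


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with mid-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant input")
    r = sps.spearmanr(x, y)
    return TestResult(float(r.statistic), float(r.pvalue), "spearman")
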