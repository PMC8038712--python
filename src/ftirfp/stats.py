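"""Nonparametric test battery for group comparisons of band ratios.

The battery mirrors what is standard for small-cohort spectroscopy:
a normality screen (D'Agostino K^2) to justify the nonparametric branch,
a Kruskal-Wallis omnibus over all groups, Dunn-type many-to-one rank
comparisons against a control with family-wise adjustment, Mann-Whitney U
for two independent groups (exact by enumeration for small tie-free
samples), and Welch's t-test for comparing peak intensities.

All rank statistics use midranks; tie corrections are applied where the
classical formulas define them. All p-values are two-sided and a result
is called significant when p <= alpha (0.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "manytoone_rank_posthoc",
    "mann_whitney_u",
    "welch_t",
    "normality_screen",
]

DEFAULT_ALPHA = 0.05


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float | None
    df: float | tuple[float, float] | None = None
    comparison: tuple[str, str] | str = "omnibus"
    adjusted: bool = False
    alpha: float = DEFAULT_ALPHA
    recommendation: str | None = None
    note: str = ""

    @property
    def significant(self) -> bool | None:
        if self.p_value is None:
            return None
        return self.p_value <= self.alpha


def _as_groups(groups, names=None):
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if names is None:
        names = [f"group_{i + 1}" for i in range(len(arrs))]
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group needs at least one value")
    if any(not np.all(np.isfinite(a)) for a in arrs):
        raise ValueError("non-finite values in input")
    return arrs, list(names)


def _tie_sum(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups, names=None, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Kruskal-Wallis H over k independent groups, chi-square p with k-1 df.

    H is computed on midranks and divided by the tie correction
    ``1 - sum(t^3 - t) / (N^3 - N)``; all values identical is degenerate
    (the correction vanishes) and raises.
    """
    arrs, names = _as_groups(groups, names)
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(arrs)
    N = pooled.size
    if N < 3:
        raise ValueError("need a total of at least 3 observations")
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate ties: all values identical")
    ranks = sps.rankdata(pooled)
    H = 0.0
    start = 0
    for a in arrs:
        r = ranks[start:start + a.size]
        H += r.sum() ** 2 / a.size
        start += a.size
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    correction = 1.0 - _tie_sum(pooled) / (N**3 - N)
    H /= correction
    df = len(arrs) - 1
    p = float(sps.chi2.sf(H, df))
    return TestResult("kruskal_wallis", float(H), p, df=float(df), alpha=alpha)


def manytoone_rank_posthoc(groups, control_index: int = 0, adjustment: str = "bonferroni",
                           names=None, alpha: float = DEFAULT_ALPHA) -> list[TestResult]:
    """Dunn-type many-to-one rank comparisons of every group vs a control.

    For each treatment i: z = (Rbar_i - Rbar_c) / sqrt(V * (1/n_i + 1/n_c))
    with V = N(N+1)/12 - sum(t^3 - t) / (12 (N-1)) on pooled midranks.
    Two-sided normal p per comparison, family-adjusted over the m = k-1
    comparisons by ``bonferroni``, ``sidak`` or ``none``.
    """
    arrs, names = _as_groups(groups, names)
    if not 0 <= control_index < len(arrs):
        raise ValueError("control_index out of range")
    if adjustment not in ("bonferroni", "sidak", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    pooled = np.concatenate(arrs)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    means, start = [], 0
    for a in arrs:
        means.append(ranks[start:start + a.size].mean())
        start += a.size
    V = N * (N + 1) / 12.0 - _tie_sum(pooled) / (12.0 * (N - 1))
    if V <= 0:
        raise ValueError("degenerate ties: all values identical")
    m = len(arrs) - 1
    out = []
    nc = arrs[control_index].size
    for i, a in enumerate(arrs):
        if i == control_index:
            continue
        z = (means[i] - means[control_index]) / np.sqrt(V * (1.0 / a.size + 1.0 / nc))
        p = float(2.0 * sps.norm.sf(abs(z)))
        if adjustment == "bonferroni":
            p_adj = min(1.0, p * m)
        elif adjustment == "sidak":
            p_adj = 1.0 - (1.0 - p) ** m
        else:
            p_adj = p
        out.append(TestResult(
            "dunn_manytoone", float(z), p_adj,
            comparison=(names[i], names[control_index]),
            adjusted=adjustment != "none", alpha=alpha,
            note=f"unadjusted p={p:.6g}; adjustment={adjustment}, m={m}",
        ))
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_distribution(n1: int, n2: int) -> np.ndarray:
    """Null distribution counts of U_x for tie-free samples.

    Classic recurrence N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1)
    over the C(n1+n2, n1) equally likely rank arrangements, obtained by
    conditioning on whether the largest observation is an x or a y.
    counts[u] = number of arrangements with U_x = u.
    """
    umax = n1 * n2
    # dp[m][u] for current n; start at n = 0 where U_x is always 0
    dp = [[1.0] + [0.0] * umax for _ in range(n1 + 1)]
    for n in range(1, n2 + 1):
        new = [[0.0] * (umax + 1) for _ in range(n1 + 1)]
        new[0][0] = 1.0
        for m in range(1, n1 + 1):
            for u in range(umax + 1):
                acc = dp[m][u]                      # largest value is a y
                if u - n >= 0:
                    acc += new[m - 1][u - n]        # largest value is an x
                new[m][u] = acc
        dp = new
    return np.array(dp[n1])


def mann_whitney_u(x, y, method: str = "auto", alpha: float = DEFAULT_ALPHA,
                   continuity: bool = True,
                   names: tuple[str, str] = ("x", "y")) -> TestResult:
    """Mann-Whitney U test for two independent samples.

    U is the smaller of U_x and U_y computed on midranks. ``exact``
    enumerates the tie-free null distribution (admissible for n1, n2 <= 8
    without ties; with ties it falls back to the normal approximation
    with a note). ``normal`` uses the tie-corrected z with a 0.5
    continuity correction. ``auto`` picks exact when admissible.
    """
    (x, y), names = _as_groups([x, y], names)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    ux = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    uy = n1 * n2 - ux
    u = min(ux, uy)
    has_ties = np.unique(pooled).size < pooled.size

    note = ""
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    use_exact = (method == "exact") or (method == "auto" and n1 <= 8 and n2 <= 8)
    if use_exact and has_ties:
        note = "ties present: exact enumeration inadmissible, fell back to normal approximation"
        use_exact = False

    if use_exact:
        dist = _u_distribution(n1, n2)
        total = dist.sum()
        p = float(min(1.0, 2.0 * dist[: int(round(u)) + 1].sum() / total))
        return TestResult("mann_whitney_u_exact", float(u), p, comparison=tuple(names),
                          alpha=alpha, note=note)

    N = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((N + 1) - _tie_sum(pooled) / (N * (N - 1)))
    if var <= 0:
        return TestResult("mann_whitney_u_normal", float(u), 1.0, comparison=tuple(names),
                          alpha=alpha, note="degenerate: zero rank variance")
    diff = u - mu
    # continuity correction pulls |U - mu| in by 0.5 (u = min(ux, uy) <= mu)
    cc = (0.5 if continuity and diff != 0 else 0.0)
    z = (diff + cc) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.cdf(-abs(z))))
    note = (note + "; " if note else "") + f"z={z:.12g}"
    return TestResult("mann_whitney_u_normal", float(u), p, comparison=tuple(names),
                      alpha=alpha, note=note)


def welch_t(x, y, alpha: float = DEFAULT_ALPHA,
            names: tuple[str, str] = ("x", "y")) -> TestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    (x, y), names = _as_groups([x, y], names)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch's t needs at least 2 values per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("degenerate input: both samples have zero variance")
    se2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (vx**2 / (x.size**2 * (x.size - 1)) + vy**2 / (y.size**2 * (y.size - 1)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult("welch_t", float(t), p, df=float(df), comparison=tuple(names), alpha=alpha)


def normality_screen(values, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """D'Agostino K^2 omnibus normality screen.

    Returns a recommendation flag (``parametric`` when normality is not
    rejected at alpha, ``nonparametric`` otherwise). Fewer than 8 values
    yields an "insufficient n" result with no recommendation.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 8:
        return TestResult("dagostino_k2", float("nan"), None, alpha=alpha,
                          note=f"insufficient n ({v.size} < 8): no recommendation")
    k2, p = sps.normaltest(v)
    rec = "parametric" if p > alpha else "nonparametric"
    return TestResult("dagostino_k2", float(k2), float(p), df=2.0, alpha=alpha,
                      recommendation=rec)
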