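"""Group-comparison statistics and the differential-expression candidate filter.

The rank and t statistics here are computed from first principles (rank
sums, Welch–Satterthwaite, variance decomposition) rather than delegated,
so that each one can be checked in the test suite against independent
oracles: full permutation enumeration for the exact Mann–Whitney null
distribution, hand computations for t/F, and scipy as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "exact_u_sf",
    "t_tests",
    "anova_bonferroni",
    "filter_candidates",
]

#: exact Mann-Whitney p-values are enumerated when n_a * n_b is at most this
EXACT_U_LIMIT = 400


@dataclass
class TestResult:
    """Outcome of one two-sample (or one omnibus) comparison."""

    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str
    two_sided: bool = True
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("sample sizes must be >= 1")

    def to_dict(self) -> dict:
        d = {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "method": self.method,
            "two_sided": self.two_sided,
        }
        if self.extra:
            d.update(self.extra)
        return d


def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U as counts: counts[u] = number of the
    C(n1+n2, n1) rank arrangements of the 'a'-labels giving U = u.

    Standard recurrence on the largest pooled observation: if it belongs
    to sample a it exceeds all j b-observations (U gains j, one fewer a),
    otherwise one fewer b at the same U —
    f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u).
    """
    umax = n1 * n2
    base = np.zeros(umax + 1)
    base[0] = 1.0
    f_prev = [base] * (n2 + 1)          # i = 0: U is always 0
    for _i in range(1, n1 + 1):
        f_cur = [base]                  # j = 0: U is always 0
        for j in range(1, n2 + 1):
            arr = f_cur[j - 1].copy()
            arr[j:] += f_prev[j][: umax + 1 - j]
            f_cur.append(arr)
        f_prev = f_cur
    return f_prev[n2]


def exact_u_sf(u: float, n1: int, n2: int) -> tuple[float, float]:
    """(P(U <= u), P(U >= u)) under the exact tie-free null."""
    counts = _u_counts(n1, n2)
    total = counts.sum()
    lo = int(np.floor(u))
    hi = int(np.ceil(u))
    p_le = counts[: lo + 1].sum() / total
    p_ge = counts[hi:].sum() / total
    return float(p_le), float(p_ge)


def mann_whitney_u(sample_a, sample_b, two_sided: bool = True) -> TestResult:
    """Mann–Whitney U test with midranks for ties.

    The reported statistic is U for ``sample_a``.  The p-value is exact
    (full null enumeration via the count recurrence) whenever
    ``n_a * n_b <= 400`` and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction is used.
    Two-sided p is the doubled smaller tail, capped at 1.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if not has_ties and n1 * n2 <= EXACT_U_LIMIT:
        p_le, p_ge = exact_u_sf(u1, n1, n2)
        method = "mann-whitney-u-exact"
        if two_sided:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        else:
            p = p_ge
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = float(((tie_counts**3 - tie_counts)).sum())
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        method = "mann-whitney-u-normal"
        if var <= 0:
            p = 1.0
        else:
            # continuity correction: shrink the deviation by 1/2
            z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(var)
            if two_sided:
                p = min(1.0, 2.0 * norm.sf(abs(z)))
            else:
                p = float(norm.sf(z))
    return TestResult(float(u1), float(p), n1, n2, method, two_sided)


def _welch(a: np.ndarray, b: np.ndarray) -> TestResult:
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch test needs n >= 2 per sample")
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if m1 == m2:
            return TestResult(0.0, 1.0, n1, n2, "welch-t")
        raise ValueError("zero variance in both samples with unequal means")
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = min(1.0, 2.0 * float(t_dist.sf(abs(t), df)))
    return TestResult(float(t), p, n1, n2, "welch-t", extra={"df": float(df)})


def _paired(a: np.ndarray, b: np.ndarray) -> TestResult:
    if a.size != b.size:
        raise ValueError("paired test needs equal-length samples")
    if a.size < 2:
        raise ValueError("paired test needs n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        if d.mean() == 0:
            return TestResult(0.0, 1.0, n, n, "paired-t")
        raise ValueError("zero variance of differences with nonzero mean")
    t = d.mean() / (sd / np.sqrt(n))
    p = min(1.0, 2.0 * float(t_dist.sf(abs(t), n - 1)))
    return TestResult(float(t), p, n, n, "paired-t", extra={"df": float(n - 1)})


def t_tests(sample_a, sample_b, paired: bool = False) -> TestResult:
    """Two-tailed paired Student's t, or unpaired Welch t (unequal variance).

    Degenerate zero-variance inputs resolve to p = 1 when the means agree
    (no evidence of a difference) and raise otherwise, rather than
    emitting NaN.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    return _paired(a, b) if paired else _welch(a, b)


def anova_bonferroni(groups) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA F test plus Bonferroni-corrected pairwise t tests.

    Pairwise comparisons use the classic post hoc construction: ordinary
    two-sample t tests whose p-values are multiplied by the number of
    pairs and capped at 1.  Returns ``(omnibus, pairwise)`` where each
    pairwise result's ``extra`` records which groups were compared.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 3:
        raise ValueError("omnibus ANOVA needs >= 3 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        if ss_between == 0:
            omnibus = TestResult(0.0, 1.0, n_total, k, "one-way-anova")
        else:
            raise ValueError("zero within-group variance with unequal means")
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(f_dist.sf(f, df_b, df_w))
        omnibus = TestResult(float(f), p, n_total, k, "one-way-anova",
                             extra={"df_between": df_b, "df_within": df_w})

    n_pairs = k * (k - 1) // 2
    pairwise = []
    for i, j in combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        if v1 == 0 and v2 == 0 and a.mean() == b.mean():
            res = TestResult(0.0, 1.0, a.size, b.size, "t-bonferroni")
        else:
            sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (a.size + b.size - 2)
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
            raw = min(1.0, 2.0 * float(t_dist.sf(abs(t), a.size + b.size - 2)))
            res = TestResult(float(t), min(1.0, n_pairs * raw), a.size, b.size,
                             "t-bonferroni", extra={"raw_p": raw})
        res.extra = {**(res.extra or {}), "pair": (i, j)}
        pairwise.append(res)
    return omnibus, pairwise


def filter_candidates(
    table: pd.DataFrame,
    lfc_min: float = 0.5,
    p_max: float = 0.01,
    p_column: str = "p_value",
) -> pd.DataFrame:
    """Candidate-gene filter: |log2ratio| >= lfc_min and p <= p_max.

    Both bounds are inclusive.  ``p_column`` selects which p-value column
    the cut applies to (raw or adjusted), since published tables carry
    both.  Row order is preserved.
    """
    if table.empty:
        return table.copy()
    if "log2ratio" not in table.columns or p_column not in table.columns:
        raise KeyError("table needs 'log2ratio' and p-value columns")
    keep = (table["log2ratio"].abs() >= lfc_min) & (table[p_column] <= p_max)
    return table.loc[keep].copy()


def mann_whitney_permutation_p(sample_a, sample_b) -> float:
    """Brute-force two-sided Mann–Whitney p by enumerating every assignment
    of the pooled values into groups.  Oracle for small tie-free samples;
    O(C(n_a+n_b, n_a)) — keep n small."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = a.size
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = []
    for idx in combinations(range(pooled.size), n1):
        r = ranks[list(idx)].sum()
        us.append(r - n1 * (n1 + 1) / 2.0)
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))
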