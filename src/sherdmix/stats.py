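"""Group-contrast statistics implemented from first principles.

Mann–Whitney U uses midranks, a tie-corrected normal approximation with
continuity correction, and the exact null distribution (via the standard
counting recurrence) for small untied samples. Pearson's r uses the t
transform with df = n − 2. The two-sample t test is Welch by default
with a pooled-variance option.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    statistic_name: str  # "U", "r" or "t"
    n1: int
    n2: int | None
    df: float | None
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # average of ranks i+1..j+1
        i = j + 1
    return ranks


@lru_cache(maxsize=None)
def _u_count_table(n1: int, n2: int) -> tuple[int, ...]:
    """Number of orderings with U = u, u = 0..n1*n2 (no ties).

    Counting recurrence N(u; n1, n2) = N(u - n2; n1-1, n2) + N(u; n1, n2-1).
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    left = _u_count_table(n1 - 1, n2)
    right = _u_count_table(n1, n2 - 1)
    out = []
    for u in range(n1 * n2 + 1):
        total = 0
        if 0 <= u - n2 < len(left):
            total += left[u - n2]
        if u < len(right):
            total += right[u]
        out.append(total)
    return tuple(out)


def mann_whitney_u(x, y, report: str = "min") -> TestResult:
    """Mann–Whitney U with midranks; exact p for small untied samples.

    ``report`` selects the reported statistic: "min" (default) gives
    min(U_x, U_y); "x" gives U of the first sample. The two-sided p-value
    is exact (counting recurrence) when n1·n2 ≤ 400 and there are no
    ties, otherwise a tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    u_x = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u_y = n1 * n2 - u_x
    u_min = min(u_x, u_y)
    statistic = u_min if report == "min" else u_x

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if not has_ties and n1 * n2 <= 400:
        counts = np.array(_u_count_table(n1, n2), dtype=float)
        pmf = counts / counts.sum()
        # two-sided: double the lower tail of the symmetric null at U_min
        p = min(1.0, 2.0 * float(pmf[: int(round(u_min)) + 1].sum()))
        method = "exact"
    else:
        N = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
        if var <= 0:  # all observations identical
            p = 1.0
        else:
            z = (u_min - mu + 0.5) / np.sqrt(var)  # continuity-corrected lower tail
            p = min(1.0, 2.0 * float(sps.norm.cdf(z)))
        method = "normal approximation, tie-corrected, continuity-corrected"
    return TestResult(statistic, "U", n1, n2, None, p, method)


def pearson_r(x, y) -> TestResult:
    """Product-moment correlation; pairs with any absent value are dropped.

    df = n − 2 and the two-sided p-value comes from the t transform
    t = r·sqrt(df / (1 − r²)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero variance in one of the variables; r undefined")
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(r, "r", n, None, float(df), min(1.0, p), "t transform")


_T_CAP = 1e15  # overflow-safe stand-in for a zero-noise mean shift


def two_sample_t(x, y, equal_variance: bool = False) -> TestResult:
    """Two-sample t test: Welch by default, pooled variance on request."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per group")
    m1, m2 = x.mean(), y.mean()
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if m1 == m2:
            raise ValueError("zero variance in both groups and equal means: t undefined")
        t = _T_CAP if m1 > m2 else -_T_CAP
        df = float(n1 + n2 - 2)
        return TestResult(t, "t", n1, n2, df, 0.0, "degenerate zero-variance shift")
    if equal_variance:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
        method = "pooled variance"
    else:
        a, b = v1 / n1, v2 / n2
        se = np.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        method = "Welch"
    if se == 0.0:
        t = _T_CAP if m1 > m2 else -_T_CAP
        p = 0.0
    else:
        t = float((m1 - m2) / se)
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(t, "t", n1, n2, float(df), min(1.0, p), method)
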