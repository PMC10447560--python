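"""Two-sample comparison battery for demographic tables.

Continuous variables are compared with a two-sided Mann–Whitney U test
(rank-based; appropriate for the skewed age/education/MMSE distributions of
a kindred sample); the sex split is compared with a Pearson chi-square test
on the 2x2 contingency table. p-values are reported unadjusted.

Conventions
-----------
* U is computed from midranks, so ties are allowed.
* For small tie-free samples (n1 + n2 ≤ 12) the two-sided p-value is exact,
  by full enumeration of all C(N, n1) rank assignments.
* Otherwise a normal approximation is used with the tie-corrected variance
  and a continuity correction of 1/2 applied to |U − n1*n2/2| (floored at
  zero, so identical samples give p = 1 exactly).
* Chi-square uses no Yates correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    tie_count: int | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def _exact_two_sided_p(ranks_x_sum: float, n1: int, n2: int) -> float:
    """Exact two-sided p by enumerating every assignment of ranks to group 1.

    Valid only for tie-free data (ranks are the integers 1..N). Two-sided
    p is the probability, under the permutation null, of a U at least as far
    from its mean n1*n2/2 as the one observed.
    """
    n = n1 + n2
    mu = n1 * n2 / 2.0
    u_obs = ranks_x_sum - n1 * (n1 + 1) / 2.0
    dev = abs(u_obs - mu)
    count = 0
    for picks in combinations(range(1, n + 1), n1):
        u = sum(picks) - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= dev - 1e-12:
            count += 1
    return count / comb(n, n1)


def mann_whitney_u(x, y, method: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U test (midrank method).

    Returns U for the first sample. ``tie_count`` is the number of
    observations belonging to tied groups in the pooled sample.
    ``method`` is "auto" (exact for tie-free pooled samples of ≤ 12,
    normal approximation otherwise), "exact" or "normal".
    """
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires two non-empty samples")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    _, tie_sizes = np.unique(pooled, return_counts=True)
    tied = tie_sizes[tie_sizes > 1]
    tie_count = int(tied.sum())

    use_exact = method == "exact" or (method == "auto" and n <= 12 and tie_count == 0)
    if use_exact:
        if tie_count:
            raise ValueError("exact enumeration requires a tie-free pooled sample")
        p = _exact_two_sided_p(r1, n1, n2)
        used = "exact"
    else:
        tie_term = float((tied**3 - tied).sum()) if tied.size else 0.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            # every pooled value identical: the test carries no information
            p = 1.0
        else:
            z = max(abs(u1 - mu) - 0.5, 0.0) / np.sqrt(var)
            p = min(1.0, 2.0 * float(sps.norm.sf(z)))
        used = "normal-approx"
    return TestResult(
        name="Mann-Whitney U",
        statistic=float(u1),
        p_value=float(p),
        n1=n1,
        n2=n2,
        tie_count=tie_count,
        method=used,
    )


def chi_square(table) -> TestResult:
    """Pearson chi-square test of independence on a contingency table.

    X² = Σ (O−E)²/E with expected counts from the row/column margins;
    no Yates continuity correction. All expected counts must be positive.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("chi_square expects a 2-D contingency table with ≥2 rows and columns")
    if (obs < 0).any():
        raise ValueError("contingency counts must be non-negative")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total if total else obs * np.nan
    if total == 0 or (expected <= 0).any():
        raise ValueError("chi_square requires every expected count to be positive")
    x2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(x2, df))
    return TestResult(
        name="Pearson chi-square",
        statistic=x2,
        p_value=p,
        n1=int(obs.sum(axis=1)[0]),
        n2=int(obs.sum(axis=1)[1]),
        method=f"chi2 df={df}",
    )
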