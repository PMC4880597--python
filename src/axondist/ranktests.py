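"""Friedman omnibus test and Nemenyi post-hoc comparison on rank matrices.

Input is a blocks x treatments matrix of ranks — here, datasets (regions or
specimens) as blocks and distribution families as treatments, each row the
within-dataset ranking of the families.  The Friedman chi-square statistic

    chi2_F = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)

(with the standard midrank tie correction when rows contain tied ranks) is
referred to a chi-square distribution with k-1 degrees of freedom.  The
Nemenyi post-hoc test flags a pair of treatments as significantly different
when their mean ranks differ by more than the critical difference

    CD = q_alpha(k) * sqrt(k (k+1) / (6 n)),

where q_alpha(k) is the Studentized-range quantile at infinite degrees of
freedom divided by sqrt(2); a frozen table covers k = 2..20 at
alpha in {0.01, 0.05, 0.10}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RankMatrix:
    """Blocks (datasets) by treatments (families) matrix of within-block ranks."""

    ranks: np.ndarray
    blocks: tuple[str, ...]
    treatments: tuple[str, ...]

    def __post_init__(self):
        r = np.asarray(self.ranks, dtype=float)
        if r.ndim != 2:
            raise ValueError("ranks must be a 2-d matrix")
        nb, nt = r.shape
        if nb != len(self.blocks) or nt != len(self.treatments):
            raise ValueError("label lengths must match matrix shape")
        object.__setattr__(self, "ranks", r)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RankMatrix":
        """Rows = blocks, columns = treatments."""
        return cls(
            df.to_numpy(dtype=float),
            tuple(str(i) for i in df.index),
            tuple(str(c) for c in df.columns),
        )

    @property
    def n_blocks(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_treatments(self) -> int:
        return self.ranks.shape[1]


def friedman_test(m: RankMatrix) -> dict[str, float]:
    """Friedman chi-square test on a rank matrix, with midrank tie correction."""
    n, k = m.n_blocks, m.n_treatments
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    col_sums = m.ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)

    # tie correction: C = 1 - sum over blocks of sum(t^3 - t) / (n k (k^2-1))
    tie_term = 0.0
    for row in m.ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n * k * (k**2 - 1))
    if denom <= 0.0:
        # every row fully tied: no information, statistic 0
        return {"statistic": 0.0, "df": float(k - 1), "p_value": 1.0}
    stat /= denom

    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return {"statistic": float(stat), "df": float(df), "p_value": p}


# q_alpha(k) = studentized-range quantile (inf df) / sqrt(2), k = 2..20
_NEMENYI_Q = {
    0.01: (2.5758, 2.9135, 3.1133, 3.2547, 3.3637, 3.4522, 3.5265, 3.5903,
           3.6463, 3.6960, 3.7407, 3.7813, 3.8185, 3.8527, 3.8843, 3.9138,
           3.9414, 3.9674, 3.9918),
    0.05: (1.9600, 2.3437, 2.5690, 2.7278, 2.8497, 2.9483, 3.0309, 3.1017,
           3.1637, 3.2187, 3.2680, 3.3127, 3.3536, 3.3912, 3.4260, 3.4584,
           3.4887, 3.5171, 3.5438),
    0.10: (1.6449, 2.0523, 2.2913, 2.4595, 2.5885, 2.6927, 2.7799, 2.8546,
           2.9199, 2.9778, 3.0297, 3.0767, 3.1197, 3.1592, 3.1957, 3.2297,
           3.2615, 3.2912, 3.3192),
}


def nemenyi_critical_difference(k: int, n: int, alpha: float = 0.05) -> float:
    """Critical mean-rank difference for the Nemenyi test."""
    if alpha not in _NEMENYI_Q:
        raise ValueError(f"alpha must be one of {sorted(_NEMENYI_Q)}, got {alpha}")
    if not 2 <= k <= 20:
        raise ValueError("tabulated q values cover 2 <= k <= 20")
    q = _NEMENYI_Q[alpha][k - 2]
    return q * np.sqrt(k * (k + 1) / (6.0 * n))


def nemenyi_posthoc(m: RankMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise mean-rank comparisons after a Friedman test.

    Returns one row per unordered treatment pair with the absolute mean-rank
    difference, the critical difference at ``alpha`` and a significance flag.
    """
    n, k = m.n_blocks, m.n_treatments
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    cd = nemenyi_critical_difference(k, n, alpha)
    mean_ranks = m.ranks.mean(axis=0)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(mean_ranks[i] - mean_ranks[j])
            rows.append(
                {
                    "treatment_a": m.treatments[i],
                    "treatment_b": m.treatments[j],
                    "mean_rank_diff": diff,
                    "critical_difference": cd,
                    "significant": bool(diff > cd),
                }
            )
    return pd.DataFrame(rows)
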