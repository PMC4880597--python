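"""Information-criterion scoring and ranking of fitted families.

The primary criterion is the finite-sample-corrected Akaike information
criterion

    AICc = 2k - 2 ln L + 2k(k+1) / (n - k - 1),

with k estimated parameters and n observations; lower is better.  BIC
(k ln n - 2 ln L) and the negative log-likelihood are reported alongside.
Ties in AICc are broken by parsimony (smaller k) then family name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import FAMILY_NAMES, get_family
from .fitting import DiameterSample, FitOptions, FitResult, fit_mle


class SmallSampleError(ValueError):
    """AICc requires n > k + 1."""


def aicc(loglik: float, k: int, n: int) -> float:
    """Finite-sample-corrected AIC; requires n > k + 1."""
    if n <= k + 1:
        raise SmallSampleError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return 2.0 * k - 2.0 * loglik + 2.0 * k * (k + 1) / (n - k - 1)


def bic(loglik: float, k: int, n: int) -> float:
    if n < 1:
        raise ValueError("n must be >= 1")
    return k * math.log(n) - 2.0 * loglik


@dataclass(frozen=True)
class SelectionRow:
    family: str
    k: int
    loglik: float
    aicc: float
    bic: float
    nll: float
    rank: int


@dataclass(frozen=True)
class SelectionTable:
    """Per-family scores and ranks for one sample (rows ordered by rank)."""

    sample_label: str
    rows: tuple[SelectionRow, ...]
    excluded: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family": r.family,
                    "rank": r.rank,
                    "k": r.k,
                    "aicc": r.aicc,
                    "bic": r.bic,
                    "nll": r.nll,
                    "loglik": r.loglik,
                }
                for r in self.rows
            ]
        )

    def rank_of(self, family: str) -> int:
        for r in self.rows:
            if r.family == family:
                return r.rank
        raise KeyError(family)

    @property
    def best(self) -> SelectionRow:
        return self.rows[0]


def score_fits(fits: list[FitResult], sample_label: str = "") -> SelectionTable:
    """Rank a list of fits by AICc; non-converged fits go to ``excluded``."""
    scored = []
    excluded = []
    for f in fits:
        if not f.converged or not np.isfinite(f.loglik):
            excluded.append((f.family, f.message or "did not converge"))
            continue
        k = get_family(f.family).n_params
        scored.append(
            (
                aicc(f.loglik, k, f.n),
                k,
                f.family,
                bic(f.loglik, k, f.n),
                -f.loglik,
                f.loglik,
            )
        )
    if not scored:
        raise ValueError(f"no family converged for sample {sample_label!r}")
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    rows = tuple(
        SelectionRow(family=fam, k=k, loglik=ll, aicc=a, bic=b, nll=nll, rank=i + 1)
        for i, (a, k, fam, b, nll, ll) in enumerate(scored)
    )
    return SelectionTable(sample_label, rows, tuple(excluded))


def fit_and_rank(
    sample: DiameterSample,
    families: tuple[str, ...] = FAMILY_NAMES,
    options: FitOptions | None = None,
) -> SelectionTable:
    """Fit every requested family and rank the converged fits by AICc."""
    if len(families) < 2:
        raise ValueError("need at least two candidate families to rank")
    fits = [fit_mle(sample, name, options) for name in families]
    label = f"{sample.specimen}/{sample.region}"
    return score_fits(fits, label)
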