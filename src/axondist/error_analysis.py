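"""Empirical summaries and fit-quality profiling.

Beyond the information criteria, fits are compared against the data itself:
summary statistics of the measured diameters, histogram/density overlays,
and the signed difference between each fitted model's CDF and the empirical
CDF across the diameter range.  The error sign convention is model minus
empirical: positive values mean the model over-estimates cumulative mass
below that diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .families import get_family
from .fitting import DiameterSample, FitResult


@dataclass(frozen=True)
class EcdfCurve:
    """Right-continuous empirical CDF (tied values collapsed)."""

    sorted_values: np.ndarray
    probabilities: np.ndarray

    def __call__(self, x) -> np.ndarray:
        """Fraction of observations <= x."""
        idx = np.searchsorted(self.sorted_values, np.asarray(x, dtype=float), side="right")
        probs = np.concatenate([[0.0], self.probabilities])
        return probs[idx]


@dataclass(frozen=True)
class ErrorProfile:
    """Model CDF minus empirical CDF over a diameter grid, for one family."""

    family: str
    grid: np.ndarray
    errors: np.ndarray

    @property
    def max_abs_error(self) -> float:
        return float(np.max(np.abs(self.errors)))


def summary_stats(sample: DiameterSample) -> dict[str, float]:
    """n, mean, SD (n-1 denominator), min, max, median — all in micrometres."""
    x = sample.values
    if x.size == 0:
        raise ValueError("empty sample")
    return {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "median": float(np.median(x)),
    }


def ecdf(sample: DiameterSample) -> EcdfCurve:
    vals, counts = np.unique(sample.values, return_counts=True)
    probs = np.cumsum(counts) / sample.n
    return EcdfCurve(vals, probs)


def cdf_error_profile(
    fit: FitResult, sample: DiameterSample, grid_size: int = 200
) -> ErrorProfile:
    """Signed CDF error on an even grid spanning the observed diameter range."""
    if not fit.converged:
        raise ValueError(f"fit of {fit.family} did not converge")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    fam = get_family(fit.family)
    grid = np.linspace(np.min(sample.values), np.max(sample.values), grid_size)
    emp = ecdf(sample)(grid)
    model = fam.cdf(fit.params, grid)
    return ErrorProfile(fit.family, grid, model - emp)


def density_overlay(
    fits: list[FitResult], sample: DiameterSample, n_bins: int = 100
) -> pd.DataFrame:
    """Histogram density of the data with each fitted density at bin centers."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    bad = [f.family for f in fits if not f.converged]
    if bad:
        raise ValueError(f"non-converged fits: {bad}")
    dens, edges = np.histogram(sample.values, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = pd.DataFrame({"bin_center": centers, "empirical_density": dens})
    for f in fits:
        out[f.family] = get_family(f.family).pdf(f.params, centers)
    return out
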