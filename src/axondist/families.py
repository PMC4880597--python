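"""The sixteen parametric distribution families compared for axon diameters.

Each family is exposed under the parameterization conventional in the axon
morphometry literature (e.g. gamma is shape-scale, log-normal parameters live
on the log scale, the generalized extreme value family is (location mu,
scale sigma, shape xi)).  The numerical back end is :mod:`scipy.stats`; this
module pins down names, parameter order, constraints and support so that the
fitting and model-selection layers can treat every family uniformly.

Conventions worth knowing:

* ``exponential`` takes the *rate* lambda (density ``lambda * exp(-lambda x)``).
* ``extreme_value`` is the minimum-type (left-skewed) Gumbel distribution,
  distinct from the generalized extreme value family.
* scipy's ``genextreme`` uses the opposite sign for the shape parameter; the
  conversion is handled here, callers always see the (mu, sigma, xi)
  convention in which xi > 0 gives a heavy right tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np
from scipy import stats


class ParameterError(ValueError):
    """Raised when a parameter vector violates a family's constraints."""


@dataclass(frozen=True)
class Family:
    """A named distribution family with a uniform numeric interface.

    Parameters are plain 1-d float arrays ordered as ``param_names``.
    All evaluation methods validate the parameter vector and raise
    :class:`ParameterError` on an infeasible one.
    """

    name: str
    param_names: tuple[str, ...]
    _frozen: Callable[[np.ndarray], "stats.distributions.rv_frozen"] = field(repr=False)
    _feasible: Callable[[np.ndarray], bool] = field(repr=False)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- parameter handling -------------------------------------------------

    def validate(self, params) -> np.ndarray:
        p = np.asarray(params, dtype=float).ravel()
        if p.size != self.n_params:
            raise ParameterError(
                f"{self.name} expects {self.n_params} parameters "
                f"{self.param_names}, got {p.size}"
            )
        if not np.all(np.isfinite(p)) or not self._feasible(p):
            raise ParameterError(f"infeasible parameters for {self.name}: {p.tolist()}")
        return p

    def is_feasible(self, params) -> bool:
        p = np.asarray(params, dtype=float).ravel()
        return (
            p.size == self.n_params
            and bool(np.all(np.isfinite(p)))
            and bool(self._feasible(p))
        )

    def frozen(self, params):
        """Return the scipy frozen distribution for a validated parameter vector."""
        return self._frozen(self.validate(params))

    # -- uniform numeric surface -------------------------------------------

    def pdf(self, params, x):
        return self.frozen(params).pdf(x)

    def logpdf(self, params, x):
        return self.frozen(params).logpdf(x)

    def cdf(self, params, x):
        return self.frozen(params).cdf(x)

    def quantile(self, params, p):
        p_arr = np.asarray(p, dtype=float)
        if np.any((p_arr <= 0.0) | (p_arr >= 1.0)):
            raise ValueError("quantile probabilities must lie strictly in (0, 1)")
        return self.frozen(params).ppf(p)

    def sample(self, params, n: int, seed: int) -> np.ndarray:
        if n < 1:
            raise ValueError("sample size must be >= 1")
        rng = np.random.default_rng(seed)
        return np.atleast_1d(self.frozen(params).rvs(size=n, random_state=rng))

    def support(self, params) -> tuple[float, float]:
        """Return (lower, upper) bounds of the support for these parameters."""
        lo, hi = self.frozen(params).support()
        return float(lo), float(hi)


def _positive(*idx: int) -> Callable[[np.ndarray], bool]:
    def check(p: np.ndarray) -> bool:
        return bool(np.all(p[list(idx)] > 0.0))

    return check


def _t_feasible(p: np.ndarray) -> bool:
    nu, sigma, _mu = p
    return nu > 0.0 and sigma > 0.0


def _nakagami_feasible(p: np.ndarray) -> bool:
    m, omega = p
    return m >= 0.5 and omega > 0.0


def _rician_feasible(p: np.ndarray) -> bool:
    nu, sigma = p
    return nu >= 0.0 and sigma > 0.0


_REGISTRY: dict[str, Family] = {}


def _register(name, param_names, frozen, feasible) -> None:
    _REGISTRY[name] = Family(name, tuple(param_names), frozen, feasible)


# Parameter order follows the field's usual symbol order for each family.
_register(
    "birnbaum_saunders",
    ("beta", "gamma"),  # scale beta, shape gamma
    lambda p: stats.fatiguelife(p[1], loc=0.0, scale=p[0]),
    _positive(0, 1),
)
_register(
    "exponential",
    ("lambda",),  # rate
    lambda p: stats.expon(scale=1.0 / p[0]),
    _positive(0),
)
_register(
    # Minimum-type Gumbel: models minima, left-skewed.
    "extreme_value",
    ("mu", "sigma"),
    lambda p: stats.gumbel_l(loc=p[0], scale=p[1]),
    _positive(1),
)
_register(
    "gamma",
    ("k", "theta"),  # shape, scale
    lambda p: stats.gamma(p[0], scale=p[1]),
    _positive(0, 1),
)
_register(
    # scipy genextreme shape c = -xi
    "generalized_extreme_value",
    ("mu", "sigma", "xi"),
    lambda p: stats.genextreme(-p[2], loc=p[0], scale=p[1]),
    _positive(1),
)
_register(
    "generalized_pareto",
    ("xi", "mu", "sigma"),  # shape, threshold, scale
    lambda p: stats.genpareto(p[0], loc=p[1], scale=p[2]),
    _positive(2),
)
_register(
    # classical IG(mean mu, shape lambda); scipy's mu argument is mean/scale
    "inverse_gaussian",
    ("mu", "lambda"),
    lambda p: stats.invgauss(p[0] / p[1], scale=p[1]),
    _positive(0, 1),
)
_register(
    "log_logistic",
    ("alpha", "beta"),  # scale (median), shape
    lambda p: stats.fisk(p[1], scale=p[0]),
    _positive(0, 1),
)
_register(
    "log_normal",
    ("mu", "sigma"),  # log-scale location and spread
    lambda p: stats.lognorm(p[1], scale=np.exp(p[0])),
    lambda p: p[1] > 0.0,
)
_register(
    "logistic",
    ("mu", "s"),
    lambda p: stats.logistic(loc=p[0], scale=p[1]),
    _positive(1),
)
_register(
    "nakagami",
    ("m", "omega"),  # shape m >= 1/2, spread Omega = E[X^2]
    lambda p: stats.nakagami(p[0], scale=np.sqrt(p[1])),
    _nakagami_feasible,
)
_register(
    "normal",
    ("mu", "sigma"),
    lambda p: stats.norm(loc=p[0], scale=p[1]),
    lambda p: p[1] > 0.0,
)
_register(
    "rayleigh",
    ("sigma",),
    lambda p: stats.rayleigh(scale=p[0]),
    _positive(0),
)
_register(
    "rician",
    ("nu", "sigma"),  # noncentrality nu >= 0, scale sigma
    lambda p: stats.rice(p[0] / p[1], scale=p[1]),
    _rician_feasible,
)
_register(
    "t_location_scale",
    ("nu", "sigma", "mu"),  # degrees of freedom, scale, location
    lambda p: stats.t(p[0], loc=p[2], scale=p[1]),
    _t_feasible,
)
_register(
    "weibull",
    ("lambda", "k"),  # scale, shape
    lambda p: stats.weibull_min(p[1], scale=p[0]),
    _positive(0, 1),
)


FAMILY_NAMES: tuple[str, ...] = tuple(_REGISTRY)
assert len(FAMILY_NAMES) == 16


def get_family(name: str) -> Family:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown family {name!r}; available: {', '.join(FAMILY_NAMES)}"
        ) from None


def iter_families() -> Iterator[Family]:
    return iter(_REGISTRY.values())
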