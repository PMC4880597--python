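"""Maximum-likelihood fitting of diameter samples.

Every family is fitted by direct maximization of the log-likelihood.  Four
families (normal, log-normal, exponential, Rayleigh) have closed-form MLEs
and are solved exactly; the rest are maximized numerically with Nelder-Mead
on a constraint-transformed parameter space (positive parameters are
log-transformed, the generalized-Pareto threshold is kept below the sample
minimum, the t degrees of freedom are bounded to [0.5, 1000]).  Method-of-
moments starting values plus seeded multiplicative jitter restarts guard
against the multimodal likelihoods of the shape families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .families import Family, ParameterError, get_family

_EULER = 0.57721566490153286


class DegenerateSampleError(ValueError):
    """Raised for samples that cannot support distribution fitting."""


@dataclass(frozen=True)
class DiameterSample:
    """A vector of axon diameters (micrometres) from one specimen/region."""

    values: np.ndarray
    region: str = "whole"
    specimen: str = "unknown"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 2:
            raise DegenerateSampleError("need at least 2 diameter measurements")
        if not np.all(np.isfinite(v)) or np.any(v <= 0.0):
            raise ValueError("diameters must be strictly positive and finite")
        if np.ptp(v) == 0.0:
            raise DegenerateSampleError("constant-valued sample cannot be fitted")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one family to one sample."""

    family: str
    params: np.ndarray
    loglik: float
    n: int
    converged: bool
    n_restarts_used: int = 0
    message: str = ""


@dataclass(frozen=True)
class FitOptions:
    tol: float = 1e-8
    max_iter: int = 500
    n_restarts: int = 5
    seed: int = 0


def loglik(sample: DiameterSample, family: Family | str, params) -> float:
    """Sum of log-densities; -inf if any observation falls outside the support."""
    fam = get_family(family) if isinstance(family, str) else family
    ll = fam.logpdf(params, sample.values)
    total = float(np.sum(ll))
    return total if np.isfinite(total) else -math.inf


# ---------------------------------------------------------------------------
# Method-of-moments starting values


def moment_init(sample: DiameterSample, family: Family | str) -> np.ndarray:
    """Feasible per-family starting point derived from sample moments."""
    fam = get_family(family) if isinstance(family, str) else family
    x = sample.values
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1))
    if s == 0.0:
        raise DegenerateSampleError("zero-variance sample")
    logx = np.log(x)
    mlog = float(np.mean(logx))
    slog = float(np.std(logx, ddof=1))
    m2 = float(np.mean(x**2))

    name = fam.name
    if name == "birnbaum_saunders":
        # median ~= beta; for small shape, sd/mean ~= gamma
        init = [float(np.median(x)), max(s / m, 1e-3)]
    elif name == "exponential":
        init = [1.0 / m]
    elif name == "extreme_value":
        sigma = s * math.sqrt(6.0) / math.pi
        init = [m + _EULER * sigma, sigma]
    elif name == "gamma":
        init = [(m / s) ** 2, s**2 / m]
    elif name == "generalized_extreme_value":
        # Gumbel-type moment start with a mildly heavy-tailed shape
        sigma = s * math.sqrt(6.0) / math.pi
        init = [m - _EULER * sigma, sigma, 0.1]
    elif name == "generalized_pareto":
        mu0 = float(np.min(x)) - 1e-6
        y, sy = m - mu0, s
        xi0 = float(np.clip(0.5 * (1.0 - y**2 / sy**2), -0.4, 0.9))
        # a negative shape bounds the support above; keep all data feasible
        if xi0 < 0.0 and float(np.max(x)) >= mu0 - y * (1.0 - xi0) / xi0:
            xi0 = 0.1
        init = [xi0, mu0, max(y * (1.0 - xi0), 1e-8)]
    elif name == "inverse_gaussian":
        init = [m, m**3 / s**2]
    elif name == "log_logistic":
        beta0 = math.pi / (math.sqrt(3.0) * max(slog, 1e-6))
        init = [math.exp(mlog), beta0]
    elif name == "log_normal":
        init = [mlog, max(slog, 1e-6)]
    elif name == "logistic":
        init = [m, s * math.sqrt(3.0) / math.pi]
    elif name == "nakagami":
        v2 = float(np.var(x**2, ddof=1))
        m0 = m2**2 / v2 if v2 > 0 else 1.0
        init = [max(m0, 0.5), m2]
    elif name == "normal":
        init = [m, s]
    elif name == "rayleigh":
        init = [math.sqrt(m2 / 2.0)]
    elif name == "rician":
        nu0 = math.sqrt(max(m**2 - s**2, 1e-8))
        init = [nu0, max(s, 1e-6)]
    elif name == "t_location_scale":
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        init = [10.0, max(iqr / 1.349, 1e-6), float(np.median(x))]
    elif name == "weibull":
        k0 = math.pi / (math.sqrt(6.0) * max(slog, 1e-6))
        init = [math.exp(mlog + _EULER / k0), k0]
    else:  # pragma: no cover
        raise KeyError(name)
    p0 = np.asarray(init, dtype=float)
    if not fam.is_feasible(p0):
        raise ParameterError(f"moment init infeasible for {name}: {p0}")
    return p0


# ---------------------------------------------------------------------------
# Parameter transforms: optimizer works on an unconstrained space u.

_BOUNDED_NU = (0.5, 1000.0)  # t location-scale degrees of freedom


def _transforms(fam: Family, x_min: float):
    """Return (to_u, to_params) mapping between constrained and free space."""
    name = fam.name

    if name == "generalized_pareto":
        # params (xi, mu, sigma); mu constrained below the sample minimum
        def to_u(p):
            return np.array([p[0], math.log(max(x_min - p[1], 1e-12)), math.log(p[2])])

        def to_p(u):
            return np.array([u[0], x_min - math.exp(u[1]), math.exp(u[2])])

        return to_u, to_p

    if name == "t_location_scale":
        lo, hi = _BOUNDED_NU

        def to_u(p):
            z = (p[0] - lo) / (hi - lo)
            z = min(max(z, 1e-12), 1 - 1e-12)
            return np.array([math.log(z / (1 - z)), math.log(p[1]), p[2]])

        def to_p(u):
            z = 1.0 / (1.0 + math.exp(-u[0]))
            return np.array([lo + (hi - lo) * z, math.exp(u[1]), u[2]])

        return to_u, to_p

    if name == "nakagami":

        def to_u(p):
            return np.array([math.log(max(p[0] - 0.5, 1e-12)), math.log(p[1])])

        def to_p(u):
            return np.array([0.5 + math.exp(u[0]), math.exp(u[1])])

        return to_u, to_p

    if name == "rician":
        # nu >= 0 via softplus-ish log1p(exp) would lose nu=0; plain log with floor
        def to_u(p):
            return np.array([math.log(max(p[0], 1e-10)), math.log(p[1])])

        def to_p(u):
            return np.array([math.exp(u[0]), math.exp(u[1])])

        return to_u, to_p

    # generic: log-transform positive-only parameters, identity for locations
    free = {
        "extreme_value": (0,),
        "generalized_extreme_value": (0, 2),
        "logistic": (0,),
        "log_normal": (0,),
        "normal": (0,),
    }.get(name, ())

    def to_u(p):
        u = np.array(p, dtype=float)
        for i in range(u.size):
            if i not in free:
                u[i] = math.log(u[i])
        return u

    def to_p(u):
        p = np.array(u, dtype=float)
        for i in range(p.size):
            if i not in free:
                p[i] = math.exp(p[i])
        return p

    return to_u, to_p


# ---------------------------------------------------------------------------
# Closed-form MLEs

_CLOSED_FORM = {"normal", "log_normal", "exponential", "rayleigh"}


def _closed_form_mle(sample: DiameterSample, name: str) -> np.ndarray:
    x = sample.values
    if name == "normal":
        return np.array([np.mean(x), np.std(x)])  # MLE sigma: n denominator
    if name == "log_normal":
        lx = np.log(x)
        return np.array([np.mean(lx), np.std(lx)])
    if name == "exponential":
        return np.array([1.0 / np.mean(x)])
    if name == "rayleigh":
        return np.array([math.sqrt(np.mean(x**2) / 2.0)])
    raise KeyError(name)  # pragma: no cover


def fit_mle(
    sample: DiameterSample,
    family: Family | str,
    options: FitOptions | None = None,
    method: str = "auto",
) -> FitResult:
    """Fit one family by maximum likelihood.

    ``method`` is "auto" (closed form where available, numerical otherwise),
    "closed_form" or "numeric"; forcing "numeric" on a closed-form family is
    mainly useful for cross-checking the optimizer.

    Never raises on optimizer failure: a fit that fails every restart is
    returned with ``converged=False`` so that ranking can proceed per family.
    """
    if method not in ("auto", "closed_form", "numeric"):
        raise ValueError(f"unknown method {method!r}")
    fam = get_family(family) if isinstance(family, str) else family
    opts = options or FitOptions()
    n = sample.n

    if method == "closed_form" and fam.name not in _CLOSED_FORM:
        raise ValueError(f"{fam.name} has no closed-form MLE")
    if fam.name in _CLOSED_FORM and method != "numeric":
        p_hat = _closed_form_mle(sample, fam.name)
        return FitResult(
            family=fam.name,
            params=p_hat,
            loglik=loglik(sample, fam, p_hat),
            n=n,
            converged=True,
            n_restarts_used=0,
            message="closed-form MLE",
        )

    try:
        p0 = moment_init(sample, fam)
    except (ParameterError, DegenerateSampleError) as exc:
        return FitResult(fam.name, np.full(fam.n_params, np.nan), -math.inf, n,
                         False, 0, f"initialization failed: {exc}")

    to_u, to_p = _transforms(fam, float(np.min(sample.values)))
    x = sample.values

    def neg_mean_ll(u: np.ndarray) -> float:
        p = to_p(u)
        if not fam.is_feasible(p):
            return 1e10
        with np.errstate(all="ignore"):
            ll = fam.logpdf(p, x)
        total = np.sum(ll)
        if not np.isfinite(total):
            return 1e10
        return -float(total) / x.size

    u0 = to_u(p0)
    best_p, best_ll = p0, loglik(sample, fam, p0)
    rng = np.random.default_rng(opts.seed)
    any_success = False
    restarts_used = 0

    for r in range(max(opts.n_restarts, 1)):
        u_start = u0 if r == 0 else u0 + rng.normal(0.0, 0.3, size=u0.size)
        res = optimize.minimize(
            neg_mean_ll,
            u_start,
            method="Nelder-Mead",
            options={
                "maxiter": opts.max_iter * u0.size,
                "xatol": opts.tol,
                "fatol": opts.tol,
            },
        )
        restarts_used = r + 1
        cand = to_p(res.x)
        if fam.is_feasible(cand):
            ll = loglik(sample, fam, cand)
            if ll > best_ll:
                best_p, best_ll = cand, ll
            if res.success and np.isfinite(ll):
                any_success = True

    converged = any_success and np.isfinite(best_ll)
    msg = "ok" if converged else "optimizer failed all restarts"
    if fam.name == "t_location_scale" and converged:
        lo, hi = _BOUNDED_NU
        if best_p[0] >= hi * 0.999 or best_p[0] <= lo * 1.001:
            msg = "ok (degrees-of-freedom bound active)"
    return FitResult(fam.name, best_p, best_ll, n, converged, restarts_used, msg)
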