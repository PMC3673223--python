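"""Population-layer densities of the hierarchical model.

Per-cell kinetic parameters are drawn from shared population distributions:

* per-copy transcription rates (on- and off-phase) — lognormal, per construct
  group (a config switch collapses the off-rate to a single global law);
* translation rate ``alpha`` — one global lognormal (same reporter protein in
  every construct);
* measurement precision ``1/sigma_eps2`` — gamma (the standard hierarchical
  prior for the precision of a normal), one per cell drawn from shared
  shape/rate;
* plasmid copy number ``c`` — zero-truncated *continuous* Poisson: the
  Poisson pmf with the factorial replaced by a gamma function, renormalized
  to exclude zero, so ``c`` can move continuously during sampling;
* switch times — flat over the observation window; they are cell-specific
  events, not population-structured.

Hyperpriors are proper but weak: N(0, 10²) on each lognormal location,
half-normal(5) on each scale, Exp(0.01) on the gamma shape/rate and the
Poisson rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, interpolate
from scipy.special import gammaln

from .kinetics import CellKinetics

__all__ = [
    "HyperParams",
    "lognormal_logpdf",
    "trunc_cpoisson_logpdf",
    "trunc_cpoisson_log_norm",
    "trunc_cpoisson_mean",
    "gamma_precision_logpdf",
    "meas_variance_logpdf",
    "log_prior_cell",
    "log_hyperprior",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class HyperParams:
    """Parameters psi of the population (second) layer.

    ``mu_tau_on``/``sigma_tau_on`` and ``mu_tau_off``/``sigma_tau_off`` map a
    group label to the location/scale of the underlying normal of that
    group's lognormal rate distribution.  The copy-number law is shared by
    all groups (single ``copy_lambda``) — that common distribution is what
    makes transcription rates comparable between constructs.
    """

    mu_tau_on: dict
    sigma_tau_on: dict
    mu_tau_off: dict
    sigma_tau_off: dict
    mu_alpha: float
    sigma_alpha: float
    precision_shape: float
    precision_rate: float
    copy_lambda: float

    def __post_init__(self) -> None:
        for d, name in (
            (self.sigma_tau_on, "sigma_tau_on"),
            (self.sigma_tau_off, "sigma_tau_off"),
        ):
            for g, v in d.items():
                if not v > 0:
                    raise ValueError(f"{name}[{g!r}] must be > 0, got {v!r}")
        for name in ("sigma_alpha", "precision_shape", "precision_rate", "copy_lambda"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if set(self.mu_tau_on) != set(self.sigma_tau_on):
            raise ValueError("mu_tau_on and sigma_tau_on must share group labels")

    @property
    def groups(self) -> list:
        return sorted(self.mu_tau_on)


def lognormal_logpdf(x: float, mu: float, sigma: float) -> float:
    """Lognormal log-density; returns -inf for x <= 0 (so MCMC can reject)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma!r}")
    if not x > 0:
        return -math.inf
    lx = math.log(x)
    z = (lx - mu) / sigma
    return -0.5 * z * z - lx - math.log(sigma) - 0.5 * _LOG_2PI


def _trunc_cpoisson_log_norm_quad(lam: float) -> float:
    """log R(lam) = log ∫_0^∞ lam^c e^(-lam) / Γ(c+1) dc by adaptive quadrature."""
    llam = math.log(lam)

    def integrand(c):
        return np.exp(c * llam - lam - gammaln(c + 1.0))

    # integrand peaks near c ≈ lam; split there so quad resolves both flanks
    split = max(lam, 1.0)
    a, _ = integrate.quad(integrand, 0.0, split, limit=200)
    b, _ = integrate.quad(integrand, split, np.inf, limit=200)
    return math.log(a + b)


class _LogNormCache:
    """Spline cache of log R(lam) over a lam-grid; direct quadrature outside.

    The spline (over log-lam) reproduces direct quadrature to < 1e-6 on the
    grid range; values outside the grid fall back to exact quadrature.
    """

    LO, HI, N = 0.02, 120.0, 600

    def __init__(self) -> None:
        self._spline = None

    def _build(self) -> None:
        grid = np.exp(np.linspace(math.log(self.LO), math.log(self.HI), self.N))
        vals = [_trunc_cpoisson_log_norm_quad(l) for l in grid]
        self._spline = interpolate.CubicSpline(np.log(grid), vals)

    def __call__(self, lam: float) -> float:
        if not self.LO <= lam <= self.HI:
            return _trunc_cpoisson_log_norm_quad(lam)
        if self._spline is None:
            self._build()
        return float(self._spline(math.log(lam)))


_log_norm_cache = _LogNormCache()


def trunc_cpoisson_log_norm(lam: float) -> float:
    """Normalization term R(lam) (log scale) of the truncated continuous Poisson."""
    if not lam > 0:
        raise ValueError(f"lambda must be > 0, got {lam!r}")
    return _log_norm_cache(lam)


def trunc_cpoisson_logpdf(c: float, lam: float) -> float:
    """Zero-truncated continuous Poisson log-density.

    ``ln[lam^c e^(-lam) / Γ(c+1)] − ln R(lam)`` with the renormalization
    ``R(lam)`` accounting for the truncation at zero; -inf for c <= 0.
    """
    if not lam > 0:
        raise ValueError(f"lambda must be > 0, got {lam!r}")
    if not c > 0:
        return -math.inf
    return c * math.log(lam) - lam - gammaln(c + 1.0) - trunc_cpoisson_log_norm(lam)


def trunc_cpoisson_mean(lam: float) -> float:
    """Mean of the truncated continuous Poisson, by quadrature."""
    llam = math.log(lam)

    def integrand(c):
        return c * np.exp(c * llam - lam - gammaln(c + 1.0))

    a, _ = integrate.quad(integrand, 0.0, max(lam, 1.0), limit=200)
    b, _ = integrate.quad(integrand, max(lam, 1.0), np.inf, limit=200)
    return (a + b) / math.exp(trunc_cpoisson_log_norm(lam))


def gamma_precision_logpdf(prec: float, shape: float, rate: float) -> float:
    """Gamma log-density over the measurement precision ``1/sigma_eps2``."""
    if shape <= 0 or rate <= 0:
        raise ValueError("shape and rate must be > 0")
    if not prec > 0:
        return -math.inf
    return (
        shape * math.log(rate)
        - gammaln(shape)
        + (shape - 1.0) * math.log(prec)
        - rate * prec
    )


def meas_variance_logpdf(sig2: float, shape: float, rate: float) -> float:
    """Density of sigma_eps2 implied by the gamma law on the precision.

    Change of variable prec = 1/sig2 contributes the Jacobian |d prec/d sig2|
    = sig2^-2, i.e. an extra −2·ln(sig2) on the log scale.  Sampling itself
    operates on log sigma_eps2; that proposal Jacobian is handled by the
    sampler, not here.
    """
    if not sig2 > 0:
        return -math.inf
    return gamma_precision_logpdf(1.0 / sig2, shape, rate) - 2.0 * math.log(sig2)


def log_prior_cell(
    theta: CellKinetics,
    psi: HyperParams,
    group,
    switch_window: tuple | None = None,
) -> float:
    """Log-density of one cell's parameters under the population layer.

    Sum of the lognormal terms for tau_on/tau_off (group-specific) and alpha
    (global), the gamma-precision term for sigma_eps2 (as a density over the
    variance), the truncated continuous Poisson term for copy number, and a
    flat prior over ``switch_window`` for the switch time.  delta_M, delta_P
    and kappa are fixed constants and contribute nothing.
    """
    if group not in psi.mu_tau_on:
        raise KeyError(f"unknown group {group!r}; known: {psi.groups}")
    tr = theta.transcription
    total = lognormal_logpdf(tr.tau_on, psi.mu_tau_on[group], psi.sigma_tau_on[group])
    g_off = group if group in psi.mu_tau_off else next(iter(psi.mu_tau_off))
    total += lognormal_logpdf(tr.tau_off, psi.mu_tau_off[g_off], psi.sigma_tau_off[g_off])
    total += lognormal_logpdf(theta.alpha, psi.mu_alpha, psi.sigma_alpha)
    total += meas_variance_logpdf(theta.sigma_eps2, psi.precision_shape, psi.precision_rate)
    total += trunc_cpoisson_logpdf(theta.copy_number, psi.copy_lambda)
    if switch_window is not None:
        lo, hi = switch_window
        if not lo <= tr.switch_time <= hi:
            return -math.inf
        total += -math.log(hi - lo)
    return total


def _normal_logpdf(x: float, mu: float, sd: float) -> float:
    z = (x - mu) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * _LOG_2PI


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if not x > 0:
        return -math.inf
    return 0.5 * math.log(2.0 / math.pi) - math.log(scale) - 0.5 * (x / scale) ** 2


def _expon_logpdf(x: float, rate: float) -> float:
    if not x > 0:
        return -math.inf
    return math.log(rate) - rate * x


def log_hyperprior(psi: HyperParams) -> float:
    """Weakly-informative hyperprior over psi (see module docstring)."""
    total = 0.0
    for d in (psi.mu_tau_on, psi.mu_tau_off):
        for mu in d.values():
            total += _normal_logpdf(mu, 0.0, 10.0)
    for d in (psi.sigma_tau_on, psi.sigma_tau_off):
        for sig in d.values():
            total += _halfnormal_logpdf(sig, 5.0)
    total += _normal_logpdf(psi.mu_alpha, 0.0, 10.0)
    total += _halfnormal_logpdf(psi.sigma_alpha, 5.0)
    total += _expon_logpdf(psi.precision_shape, 0.01)
    total += _expon_logpdf(psi.precision_rate, 0.01)
    total += _expon_logpdf(psi.copy_lambda, 0.01)
    return total
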