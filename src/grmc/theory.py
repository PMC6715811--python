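"""Closed-form contact-probability / mean-distance relations for Gaussian chains.

For a harmonic (Rouse-like) chain the vector between two loci is an isotropic
Gaussian, so the scalar distance follows a chi distribution with three degrees
of freedom parameterized by the per-axis standard deviation ``sigma``.  The
probability that the two loci are within a contact threshold ``r_c`` then has
an exact closed form, and — because the mean distance is ``2*sqrt(2/pi)*sigma``
— contact probability and mean spatial distance are linked one-to-one:

    P = erf(2 r_c / (sqrt(pi) <R>)) - (4/pi) (r_c/<R>) exp(-4 r_c^2 / (pi <R>^2))

This module provides that map, its numerical inverse (the operation that turns
a Hi-C contact probability into a FISH-comparable mean distance), and the
Redner–des Cloizeaux (RdC) generalization — a two-exponent generalized-gamma
family of polymer end-to-end distance distributions of which the Gaussian
chain is the (g, delta) = (0, 2) special case.

All functions are unit-agnostic: lengths may be in micrometers (real data) or
in units of the bond length ``a`` (simulation), as long as one system is used
consistently within a call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "ContactTheoryParams",
    "PairGaussianStats",
    "MEAN_TO_SIGMA",
    "chi_pdf",
    "chi_cdf",
    "contact_prob_chi",
    "contact_prob_from_mean",
    "invert_contact_to_mean",
    "rdc_b",
    "rdc_pdf",
    "rdc_cdf",
    "rdc_contact_prob",
    "rdc_ppf",
    "sigma_from_mean",
    "mean_from_sigma",
]

# <R> = 2*sqrt(2/pi)*sigma  =>  sigma = MEAN_TO_SIGMA * <R>
MEAN_TO_SIGMA = np.sqrt(np.pi) / (2.0 * np.sqrt(2.0))


def mean_from_sigma(sigma):
    """Mean of the 3D chi distance distribution, ``2*sqrt(2/pi)*sigma``."""
    return 2.0 * np.sqrt(2.0 / np.pi) * np.asarray(sigma, dtype=float)


def sigma_from_mean(mean_distance):
    """Per-axis Gaussian width corresponding to a mean distance."""
    return MEAN_TO_SIGMA * np.asarray(mean_distance, dtype=float)


@dataclass(frozen=True)
class ContactTheoryParams:
    """Distance-distribution family for one homogeneous subpopulation.

    Parameters
    ----------
    r_c : float
        Contact threshold distance (same length unit as the distances).
    g : float
        Correlation-hole exponent of the RdC family; ``g = 0`` recovers the
        Gaussian chain. Inferred experimentally from ``P ~ <R>^-(3+g)``.
    delta : float
        Stretching exponent of the RdC tail, related to the Flory exponent by
        ``delta = 1/(1 - nu)``; ``delta = 2`` is the Gaussian chain.
    """

    r_c: float
    g: float = 0.0
    delta: float = 2.0

    def __post_init__(self):
        if not self.r_c > 0:
            raise ValueError(f"r_c must be positive, got {self.r_c}")
        if not self.delta > 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.g < 0:
            raise ValueError(f"g must be nonnegative, got {self.g}")

    @classmethod
    def from_nu(cls, r_c: float, g: float, nu: float) -> "ContactTheoryParams":
        """Build parameters from the Flory exponent via ``delta = 1/(1 - nu)``."""
        if not 0 < nu < 1:
            raise ValueError(f"nu must be in (0, 1), got {nu}")
        return cls(r_c=r_c, g=g, delta=1.0 / (1.0 - nu))


@dataclass(frozen=True)
class PairGaussianStats:
    """Exact Gaussian statistics of one locus pair: per-axis ``sigma`` and mean distance."""

    sigma: float
    mean_distance: float

    def __post_init__(self):
        if not (self.sigma > 0 and self.mean_distance > 0):
            raise ValueError("sigma and mean_distance must be positive")

    @classmethod
    def from_sigma(cls, sigma: float) -> "PairGaussianStats":
        return cls(sigma=sigma, mean_distance=float(mean_from_sigma(sigma)))

    @classmethod
    def from_mean(cls, mean_distance: float) -> "PairGaussianStats":
        return cls(sigma=float(sigma_from_mean(mean_distance)), mean_distance=mean_distance)


def _check_positive(**kwargs):
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be positive, got {value}")


def chi_pdf(r, sigma):
    """Density of the 3D distance for an isotropic Gaussian pair vector.

    ``f(r) = sqrt(2/pi) * r^2 / sigma^3 * exp(-r^2 / (2 sigma^2))`` for r >= 0.
    """
    _check_positive(sigma=sigma)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be nonnegative")
    out = np.sqrt(2.0 / np.pi) * r**2 / np.asarray(sigma, float) ** 3 * np.exp(
        -(r**2) / (2.0 * np.asarray(sigma, float) ** 2)
    )
    return out if out.ndim else float(out)


def chi_cdf(r, sigma):
    """CDF of the 3D chi distance distribution (closed form)."""
    _check_positive(sigma=sigma)
    r = np.asarray(r, dtype=float)
    x = r / np.asarray(sigma, float)
    out = special.erf(x / np.sqrt(2.0)) - np.sqrt(2.0 / np.pi) * x * np.exp(-(x**2) / 2.0)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def contact_prob_chi(sigma, r_c):
    """Probability that the pair distance is below ``r_c``, i.e. ``chi_cdf(r_c, sigma)``."""
    _check_positive(sigma=sigma, r_c=r_c)
    return chi_cdf(r_c, sigma)


def contact_prob_from_mean(mean_distance, r_c):
    """Contact probability as a function of the mean spatial distance.

    This is the chi contact probability with ``sigma`` eliminated in favor of
    ``<R> = 2*sqrt(2/pi)*sigma``:

    ``P = erf(2 r_c/(sqrt(pi) <R>)) - (4/pi)(r_c/<R>) exp(-4 r_c^2/(pi <R>^2))``

    Strictly decreasing in ``mean_distance`` for fixed ``r_c``.
    """
    _check_positive(mean_distance=mean_distance, r_c=r_c)
    R = np.asarray(mean_distance, dtype=float)
    x = r_c / R
    out = special.erf(2.0 * x / np.sqrt(np.pi)) - (4.0 / np.pi) * x * np.exp(
        -4.0 * x**2 / np.pi
    )
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def invert_contact_to_mean(P, r_c, *, rtol: float = 1e-12) -> float:
    """Invert the contact-probability relation: find ``<R>`` with ``R_0(<R>) = P``.

    The map is strictly monotone, so the root is unique and bracketed between
    ``r_c * 1e-3`` (P -> 1) and a multiple of the small-P asymptote
    ``r_c * P**(-1/3)``.  Brent's method on that bracket is guaranteed to
    converge.

    Parameters
    ----------
    P : float
        Contact probability, strictly inside (0, 1).
    r_c : float
        Contact threshold, same unit as the returned mean distance.
    """
    P = float(P)
    _check_positive(r_c=r_c)
    if not 0.0 < P < 1.0:
        raise ValueError(f"P must be in the open interval (0, 1), got {P}")
    lo = r_c * 1e-3
    hi = 10.0 * r_c * P ** (-1.0 / 3.0)
    # widen defensively; monotonicity guarantees a sign change exists
    while contact_prob_from_mean(lo, r_c) < P:
        lo *= 0.5
        if lo < r_c * 1e-12:
            raise RuntimeError(f"failed to bracket root for P={P}, r_c={r_c}")
    while contact_prob_from_mean(hi, r_c) > P:
        hi *= 2.0
        if hi > r_c * 1e12:
            raise RuntimeError(f"failed to bracket root for P={P}, r_c={r_c}")
    root, res = optimize.brentq(
        lambda R: contact_prob_from_mean(R, r_c) - P,
        lo,
        hi,
        rtol=rtol,
        full_output=True,
    )
    if not res.converged:
        raise RuntimeError(
            f"root finding did not converge for P={P}, r_c={r_c}: {res.flag}"
        )
    return float(root)


# ---------------------------------------------------------------------------
# Redner–des Cloizeaux generalized family
# ---------------------------------------------------------------------------
#
# f(r) = delta * b^(3+g) / Gamma((3+g)/delta) * r^(2+g) * exp(-(b r)^delta)
#
# The scale b and the normalization are fixed by the two constraints
# integral(f) = 1 and E[r] = mean_distance, which give
# b = Gamma((4+g)/delta) / (Gamma((3+g)/delta) * mean_distance).


def rdc_b(mean_distance, params: ContactTheoryParams):
    """Inverse length scale of the RdC density fixed by the mean constraint."""
    _check_positive(mean_distance=mean_distance)
    k = (3.0 + params.g) / params.delta
    k1 = (4.0 + params.g) / params.delta
    return special.gamma(k1) / (special.gamma(k) * np.asarray(mean_distance, float))


def rdc_pdf(r, mean_distance, params: ContactTheoryParams):
    """Redner–des Cloizeaux distance density with unit mass and given mean.

    ``(g, delta) = (0, 2)`` reduces exactly to the chi density of the Gaussian
    chain with ``sigma = sqrt(pi)/(2 sqrt(2)) * <R>``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be nonnegative")
    b = rdc_b(mean_distance, params)
    g, d = params.g, params.delta
    k = (3.0 + g) / d
    out = d * b ** (3.0 + g) / special.gamma(k) * r ** (2.0 + g) * np.exp(
        -((b * r) ** d)
    )
    return out if out.ndim else float(out)


def rdc_cdf(r, mean_distance, params: ContactTheoryParams):
    """CDF of the RdC density: regularized lower incomplete gamma of ``(b r)^delta``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be nonnegative")
    b = rdc_b(mean_distance, params)
    k = (3.0 + params.g) / params.delta
    out = special.gammainc(k, (b * r) ** params.delta)
    return out if out.ndim else float(out)


def rdc_contact_prob(mean_distance, params: ContactTheoryParams):
    """Contact probability ``integral_0^{r_c} f(r) dr = rdc_cdf(r_c)``."""
    return rdc_cdf(params.r_c, mean_distance, params)


def rdc_ppf(q, mean_distance, params: ContactTheoryParams):
    """Quantile function (inverse CDF), exact via the inverse incomplete gamma.

    Used for inverse-transform sampling of RdC-distributed distances.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantiles must lie in [0, 1]")
    b = rdc_b(mean_distance, params)
    k = (3.0 + params.g) / params.delta
    out = special.gammaincinv(k, q) ** (1.0 / params.delta) / b
    return out if out.ndim else float(out)
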