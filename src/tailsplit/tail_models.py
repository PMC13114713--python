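"""Distribution arithmetic for the tail models of the sequential design.

The resistance of interest ``R`` is a positive latent variable; extreme
*lower* quantiles of ``R`` are estimated through extreme *upper* quantiles of
the reciprocal ``R~ = 1/R`` (``q_alpha(R) = 1 / q_{1-alpha}(R~)``).  Two
parametric families are supported for ``R~``:

* the Generalized Pareto distribution with strictly positive tail index,
  which is exactly stable under threshold conditioning (the excess
  ``R~ - s`` given ``R~ > s`` is again GPD with scale ``a + c*s``), and
* the Weibull distribution, whose conditional exceedance probabilities obey
  a scale-free identity in the shape parameter alone.

The module also provides the Gamma-mixture representation of the GPD
survival function (a completely monotone function is a Laplace transform)
and a family of transformed-GPD survival functions that deform the
distribution near the origin while keeping the Pareto tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GPDParams:
    """Generalized Pareto parameters for the reciprocal resistance.

    Attributes
    ----------
    c : float
        Tail index, strictly positive (heavy Pareto-type tail).  The
        exponential boundary case ``c = 0`` is excluded: it is memoryless and
        carries no information across thresholds.
    a : float
        Scale, strictly positive, in the units of ``R~``.
    """

    c: float
    a: float

    def __post_init__(self) -> None:
        if not (self.c > 0):
            raise ValueError(f"tail index c must be > 0, got {self.c}")
        if not (self.a > 0):
            raise ValueError(f"scale a must be > 0, got {self.a}")


@dataclass(frozen=True)
class WeibullParams:
    """Weibull scale/shape parameters for the reciprocal resistance."""

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if not (self.shape > 0):
            raise ValueError(f"shape must be > 0, got {self.shape}")


_TRANSFORM_FORMS = ("exponential", "logarithmic", "root", "fraction")


@dataclass(frozen=True)
class TransformedGPDSpec:
    """A deformation ``W_bar = L_bar(G(x))`` of a base GPD.

    ``L`` is an increasing bijection of [0, 1] with completely monotone
    complement, so the transformed survival function stays completely
    monotone while the behaviour near 0 becomes more flexible.

    ``form_param`` is the lambda of the exponential form and the alpha of the
    fraction form; it is unused for the logarithmic and root forms.  The
    exponent inside the exponential form defaults to 1 (``exp_alpha``),
    constrained to (0, 1].
    """

    base: GPDParams
    form: str
    form_param: float = 1.0
    exp_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in _TRANSFORM_FORMS:
            raise ValueError(
                f"unknown form {self.form!r}; expected one of {_TRANSFORM_FORMS}"
            )
        if self.form in ("exponential", "fraction") and not (self.form_param > 0):
            raise ValueError("form_param must be > 0 for this form")
        if not (0 < self.exp_alpha <= 1):
            raise ValueError("exponential-form exponent must be in (0, 1]")


# --------------------------------------------------------------------------
# GPD survival / quantile / conditioning
# --------------------------------------------------------------------------

def gpd_sf(x, params: GPDParams):
    """Survival function ``(1 + c*x/a)^(-1/c)`` of the GPD, for x >= 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("gpd_sf requires x >= 0")
    out = np.power(1.0 + params.c * x / params.a, -1.0 / params.c)
    return out if out.ndim else float(out)


def gpd_quantile(u, params: GPDParams):
    """Quantile ``(a/c) * ((1-u)^(-c) - 1)``, the exact inverse of the CDF.

    Defined for u in [0, 1); increasing in u.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("gpd_quantile requires 0 <= u < 1")
    out = (params.a / params.c) * (np.power(1.0 - u, -params.c) - 1.0)
    return out if out.ndim else float(out)


def gpd_condition(params: GPDParams, s: float) -> GPDParams:
    """Parameters of the excess ``R~ - s`` given ``R~ > s``: (c, a + c*s)."""
    if s < 0:
        raise ValueError("threshold s must be >= 0")
    return GPDParams(params.c, params.a + params.c * s)


# --------------------------------------------------------------------------
# Weibull survival / quantile / conditional identities
# --------------------------------------------------------------------------

def weibull_sf(x, params: WeibullParams):
    """Survival ``exp(-(x/scale)^shape)`` for x >= 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("weibull_sf requires x >= 0")
    out = np.exp(-np.power(x / params.scale, params.shape))
    return out if out.ndim else float(out)


def weibull_quantile(u, params: WeibullParams):
    """Quantile ``scale * (-log(1-u))^(1/shape)`` for u in [0, 1)."""
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("weibull_quantile requires 0 <= u < 1")
    out = params.scale * np.power(-np.log1p(-u), 1.0 / params.shape)
    return out if out.ndim else float(out)


def weibull_cond_log_sf(
    s_prev: float, s_next: float, shape: float, log_p_prev: float
) -> float:
    """Conditional log-survival ``log P(R~ > s_next | R~ > s_prev)``.

    Uses the scale-free Weibull identity
    ``((s_next/s_prev)^shape - 1) * log P(R~ > s_prev)``: the scale
    parameter cancels, so the conditional exceedance probability across two
    thresholds is determined by the shape and the (log) probability of the
    lower one.  ``log_p_prev`` is ``log P(R~ > s_prev)`` (or a conditional
    log-probability, in the iterated three-level form).
    """
    if not (0 < s_prev <= s_next):
        raise ValueError("need 0 < s_prev <= s_next")
    if log_p_prev >= 0 and s_next != s_prev:
        raise ValueError("log_p_prev must be negative")
    return (np.power(s_next / s_prev, shape) - 1.0) * log_p_prev


def weibull_cond_log_sf_three_level(
    s_jm1: float, s_j: float, s_jp1: float, shape: float, log_p_cond: float
) -> float:
    """Three-level form of the conditional log-survival identity.

    Returns ``log P(R~ > s_jp1 | R~ > s_j)`` from the conditional
    ``log_p_cond = log P(R~ > s_j | R~ > s_jm1)``:

    ``[ (s_jm1^b - s_jp1^b) / (s_jm1^b - s_j^b) - 1 ] * log_p_cond``.

    ``s_jm1 = 0`` reduces this to the two-level identity.
    """
    if not (0 <= s_jm1 < s_j <= s_jp1):
        raise ValueError("need 0 <= s_jm1 < s_j <= s_jp1")
    if log_p_cond >= 0:
        raise ValueError("log_p_cond must be negative")
    b = shape
    num = s_jm1**b - s_jp1**b
    den = s_jm1**b - s_j**b
    return (num / den - 1.0) * log_p_cond


# --------------------------------------------------------------------------
# Gamma-mixture representation of the GPD
# --------------------------------------------------------------------------

def gpd_sf_via_gamma_mixture(x: float, params: GPDParams, quad_tol: float = 1e-9) -> float:
    """GPD survival computed as the Laplace transform of a Gamma variable.

    The GPD survival with c > 0 is completely monotone and equals
    ``integral_0^inf exp(-x*y) v(y) dy`` with ``v`` the Gamma density of
    shape ``1/c`` and rate ``a/c``.  Evaluated by adaptive quadrature; this
    is an identity-checking path, not a fast path.
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    c, a = params.c, params.a
    shape, rate = 1.0 / c, a / c
    log_norm = shape * np.log(rate) - special.gammaln(shape)

    def integrand(y: float) -> float:
        return np.exp(log_norm + (shape - 1.0) * np.log(y) - rate * y - x * y)

    val, err = integrate.quad(integrand, 0.0, np.inf, epsabs=quad_tol, limit=200)
    if err > max(quad_tol * 100, 1e-6):
        raise RuntimeError(
            f"gamma-mixture quadrature did not converge: value={val}, abserr={err}"
        )
    return val


# --------------------------------------------------------------------------
# Transformed-GPD survival families
# --------------------------------------------------------------------------

def transformed_gpd_sf(x, spec: TransformedGPDSpec):
    """Survival of the transformed GPD, ``W_bar(x) = 1 - L(G(x))``.

    The four admissible deformations ``L`` (increasing bijections of [0,1]):

    * exponential: ``L(u) = (1 - exp(-lam*u^alpha)) / (1 - exp(-lam))``
    * logarithmic: ``L(u) = log(u + 1) / log 2``
    * root:        ``L(u) = (sqrt(u + 1) - 1) / (sqrt 2 - 1)``
    * fraction:    ``L(u) = (alpha + 1) * u / (u + alpha)``
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("transformed_gpd_sf requires x >= 0")
    g = 1.0 - np.power(1.0 + spec.base.c * x / spec.base.a, -1.0 / spec.base.c)
    if spec.form == "exponential":
        lam = spec.form_param
        L = -np.expm1(-lam * np.power(g, spec.exp_alpha)) / -np.expm1(-lam)
    elif spec.form == "logarithmic":
        L = np.log1p(g) / np.log(2.0)
    elif spec.form == "root":
        L = (np.sqrt(g + 1.0) - 1.0) / (np.sqrt(2.0) - 1.0)
    else:  # fraction
        al = spec.form_param
        L = (al + 1.0) * g / (g + al)
    out = 1.0 - L
    return out if out.ndim else float(out)


def reciprocal_quantile(q_tilde: float) -> float:
    """Map the (1-alpha)-quantile of ``R~`` to the alpha-quantile of ``R``."""
    if not (q_tilde > 0):
        raise ValueError("q_tilde must be > 0")
    return 1.0 / q_tilde
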