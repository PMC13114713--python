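"""Neighborhood-based control of deviations from the GPD model.

The true law of the reciprocal resistance may only approach a GPD in the
tail.  A weighted sup-norm neighborhood

    V_eps(F) = { G : sup_x |F_bar(x) - G_bar(x)| * w(x) <= eps }

with an increasing, diverging weight w constrains departures tightly in the
right tail.  Within such a neighborhood the conditional survival ratios —
the quantities the sequential design actually consumes — can be bracketed,
and the bracket converted to a first-order relative-error band whose width
guides the choice of admissible thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize

from .tail_models import GPDParams, gpd_sf


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Contamination radius and weight function of the neighborhood.

    The default weight ``w(x) = 1 + x`` is increasing and diverges, and for
    the unit GPD makes the relative-error kernel constant — a convenient
    reference case.
    """

    epsilon: float = 0.0
    weight: Callable[[np.ndarray], np.ndarray] = None

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.weight is None:
            object.__setattr__(self, "weight", lambda x: 1.0 + np.asarray(x, dtype=float))

    def w(self, x):
        val = np.asarray(self.weight(x), dtype=float)
        if np.any(val <= 0):
            raise ValueError("weight must be positive on the support")
        return val if val.ndim else float(val)


class InfeasibleNeighborhoodError(ValueError):
    """The contamination allows G_bar(s) = 0: conditional ratios unbounded."""


def conditional_sf_bounds(
    x: float, s: float, params: GPDParams, nb: NeighborhoodSpec
) -> tuple[float, float]:
    """Exact bracket of the conditional survival G_bar(x)/G_bar(s).

    ``( (F_bar(x) - eps/w(x)) / (F_bar(s) + eps/w(s)),
       (F_bar(x) + eps/w(x)) / (F_bar(s) - eps/w(s)) )``
    clipped to [0, 1].  Errors out when the GPD survival at s does not
    dominate the contamination there.
    """
    if not (x >= s >= 0):
        raise ValueError("need x >= s >= 0")
    eps = nb.epsilon
    fx, fs = gpd_sf(x, params), gpd_sf(s, params)
    ex, es = eps / nb.w(x), eps / nb.w(s)
    if fs - es <= 0:
        raise InfeasibleNeighborhoodError(
            f"F_bar(s)={fs} <= eps/w(s)={es}: neighborhood too wide at s={s}"
        )
    lower = max(0.0, (fx - ex) / (fs + es))
    upper = min(1.0, (fx + ex) / (fs - es))
    return lower, upper


def relative_error_bound_u(
    s: float, x: float, params: GPDParams, nb: NeighborhoodSpec
) -> float:
    """First-order relative-error kernel u(s, x).

    ``(1 + c*s/a)^(1/c) / w(s) + (1 + c*x/a)^(1/c) / w(x)``; the implied
    band on the conditional-survival ratio is [1 - u*eps, 1 + u*eps].
    The kernel is symmetric in its two arguments.
    """
    if not (x >= 0 and s >= 0):
        raise ValueError("need s, x >= 0")
    c, a = params.c, params.a
    term = lambda t: (1.0 + c * t / a) ** (1.0 / c) / nb.w(t)
    return float(term(s) + term(x))


def threshold_for_tolerance(
    params: GPDParams,
    nb: NeighborhoodSpec,
    delta_tol: float,
    x: float,
    search_hi: float = 1e6,
) -> float:
    """Smallest threshold s keeping the first-order relative error below delta.

    Solves ``(1 + c*s/a)^(1/c) / w(s) <= delta/eps - (1 + c*x/a)^(1/c) / w(x)``
    for the minimal s in [0, search_hi] by bracketed root finding on a
    log-spaced bracket.  Returns 0.0 when s = 0 already qualifies; raises
    when no threshold in range does.
    """
    if not (delta_tol > 0):
        raise ValueError("delta_tol must be > 0")
    if not (nb.epsilon > 0):
        raise ValueError("epsilon must be > 0 for a tolerance threshold")
    c, a = params.c, params.a
    budget = delta_tol / nb.epsilon - (1.0 + c * x / a) ** (1.0 / c) / nb.w(x)

    def g(s: float) -> float:
        return (1.0 + c * s / a) ** (1.0 / c) / nb.w(s) - budget

    if g(0.0) <= 0:
        return 0.0
    # g is the constraint gap; find the first sign change on a log grid
    grid = np.concatenate([[0.0], np.geomspace(1e-9, search_hi, 400)])
    vals = np.array([g(s) for s in grid])
    idx = np.nonzero(vals <= 0)[0]
    if idx.size == 0:
        raise ValueError(
            f"no threshold in [0, {search_hi}] meets tolerance {delta_tol} "
            f"at epsilon {nb.epsilon}"
        )
    i = idx[0]
    return float(optimize.brentq(g, grid[i - 1], grid[i], xtol=1e-12))
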