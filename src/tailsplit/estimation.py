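"""Parameter estimation from binary stage data.

Each stage of the sequential design observes only K Bernoulli indicators of
exceedance over the current threshold, so a single stage identifies at most
one probability — far too little for the two GPD parameters, and the
Bernoulli log-likelihood surface is notoriously flat in (c, a).  The
estimator implemented here therefore combines two criteria:

* an *admissibility* constraint: the candidate pair must reproduce the
  observed stage exceedance fraction within a Wald confidence interval, and
* a *backward-consistency* objective: among admissible pairs, pick the one
  whose implied conditional quantile best reproduces the threshold
  increment actually realized at the previous stage.

Candidates (c, a) are always expressed on the *initial* (unconditioned)
scale; the GPD threshold-stability identity converts them to the
conditional law above any stage threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .tail_models import GPDParams, gpd_quantile, gpd_sf

DEFAULT_SEARCH_BOX = (0.05, 5.0, 0.05, 20.0)  # c_min, c_max, a_min, a_max


@dataclass(frozen=True)
class AdmissibleInterval:
    """Wald confidence interval for a stage exceedance probability."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError(f"invalid interval [{self.lower}, {self.upper}]")

    def contains(self, p) -> bool:
        return (self.lower <= p) & (p <= self.upper)


@dataclass(frozen=True)
class EstimatorConfig:
    """Plumbing for the constrained grid minimizer.

    The grid is log-spaced over the search box (flat likelihoods favour wide
    multiplicative exploration); ties are broken toward the smallest c then
    smallest a (parsimony toward lighter tails); an empty admissible set is
    retried once with the interval level gamma halved (wider interval).
    """

    search_box: tuple[float, float, float, float] = DEFAULT_SEARCH_BOX
    grid_size: int = 200
    refine: bool = True
    fallback_halve_gamma: bool = True

    def __post_init__(self) -> None:
        c_lo, c_hi, a_lo, a_hi = self.search_box
        if not (0 < c_lo < c_hi and 0 < a_lo < a_hi):
            raise ValueError("search box bounds must be positive and ordered")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2 per axis")

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        c_lo, c_hi, a_lo, a_hi = self.search_box
        c = np.geomspace(c_lo, c_hi, self.grid_size)
        a = np.geomspace(a_lo, a_hi, self.grid_size)
        cc, aa = np.meshgrid(c, a, indexing="ij")
        return cc.ravel(), aa.ravel()


class EstimationError(RuntimeError):
    """Raised when no admissible parameter pair can be found at a stage."""


def empirical_p(outcomes) -> float:
    """Mean of a nonempty binary outcome vector."""
    outcomes = np.asarray(outcomes)
    if outcomes.size == 0:
        raise ValueError("empty outcome vector")
    return float(outcomes.mean())


def shrunk_p(outcomes) -> float:
    """Anscombe-shrunk exceedance fraction ``(sum + 0.5) / (K + 1)``.

    Keeps logs and Wald intervals finite when a stage observes all zeros or
    all ones; equals nearly the raw mean otherwise.
    """
    outcomes = np.asarray(outcomes)
    if outcomes.size == 0:
        raise ValueError("empty outcome vector")
    return float((outcomes.sum() + 0.5) / (outcomes.size + 1))


def wald_interval(p_hat: float, K: int, gamma: float) -> AdmissibleInterval:
    """Wald interval ``p_hat +/- z_{1-gamma/2} * sqrt(p_hat(1-p_hat)/(K-1))``.

    Note the K-1 denominator (sample-variance convention).  Clipped to
    [0, 1].
    """
    if K < 2:
        raise ValueError("need K >= 2 trials for a Wald interval")
    if not (0 < p_hat < 1):
        raise ValueError("p_hat must be strictly inside (0, 1); shrink first")
    if not (0 < gamma < 1):
        raise ValueError("gamma must be in (0, 1)")
    z = stats.norm.ppf(1.0 - gamma / 2.0)
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / (K - 1))
    return AdmissibleInterval(max(0.0, p_hat - half), min(1.0, p_hat + half))


def is_admissible(c, a, s_j, s_jm1, interval: AdmissibleInterval):
    """Whether conditional params (c, a) put P(exceed s_j | > s_jm1) in the interval.

    (c, a) are the parameters of the conditional law *already at threshold
    s_jm1*; the probability checked is the GPD survival of the increment
    ``s_j - s_jm1``.
    """
    if np.any(np.asarray(s_j) <= np.asarray(s_jm1)):
        raise ValueError("need s_j > s_jm1")
    c = np.asarray(c, dtype=float)
    a = np.asarray(a, dtype=float)
    sf = np.power(1.0 + c * (s_j - s_jm1) / a, -1.0 / c)
    return interval.contains(sf)


def backward_objective(c, a, s_jm1, s_jm2, p_hat_jm1):
    """Backward-consistency discrepancy for initial-scale candidates (c, a).

    ``| (s_jm1 - s_jm2) - Q |`` where Q is the (1 - p_hat_jm1)-quantile of
    the conditional GPD above s_jm2, i.e. of GPD(c, a + c*s_jm2).  Small
    values mean the candidate pair retrodicts the previously realized
    threshold increment.
    """
    if not (s_jm1 > s_jm2 >= 0):
        raise ValueError("need s_jm1 > s_jm2 >= 0")
    if not (0 < p_hat_jm1 < 1):
        raise ValueError("p_hat_jm1 must be in (0, 1)")
    c = np.asarray(c, dtype=float)
    a = np.asarray(a, dtype=float)
    a_cond = a + c * s_jm2
    q = (a_cond / c) * (np.power(p_hat_jm1, -c) - 1.0)
    out = np.abs((s_jm1 - s_jm2) - q)
    return out if out.ndim else float(out)


def _admissible_mask(cc, aa, s_j, s_jm1, interval):
    """Vectorized admissibility of initial-scale candidates at stage j."""
    a_cond = aa + cc * s_jm1
    sf = np.power(1.0 + cc * (s_j - s_jm1) / a_cond, -1.0 / cc)
    return interval.contains(sf)


def estimate_stage(
    s_jm2: float,
    s_jm1: float,
    s_j: float,
    p_hat_jm1: float,
    interval_j: AdmissibleInterval,
    cfg: EstimatorConfig = EstimatorConfig(),
    gamma: float | None = None,
    p_hat_j: float | None = None,
    K: int | None = None,
) -> tuple[GPDParams, float]:
    """Dual-criterion stage estimate on the initial (c, a) scale.

    Minimizes the backward objective over the grid points of the search box
    that are admissible for stage j's interval, with optional Nelder--Mead
    refinement constrained to the admissible set.  If the admissible set is
    empty on the grid, the interval is widened once by halving gamma
    (requires `gamma`, `p_hat_j`, `K` to recompute it); a still-empty set
    raises EstimationError.

    Deterministic given the configuration; ties broken toward smallest c,
    then smallest a.
    """
    if not (0 <= s_jm2 < s_jm1 < s_j):
        raise ValueError("need 0 <= s_jm2 < s_jm1 < s_j")
    cc, aa = cfg.grid()
    mask = _admissible_mask(cc, aa, s_j, s_jm1, interval_j)
    interval_used = interval_j
    if not mask.any() and cfg.fallback_halve_gamma and gamma is not None:
        if p_hat_j is None or K is None:
            raise EstimationError("empty admissible set and no data to widen gamma")
        interval_used = wald_interval(p_hat_j, K, gamma / 2.0)
        mask = _admissible_mask(cc, aa, s_j, s_jm1, interval_used)
    if not mask.any():
        raise EstimationError(
            f"empty admissible set at stage with thresholds "
            f"({s_jm2}, {s_jm1}, {s_j}), interval {interval_used}"
        )

    c_adm, a_adm = cc[mask], aa[mask]
    obj = backward_objective(c_adm, a_adm, s_jm1, s_jm2, p_hat_jm1)
    # lexicographic argmin: objective, then c, then a
    order = np.lexsort((a_adm, c_adm, obj))
    best = order[0]
    c_best, a_best, f_best = float(c_adm[best]), float(a_adm[best]), float(obj[best])

    if cfg.refine:
        c_lo, c_hi, a_lo, a_hi = cfg.search_box

        def penalized(log_theta):
            c, a = np.exp(log_theta)
            if not (c_lo <= c <= c_hi and a_lo <= a <= a_hi):
                return np.inf
            if not _admissible_mask(
                np.asarray(c), np.asarray(a), s_j, s_jm1, interval_used
            ):
                return np.inf
            return backward_objective(c, a, s_jm1, s_jm2, p_hat_jm1)

        res = optimize.minimize(
            penalized,
            np.log([c_best, a_best]),
            method="Nelder-Mead",
            options={"maxiter": 120, "xatol": 1e-6, "fatol": 1e-10},
        )
        if np.isfinite(res.fun) and res.fun < f_best:
            c_best, a_best = map(float, np.exp(res.x))
            f_best = float(res.fun)

    return GPDParams(c_best, a_best), f_best


def estimate_stage_one(
    s_1: float,
    interval_1: AdmissibleInterval,
    cfg: EstimatorConfig = EstimatorConfig(),
) -> GPDParams:
    """Stage-1 estimate under identifiability limits.

    One Bernoulli probability cannot pin down two parameters: among grid
    points whose unconditional survival at s_1 lies in the interval, return
    the one closest (Euclidean after log-scaling both axes) to the center of
    the search box — a neutral stand-in for the expert judgment the design
    assumes at the first level.
    """
    cc, aa = cfg.grid()
    sf = np.power(1.0 + cc * s_1 / aa, -1.0 / cc)
    mask = interval_1.contains(sf)
    if not mask.any():
        raise EstimationError(f"no grid point matches stage-1 interval {interval_1}")
    c_lo, c_hi, a_lo, a_hi = cfg.search_box
    log_center = (
        0.5 * (np.log(c_lo) + np.log(c_hi)),
        0.5 * (np.log(a_lo) + np.log(a_hi)),
    )
    c_adm, a_adm = cc[mask], aa[mask]
    d2 = (np.log(c_adm) - log_center[0]) ** 2 + (np.log(a_adm) - log_center[1]) ** 2
    order = np.lexsort((a_adm, c_adm, d2))
    best = order[0]
    return GPDParams(float(c_adm[best]), float(a_adm[best]))


def bernoulli_loglik(pi, outcomes):
    """Bernoulli log-likelihood of binary outcomes at model probability pi.

    ``pi`` may be a scalar or an array of candidate model probabilities; the
    log-likelihood is summed over outcomes.  A boundary probability
    mismatching the data yields -inf (documented sentinel).
    """
    outcomes = np.asarray(outcomes, dtype=float)
    pi = np.asarray(pi, dtype=float)
    n1 = outcomes.sum()
    n0 = outcomes.size - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = n1 * np.log(pi) + n0 * np.log1p(-pi)
    ll = np.where(np.isnan(ll), -np.inf, ll)
    return ll if ll.ndim else float(ll)


def ml_estimate(
    thresholds: list[float],
    counts: list[tuple[int, int]],
    cfg: EstimatorConfig = EstimatorConfig(),
) -> GPDParams:
    """Naive cumulative maximum-likelihood baseline.

    Maximizes the product of the stage Bernoulli likelihoods over the search
    box (unconstrained by any interval).  ``thresholds`` is the ladder
    ``[s_0=0, s_1, ..., s_j]``; ``counts[i]`` is (number of exceedances,
    K) observed at threshold ``thresholds[i+1]`` under the conditional law
    above ``thresholds[i]``.  This is the flat-likelihood baseline the
    dual-criterion estimator improves upon.
    """
    cc, aa = cfg.grid()
    total = np.zeros_like(cc)
    for (n_exc, K), s_prev, s_cur in zip(counts, thresholds[:-1], thresholds[1:]):
        a_cond = aa + cc * s_prev
        sf = np.power(1.0 + cc * (s_cur - s_prev) / a_cond, -1.0 / cc)
        with np.errstate(divide="ignore"):
            total += n_exc * np.log(sf) + (K - n_exc) * np.log1p(-sf)
    total = np.where(np.isnan(total), -np.inf, total)
    order = np.lexsort((aa, cc, -total))
    best = order[0]
    return GPDParams(float(cc[best]), float(aa[best]))


def recover_initial(params_j: GPDParams, s_j: float) -> GPDParams:
    """Invert threshold conditioning: initial scale is ``a_j - c*s_j``.

    Raises ValueError when the recovered scale is nonpositive (the stage
    estimate is then incompatible with any unconditional GPD).
    """
    if s_j < 0:
        raise ValueError("s_j must be >= 0")
    a0 = params_j.a - params_j.c * s_j
    if a0 <= 0:
        raise ValueError(
            f"recovered initial scale {a0} <= 0 for params {params_j} at s={s_j}"
        )
    return GPDParams(params_j.c, a0)


def weibull_estimate_shape(
    thresholds: list[float],
    log_p_conds: list[float],
    bracket: tuple[float, float] = (0.1, 10.0),
) -> float:
    """Weibull shape from the three-level conditional log-survival identity.

    ``thresholds`` is the ladder ``[s_0=0, s_1, ..., s_j]`` and
    ``log_p_conds[i]`` the observed ``log p_hat`` of exceeding
    ``thresholds[i+1]`` given exceedance of ``thresholds[i]``.  Each
    consecutive triple yields one identity in the shape alone; with one
    triple the equation is solved by bracketed root finding, with several
    the summed squared log-discrepancy is minimized on the bracket.
    """
    if len(log_p_conds) < 2 or len(thresholds) < 3:
        raise ValueError("need at least two completed stages")

    triples = [
        (thresholds[i], thresholds[i + 1], thresholds[i + 2],
         log_p_conds[i], log_p_conds[i + 1])
        for i in range(len(log_p_conds) - 1)
    ]

    def discrepancy(b: float) -> np.ndarray:
        out = []
        for s0, s1, s2, lp_prev, lp_next in triples:
            num = s0**b - s2**b
            den = s0**b - s1**b
            out.append((num / den - 1.0) * lp_prev - lp_next)
        return np.asarray(out)

    if len(triples) == 1:
        f = lambda b: float(discrepancy(b)[0])
        lo, hi = bracket
        f_lo, f_hi = f(lo), f(hi)
        if f_lo * f_hi > 0:
            raise EstimationError(
                f"no sign change for the shape equation on [{lo}, {hi}]"
            )
        return float(optimize.brentq(f, lo, hi, xtol=1e-12))
    res = optimize.minimize_scalar(
        lambda b: float((discrepancy(b) ** 2).sum()),
        bounds=bracket,
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
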