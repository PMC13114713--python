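"""Comparator procedures: staircase (up-and-down), CRM, and de Valk.

These are the three reference methods the splitting design is measured
against.  The staircase and CRM operate on the same binary-exceedance data
as the splitting design but target the central tendency and moderate
quantile levels respectively; de Valk's estimator operates on *complete*
samples and serves as an idealized upper bound on achievable accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


# --------------------------------------------------------------------------
# Staircase (Dixon-Mood up-and-down) method
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseConfig:
    """Up-and-down design: start at s_ini, step +/- delta, K trials.

    ``latent_model`` is "exponential" (params: rate) or "gaussian"
    (params: mu, sigma).  A *failure* is the event R <= s (the specimen
    breaks at the applied level); the level is increased after a survival
    and decreased after a failure.
    """

    s_ini: float
    delta: float
    K: int
    latent_model: str = "exponential"
    latent_params: tuple[float, ...] = (0.2,)

    def __post_init__(self) -> None:
        if not (self.delta > 0):
            raise ValueError("delta must be > 0")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.latent_model not in ("exponential", "gaussian"):
            raise ValueError(f"unknown latent model {self.latent_model!r}")


def _failure_prob(model: str, params, s) -> np.ndarray:
    """P(R <= s) of the latent resistance model."""
    s = np.asarray(s, dtype=float)
    if model == "exponential":
        (rate,) = params
        return -np.expm1(-rate * np.maximum(s, 0.0))
    mu, sigma = params
    return stats.norm.cdf((s - mu) / sigma)


def staircase_run(
    cfg: StaircaseConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate K sequential up-and-down trials.

    Returns the visited levels and the binary outcomes (1 = failure).
    Levels are floored at 0 for the nonnegative exponential model; the
    Gaussian model may walk through negative levels.
    """
    levels = np.empty(cfg.K)
    outcomes = np.empty(cfg.K, dtype=np.int8)
    s = cfg.s_ini
    for i in range(cfg.K):
        levels[i] = s
        fail = rng.random() < _failure_prob(cfg.latent_model, cfg.latent_params, s)
        outcomes[i] = fail
        s = s - cfg.delta if fail else s + cfg.delta
        if cfg.latent_model == "exponential":
            s = max(s, 0.0)
    return levels, outcomes


def staircase_mle(levels, outcomes, latent_model: str = "exponential"):
    """Binary (quantal-response) maximum likelihood on the staircase record.

    Exponential: solves the scalar score equation for the rate by bracketed
    root finding.  Gaussian: probit likelihood maximized over (mu, log
    sigma) with sigma box-constrained to [1e-3, 1e3].  Returns the
    parameter estimates and the implied 1e-3 latent quantile.  Raises on
    complete separation (no failures or no survivals).
    """
    levels = np.asarray(levels, dtype=float)
    outcomes = np.asarray(outcomes)
    if outcomes.sum() == 0 or outcomes.sum() == outcomes.size:
        raise ValueError("separation: need at least one failure and one survival")

    if latent_model == "exponential":
        fail_levels = levels[(outcomes == 1) & (levels > 0)]
        surv_levels = levels[(outcomes == 0) & (levels > 0)]
        if fail_levels.size == 0 or surv_levels.sum() == 0:
            # no failures, or every survival sat at the zero-stress floor:
            # the score equation has no interior root
            raise ValueError("degenerate staircase record for exponential MLE")

        def score(lam: float) -> float:
            # d/dlam of sum y*log(1-e^(-lam s)) - (1-y)*lam*s
            with np.errstate(over="ignore"):
                t = fail_levels * np.exp(-lam * fail_levels) / (
                    -np.expm1(-lam * fail_levels)
                )
            return float(t.sum() - surv_levels.sum())

        lo, hi = 1e-8, 1e4
        if score(lo) <= 0 or score(hi) >= 0:
            raise ValueError("degenerate staircase record for exponential MLE")
        lam = optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-12)
        q = -np.log1p(-1e-3) / lam
        return {"rate": float(lam), "q_alpha": float(q)}

    if latent_model != "gaussian":
        raise ValueError(f"unknown latent model {latent_model!r}")

    def negloglik(theta):
        mu, log_sigma = theta
        sigma = np.exp(np.clip(log_sigma, np.log(1e-3), np.log(1e3)))
        p = stats.norm.cdf((levels - mu) / sigma)
        p = np.clip(p, 1e-300, 1 - 1e-16)
        return -float(
            np.sum(outcomes * np.log(p) + (1 - outcomes) * np.log1p(-p))
        )

    x0 = np.array([levels.mean(), np.log(max(levels.std(), 1e-2))])
    res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    mu, sigma = float(res.x[0]), float(np.exp(np.clip(res.x[1], np.log(1e-3), np.log(1e3))))
    q = mu + sigma * stats.norm.ppf(1e-3)
    return {"mu": mu, "sigma": sigma, "q_alpha": float(q)}


# --------------------------------------------------------------------------
# Continual Reassessment Method (CRM)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CRMConfig:
    """CRM under the exponential latent model with a Beta prior.

    The prior Beta(k, n-k+1) on the failure probability at the prior level
    reads "we expect k failures out of n trials there".  Each iteration
    performs ``J_per_iter`` trials at the currently selected level; the rate
    is summarized by the Monte-Carlo mean of -log(1-pi)/s over L posterior
    draws.
    """

    levels: tuple[float, ...]
    prior_k: float = 2.0
    prior_n: float = 10.0
    L: int = 1000
    J_per_iter: int = 50
    N_iter: int = 10
    alpha_target: float = 1e-3
    prior_level: float | None = None     # default: median of levels

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.size == 0 or np.any(np.diff(lv) <= 0):
            raise ValueError("levels must be nonempty and strictly increasing")
        if not (0 < self.prior_k < self.prior_n):
            raise ValueError("need 0 < prior_k < prior_n")


def crm_lambda_draw(pi_s, s: float):
    """Exponential rate implied by failure probability pi_s at level s."""
    pi_s = np.asarray(pi_s, dtype=float)
    if np.any((pi_s <= 0) | (pi_s >= 1)):
        raise ValueError("pi_s must be strictly inside (0, 1)")
    if not (s > 0):
        raise ValueError("s must be > 0")
    out = -np.log1p(-pi_s) / s
    return out if out.ndim else float(out)


def crm_posterior(
    prior_k: float, prior_n: float, cum_failures: int, cum_trials: int
) -> tuple[float, float]:
    """Beta posterior pseudo-counts after pooling all trials so far.

    Beta(k + F, n + T - (k + F) + 1) for F failures in T trials.
    """
    if cum_failures > cum_trials:
        raise ValueError("cum_failures cannot exceed cum_trials")
    a = prior_k + cum_failures
    b = prior_n + cum_trials - a + 1
    return float(a), float(b)


def crm_select_level(lambda_bar: float, levels, alpha_target: float) -> float:
    """Level whose model failure probability is closest to the target.

    Minimizes |1 - exp(-lambda_bar * s_j) - alpha_target|; ties go to the
    smaller level.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("levels must be nonempty")
    gap = np.abs(-np.expm1(-lambda_bar * levels) - alpha_target)
    return float(levels[np.argmin(gap)])   # argmin takes the first (smallest) tie


def crm_run(
    cfg: CRMConfig, true_rate: float, rng: np.random.Generator
) -> dict:
    """Full CRM run against an exponential(true_rate) latent resistance.

    Returns the trajectory of selected levels and the final quantile
    estimate (the last selected level, per the arginf estimator).
    """
    prior_level = cfg.prior_level if cfg.prior_level is not None else float(
        np.median(np.asarray(cfg.levels))
    )
    draws = stats.beta.rvs(cfg.prior_k, cfg.prior_n - cfg.prior_k + 1,
                           size=cfg.L, random_state=rng)
    lambda_bar = float(np.mean(crm_lambda_draw(draws, prior_level)))
    level = crm_select_level(lambda_bar, cfg.levels, cfg.alpha_target)

    cum_fail, cum_trials = 0, 0
    trajectory = []
    for _ in range(cfg.N_iter):
        y = rng.random(cfg.J_per_iter) < _failure_prob(
            "exponential", (true_rate,), level
        )
        cum_fail += int(y.sum())
        cum_trials += cfg.J_per_iter
        a, b = crm_posterior(cfg.prior_k, cfg.prior_n, cum_fail, cum_trials)
        draws = stats.beta.rvs(a, b, size=cfg.L, random_state=rng)
        lambda_bar = float(np.mean(crm_lambda_draw(draws, level)))
        level = crm_select_level(lambda_bar, cfg.levels, cfg.alpha_target)
        trajectory.append(level)

    return {
        "q_alpha_est": trajectory[-1],
        "lambda_bar": lambda_bar,
        "trajectory": trajectory,
        "cum_failures": cum_fail,
        "cum_trials": cum_trials,
    }


# --------------------------------------------------------------------------
# de Valk's complete-data extreme quantile estimator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DeValkConfig:
    """Complete-data extrapolation settings.

    ``l_n`` is the intermediate order count (default floor(n/10) at call
    time when set to None); ``theta`` is the tail-regularity exponent (1
    for Pareto-type tails); ``g_slope`` is the slope c of the regularity
    function g(x) = c*x, or "estimate" for the Hill estimator on the top
    l_n + 1 order statistics.
    """

    l_n: int | None = None
    theta: float = 1.0
    g_slope: float | str = "estimate"
    g_form: str = "linear"              # g(x) = slope*x, or "const": g(x) = slope

    def __post_init__(self) -> None:
        if self.g_form not in ("linear", "const"):
            raise ValueError(f"unknown g_form {self.g_form!r}")


def devalk_theta_sum(k: int, n: int) -> float:
    """Harmonic tail sum ``sum_{j=k}^{n} 1/j``."""
    if not (1 <= k <= n):
        raise ValueError("need 1 <= k <= n")
    return float(np.sum(1.0 / np.arange(k, n + 1)))


def hill_estimator(sample, k: int) -> float:
    """Hill tail-index estimate from the top k+1 order statistics."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if not (1 <= k < n):
        raise ValueError("need 1 <= k < n")
    top = x[n - k:]
    return float(np.mean(np.log(top)) - np.log(x[n - k - 1]))


def _h_theta(lam: float, theta: float) -> float:
    if theta == 0:
        return float(np.log(lam))
    return (lam**theta - 1.0) / theta


def devalk_quantile(sample, z: float, cfg: DeValkConfig = DeValkConfig()) -> float:
    """de Valk extreme quantile estimate at exceedance probability e^(-z).

    ``X_{n-l:n} * exp( g(theta_sum(l, n)) * h_theta(z / theta_sum(l+1, n)) )``
    with g(x) = c*x; c is taken from the config or Hill-estimated.  The
    anchor is the intermediate order statistic X_{n-l:n}.
    """
    if not (z > 0):
        raise ValueError("z must be > 0")
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    l_n = cfg.l_n if cfg.l_n is not None else n // 10
    if not (1 <= l_n < n):
        raise ValueError(f"l_n={l_n} out of range for n={n}")
    anchor = x[n - l_n - 1]          # X_{n-l_n:n}, 1-based order statistic
    if cfg.g_slope == "estimate":
        c = hill_estimator(x, l_n)
    else:
        c = float(cfg.g_slope)
    th_l = devalk_theta_sum(l_n, n)
    th_l1 = devalk_theta_sum(l_n + 1, n)
    g_val = c * th_l if cfg.g_form == "linear" else c
    return float(anchor * np.exp(g_val * _h_theta(z / th_l1, cfg.theta)))
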