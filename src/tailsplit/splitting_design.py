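"""Sequential splitting design for extreme quantile estimation.

The target risk level alpha (typically 1e-3) is decomposed into a product
of m moderate conditional exceedance probabilities along an increasing
ladder of thresholds on the reciprocal-resistance scale:

    alpha = P(R~ > s~_1) * prod_j P(R~ > s~_{j+1} | R~ > s~_j),

each factor held near a target level p (typically 0.2-0.3).  At each stage
K binary exceedance indicators are sampled under the conditional law above
the previous threshold, the model parameters are re-estimated from the
binary record, and the next threshold is set to the (1-p)-quantile of the
estimated conditional law.  The final threshold s~_m estimates the
(1-alpha)-quantile of R~, hence 1/s~_m estimates the alpha-quantile of the
resistance R itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import estimation as est
from .tail_models import (
    GPDParams,
    WeibullParams,
    gpd_condition,
    gpd_quantile,
    gpd_sf,
    weibull_quantile,
    weibull_sf,
)

DEFAULT_GAMMA = 0.2  # complement of the 0.8 confidence level of the admissible set


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child stream keyed by (seed, *key).

    Uses numpy's SeedSequence spawn keys so that streams for different
    (replica, stage) keys are independent and insensitive to how many draws
    other streams consumed.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# --------------------------------------------------------------------------
# Configuration and result containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignConfig:
    """Everything needed to run one sequential design.

    ``m`` defaults to the conservative stage count ceil(log alpha / log p);
    ``gamma`` is the complement of the admissible-interval confidence level
    (0.2 for the 0.8 level used throughout); ``s1_tilde`` is the initial
    threshold on the reciprocal scale, in practice supplied by expert
    knowledge of the medium-stress regime.
    """

    alpha: float = 1e-3
    p: float = 0.25
    K: int = 50
    s1_tilde: float = 1.0
    m: int | None = None
    gamma: float = DEFAULT_GAMMA
    model: str = "gpd"
    search_box: tuple[float, float, float, float] = est.DEFAULT_SEARCH_BOX
    grid_size: int = 200
    refine: bool = True
    shape_bracket: tuple[float, float] = (0.1, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < self.p < 1):
            raise ValueError("need 0 < alpha < p < 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 < self.gamma < 1):
            raise ValueError("gamma must be in (0, 1)")
        if not (self.s1_tilde > 0):
            raise ValueError("s1_tilde must be > 0")
        if self.model not in ("gpd", "weibull"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.m is not None and self.m < 2:
            raise ValueError("m must be >= 2")

    @property
    def n_stages(self) -> int:
        return self.m if self.m is not None else conservative_stage_count(self.alpha, self.p)

    def estimator_config(self) -> est.EstimatorConfig:
        return est.EstimatorConfig(
            search_box=self.search_box, grid_size=self.grid_size, refine=self.refine
        )


@dataclass
class StageRecord:
    """Audit record of one stage of the design."""

    stage_index: int
    threshold: float
    outcomes: np.ndarray
    p_hat: float                         # raw empirical exceedance fraction
    p_hat_safe: float                    # Anscombe-shrunk when p_hat is 0 or 1
    interval: est.AdmissibleInterval | None
    est_params: GPDParams | WeibullParams | None
    objective_value: float | None

    def __post_init__(self) -> None:
        if abs(self.p_hat - float(np.mean(self.outcomes))) > 1e-12:
            raise ValueError("p_hat must equal mean(outcomes)")


@dataclass
class SplittingResult:
    """Full outcome of one sequential run."""

    ladder: list[float]
    q_tilde_est: float
    q_est: float
    alpha_attained: float
    stages: list[StageRecord]
    initial_params_est: GPDParams | WeibullParams | None
    p_adjusted: float
    config: DesignConfig = field(repr=False, default=None)


class SplittingRunError(RuntimeError):
    """Estimation failed mid-run; carries the completed stage records."""

    def __init__(self, message: str, stages: list[StageRecord]):
        super().__init__(message)
        self.stages = stages


# --------------------------------------------------------------------------
# Elementary design operations
# --------------------------------------------------------------------------

def conservative_stage_count(alpha: float, p: float) -> int:
    """Smallest m with p^m <= alpha: ceil(log alpha / log p).

    alpha == p is the degenerate one-stage design.
    """
    if not (0 < alpha <= p < 1):
        raise ValueError("need 0 < alpha <= p < 1")
    return math.ceil(math.log(alpha) / math.log(p))


def next_threshold(est_params: GPDParams, s_prev: float, p: float) -> float:
    """Next GPD ladder point: (1-p)-quantile of the conditional law + s_prev.

    ``est_params`` must already be the parameters of the conditional law of
    the excess above ``s_prev``.
    """
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    return gpd_quantile(1.0 - p, est_params) + s_prev


def weibull_next_threshold(
    s_prevprev: float, s_prev: float, shape: float, p: float, p_hat_prev: float
) -> float:
    """Next Weibull ladder point from the three-level conditional identity.

    Solves ``log p = [(s_pp^b - s_next^b)/(s_pp^b - s_prev^b) - 1] * log
    p_hat_prev`` for s_next, where ``p_hat_prev`` estimates the conditional
    probability of exceeding ``s_prev`` given exceedance of ``s_prevprev``
    (with the convention s_prevprev = 0 for the first step).
    """
    if not (0 <= s_prevprev < s_prev):
        raise ValueError("need 0 <= s_prevprev < s_prev")
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    if not (0 < p_hat_prev < 1):
        raise ValueError("p_hat_prev in {0,1}: degenerate stage data")
    b = shape
    ratio = math.log(p) / math.log(p_hat_prev)
    radicand = s_prevprev**b - (1.0 + ratio) * (s_prevprev**b - s_prev**b)
    if radicand <= s_prev**b:
        raise ValueError(
            f"infeasible geometry: radicand {radicand} does not exceed s_prev^b"
        )
    return radicand ** (1.0 / b)


def _true_sf(params, x: float) -> float:
    if isinstance(params, GPDParams):
        return gpd_sf(x, params)
    return weibull_sf(x, params)


def sample_stage(
    true_params, s_cur: float, s_prev: float, K: int, rng: np.random.Generator
) -> np.ndarray:
    """K Bernoulli exceedance indicators of s_cur under the law above s_prev.

    The success probability is the closed-form conditional survival
    P(R~ > s_cur | R~ > s_prev) of the *true* model; this is the synthetic
    stand-in for physically testing K weakened specimens.
    """
    if not (s_cur >= s_prev >= 0):
        raise ValueError("need s_cur >= s_prev >= 0")
    p_cond = _true_sf(true_params, s_cur) / _true_sf(true_params, s_prev)
    return (rng.random(K) < p_cond).astype(np.int8)


def attained_alpha(p_hat_1: float, p: float, m: int) -> float:
    """The probability level actually reached: p_hat_1 * p^(m-1)."""
    if not (0 < p_hat_1 <= 1 and 0 < p <= 1):
        raise ValueError("probabilities must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return p_hat_1 * p ** (m - 1)


def adjust_p(alpha: float, p_hat_1: float, m: int) -> float:
    """Per-stage level making p_hat_1 * p^(m-1) = alpha, clipped to (0.01, 0.99)."""
    if m < 2:
        raise ValueError("m must be >= 2")
    return float(np.clip((alpha / p_hat_1) ** (1.0 / (m - 1)), 0.01, 0.99))


def _safe_p(outcomes) -> tuple[float, float]:
    p_raw = est.empirical_p(outcomes)
    p_safe = p_raw if 0.0 < p_raw < 1.0 else est.shrunk_p(outcomes)
    return p_raw, p_safe


# --------------------------------------------------------------------------
# Full sequential runs
# --------------------------------------------------------------------------

def run_splitting(
    config: DesignConfig,
    true_params,
    rng: np.random.Generator | None = None,
    estimator: str = "dual",
    oracle: bool = False,
) -> SplittingResult:
    """Execute one full sequential design run.

    ``true_params`` drive the trial simulator only; the estimators never
    read them.  ``estimator`` selects the dual-criterion procedure
    ("dual") or the naive cumulative Bernoulli maximum likelihood ("ml").
    With ``oracle=True`` the estimator is replaced by the true parameters
    and every empirical probability by its exact value — a noise-free
    self-consistency mode used for telescoping checks.
    """
    if config.model == "weibull":
        return _run_weibull(config, true_params, rng, oracle=oracle)
    if estimator not in ("dual", "ml"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if rng is None:
        rng = child_rng(config.seed)
    m, K = config.n_stages, config.K
    cfg = config.estimator_config()
    seeds = rng.integers(0, 2**31 - 1)  # replica-level entropy for stage streams
    stage_rngs = [child_rng(int(seeds), j) for j in range(m + 1)]

    ladder = [config.s1_tilde]
    stages: list[StageRecord] = []

    # ---- stage 1: unconditional trials at s~_1 ----
    if oracle:
        p1_raw = p1_safe = gpd_sf(config.s1_tilde, true_params)
        outcomes1 = np.array([], dtype=np.int8)
        theta0 = true_params
        interval1 = None
    else:
        outcomes1 = sample_stage(true_params, config.s1_tilde, 0.0, K, stage_rngs[1])
        p1_raw, p1_safe = _safe_p(outcomes1)
        interval1 = est.wald_interval(p1_safe, K, config.gamma)
        try:
            if estimator == "dual":
                theta0 = est.estimate_stage_one(config.s1_tilde, interval1, cfg)
            else:
                theta0 = est.ml_estimate(
                    [0.0, config.s1_tilde], [(int(outcomes1.sum()), K)], cfg
                )
        except est.EstimationError as exc:
            raise SplittingRunError(str(exc), stages) from exc
    if not oracle:
        stages.append(
            StageRecord(1, config.s1_tilde, outcomes1, p1_raw, p1_safe,
                        interval1, gpd_condition(theta0, config.s1_tilde), None)
        )
    # noise-free oracle keeps the nominal p so the ladder telescopes exactly
    p_adj = config.p if oracle else adjust_p(config.alpha, p1_safe, m)

    p_safe_prev = p1_safe
    for j in range(2, m + 1):
        s_prev = ladder[-1]
        s_new = next_threshold(gpd_condition(theta0, s_prev), s_prev, p_adj)
        ladder.append(s_new)
        if oracle:
            p_raw = p_safe = p_adj
            outcomes = np.array([], dtype=np.int8)
            theta0 = true_params
            p_safe_prev = p_safe
            continue
        outcomes = sample_stage(true_params, s_new, s_prev, K, stage_rngs[j])
        p_raw, p_safe = _safe_p(outcomes)
        interval = est.wald_interval(p_safe, K, config.gamma)
        s_jm2 = ladder[-3] if j > 2 else 0.0
        try:
            if estimator == "dual":
                theta0, obj = est.estimate_stage(
                    s_jm2, s_prev, s_new, p_safe_prev, interval, cfg,
                    gamma=config.gamma, p_hat_j=p_safe, K=K,
                )
            else:
                counts = [(int(r.outcomes.sum()), len(r.outcomes)) for r in stages]
                counts.append((int(outcomes.sum()), K))
                theta0 = est.ml_estimate([0.0] + ladder, counts, cfg)
                obj = None
        except est.EstimationError as exc:
            stages.append(StageRecord(j, s_new, outcomes, p_raw, p_safe,
                                      interval, None, None))
            raise SplittingRunError(str(exc), stages) from exc
        stages.append(
            StageRecord(j, s_new, outcomes, p_raw, p_safe, interval,
                        gpd_condition(theta0, s_new), obj)
        )
        p_safe_prev = p_safe

    q_tilde = ladder[-1]
    initial_est = None if oracle else theta0
    return SplittingResult(
        ladder=ladder,
        q_tilde_est=q_tilde,
        q_est=1.0 / q_tilde,
        alpha_attained=attained_alpha(p1_safe, p_adj, m),
        stages=stages,
        initial_params_est=initial_est,
        p_adjusted=p_adj,
        config=config,
    )


def _run_weibull(
    config: DesignConfig,
    true_params: WeibullParams,
    rng: np.random.Generator | None,
    oracle: bool = False,
) -> SplittingResult:
    """Weibull variant: only the shape enters the threshold recursion.

    The conditional log-survival identity is scale-free, so each new
    threshold needs only the shape estimate and the previous stage's
    empirical conditional probability.  The shape starts at a neutral prior
    guess (geometric center of the bracket) and is re-estimated from the
    accumulated (threshold, p_hat) history from stage 2 on.
    """
    if rng is None:
        rng = child_rng(config.seed)
    m, K = config.n_stages, config.K
    seeds = rng.integers(0, 2**31 - 1)
    stage_rngs = [child_rng(int(seeds), j) for j in range(m + 1)]
    lo, hi = config.shape_bracket
    shape_est = true_params.shape if oracle else float(np.sqrt(lo * hi))

    ladder = [config.s1_tilde]
    stages: list[StageRecord] = []
    log_p_conds: list[float] = []

    if oracle:
        p1_raw = p1_safe = weibull_sf(config.s1_tilde, true_params)
        outcomes1 = np.array([], dtype=np.int8)
        interval1 = None
    else:
        outcomes1 = sample_stage(true_params, config.s1_tilde, 0.0, K, stage_rngs[1])
        p1_raw, p1_safe = _safe_p(outcomes1)
        interval1 = est.wald_interval(p1_safe, K, config.gamma)
        stages.append(
            StageRecord(1, config.s1_tilde, outcomes1, p1_raw, p1_safe,
                        interval1, _implied_weibull(config.s1_tilde, p1_safe, shape_est),
                        None)
        )
    p_adj = config.p if oracle else adjust_p(config.alpha, p1_safe, m)
    log_p_conds.append(math.log(p1_safe))

    p_safe_prev = p1_safe
    for j in range(2, m + 1):
        s_prev = ladder[-1]
        s_prevprev = ladder[-2] if j > 2 else 0.0
        s_new = weibull_next_threshold(s_prevprev, s_prev, shape_est, p_adj, p_safe_prev)
        ladder.append(s_new)
        if oracle:
            p_safe_prev = p_adj
            log_p_conds.append(math.log(p_adj))
            continue
        outcomes = sample_stage(true_params, s_new, s_prev, K, stage_rngs[j])
        p_raw, p_safe = _safe_p(outcomes)
        interval = est.wald_interval(p_safe, K, config.gamma)
        log_p_conds.append(math.log(p_safe))
        try:
            shape_est = est.weibull_estimate_shape(
                [0.0] + ladder, log_p_conds, bracket=config.shape_bracket
            )
        except est.EstimationError as exc:
            stages.append(StageRecord(j, s_new, outcomes, p_raw, p_safe,
                                      interval, None, None))
            raise SplittingRunError(str(exc), stages) from exc
        stages.append(
            StageRecord(j, s_new, outcomes, p_raw, p_safe, interval,
                        _implied_weibull(config.s1_tilde, p1_safe, shape_est), None)
        )
        p_safe_prev = p_safe

    q_tilde = ladder[-1]
    initial_est = None if oracle else _implied_weibull(config.s1_tilde, p1_safe, shape_est)
    return SplittingResult(
        ladder=ladder,
        q_tilde_est=q_tilde,
        q_est=1.0 / q_tilde,
        alpha_attained=attained_alpha(p1_safe, p_adj, m),
        stages=stages,
        initial_params_est=initial_est,
        p_adjusted=p_adj,
        config=config,
    )


def _implied_weibull(s1: float, p1: float, shape: float) -> WeibullParams:
    """Plug-in Weibull: scale chosen so P(R~ > s1) matches p1 at this shape."""
    return WeibullParams(scale=s1 / (-math.log(p1)) ** (1.0 / shape), shape=shape)
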