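"""Policy-gradient learning of the global mixing weight alpha.

Alpha is the mean of a Beta(a, b) policy whose parameters are optimized by
the score-function (REINFORCE) estimator: each epoch, candidate alphas are
sampled from the policy, each candidate is scored by an endorsement-
agreement reward on a calibration batch, and (a, b) ascend the advantage-
weighted log-density gradient.  Two stability mechanisms: a warmup period
during which the policy is frozen, and a mild penalty lambda * (alpha_hat -
0.5)^2 on the policy mean that discourages collapse to either extreme
unless the endorsement data consistently supports it.

(a, b) are parametrized as softplus(theta) + floor so they stay positive
under unconstrained updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, expit

from .calibrator import binarize, to_probability
from .errors import NumericError

_FLOOR = 1e-3
_BASELINE_DECAY = 0.9


def _softplus(x: float) -> float:
    return float(np.logaddexp(0.0, x))


def _softplus_inv(y: float) -> float:
    # inverse of softplus for y > 0
    return float(np.log(np.expm1(y)))


@dataclass
class PolicyState:
    """Beta-policy parameters and bookkeeping for the alpha update."""

    theta_a: float = _softplus_inv(1.0 - _FLOOR)
    theta_b: float = _softplus_inv(1.0 - _FLOOR)
    baseline: float = 0.5
    lambda_reg: float = 0.05
    m_candidates: int = 8
    lr_policy: float = 0.2
    warmup_epochs: int = 100
    epoch_counter: int = 0

    @property
    def a(self) -> float:
        return _softplus(self.theta_a) + _FLOOR

    @property
    def b(self) -> float:
        return _softplus(self.theta_b) + _FLOOR

    @property
    def in_warmup(self) -> bool:
        return self.epoch_counter < self.warmup_epochs

    def to_checkpoint(self) -> dict:
        return {
            "theta_a": self.theta_a, "theta_b": self.theta_b,
            "a": self.a, "b": self.b, "baseline": self.baseline,
            "lambda_reg": self.lambda_reg, "m_candidates": self.m_candidates,
            "lr_policy": self.lr_policy, "warmup_epochs": self.warmup_epochs,
            "epoch_counter": self.epoch_counter,
        }


def policy_mean(state: PolicyState) -> float:
    """alpha_hat = a / (a + b): the reported, evaluation-time mixing weight."""
    return state.a / (state.a + state.b)


def sample_candidates(state: PolicyState, rng: np.random.Generator) -> np.ndarray:
    """m independent draws from Beta(a, b), clipped into the open unit
    interval (extreme shape parameters can round draws to exactly 0 or 1,
    where the log-density is undefined)."""
    draws = rng.beta(state.a, state.b, size=state.m_candidates)
    return np.clip(draws, 1e-9, 1.0 - 1e-9)


def compute_reward(p_blend: np.ndarray,
                   comm_labels: np.ndarray,
                   phys_labels: np.ndarray, phys_mask: np.ndarray,
                   alpha: float) -> float:
    """Alpha-weighted endorsement agreement of the binarized prediction.

    R = alpha * A_comm + (1 - alpha) * A_phys, where A_comm is the fraction
    of batch cases whose 0.5-cutoff recommendation matches the community
    label, and A_phys the same fraction over the physician-queried subset
    (0.5, neutral, if the subset is empty).
    """
    p_blend = np.asarray(p_blend)
    comm_labels = np.asarray(comm_labels)
    phys_labels = np.asarray(phys_labels)
    phys_mask = np.asarray(phys_mask, dtype=bool)
    if not (len(p_blend) == len(comm_labels) == len(phys_labels) == len(phys_mask)):
        raise ValueError("reward inputs must share length")
    rec = binarize(p_blend)
    a_comm = float((rec == comm_labels).mean())
    if phys_mask.any():
        a_phys = float((rec[phys_mask] == phys_labels[phys_mask]).mean())
    else:
        a_phys = 0.5
    return alpha * a_comm + (1.0 - alpha) * a_phys


def log_beta_pdf_grad(alpha: float, a: float, b: float) -> tuple[float, float]:
    """d/da and d/db of log BetaPDF(alpha; a, b)."""
    common = digamma(a + b)
    return (np.log(alpha) - digamma(a) + common,
            np.log(1.0 - alpha) - digamma(b) + common)


def policy_update(state: PolicyState,
                  candidates: np.ndarray,
                  rewards: np.ndarray) -> PolicyState:
    """One REINFORCE step on (theta_a, theta_b), with warmup and penalty.

    During warmup only the reward baseline and epoch counter advance; the
    policy parameters are untouched, so alpha_hat stays at its initial
    value exactly.  After warmup, theta ascends the mean advantage-weighted
    log-density gradient minus the gradient of lambda * (alpha_hat - 0.5)^2.
    """
    candidates = np.asarray(candidates, dtype=np.float64)
    rewards = np.asarray(rewards, dtype=np.float64)
    if candidates.shape != rewards.shape:
        raise ValueError("candidates and rewards must have equal length")

    mean_r = float(rewards.mean())
    if not state.in_warmup:
        a, b = state.a, state.b
        adv = rewards - state.baseline
        d_la, d_lb = log_beta_pdf_grad(candidates, a, b)
        g_a = float(np.mean(adv * d_la))
        g_b = float(np.mean(adv * d_lb))

        # penalty lambda*(mean-0.5)^2 on alpha_hat = a/(a+b)
        mean = a / (a + b)
        dmean_da = b / (a + b) ** 2
        dmean_db = -a / (a + b) ** 2
        pen = 2.0 * state.lambda_reg * (mean - 0.5)
        g_a -= pen * dmean_da
        g_b -= pen * dmean_db

        # chain through softplus
        g_ta = g_a * expit(state.theta_a)
        g_tb = g_b * expit(state.theta_b)
        if not (np.isfinite(g_ta) and np.isfinite(g_tb)):
            raise NumericError(
                f"non-finite policy gradient (state={state.to_checkpoint()})"
            )
        state.theta_a += state.lr_policy * g_ta
        state.theta_b += state.lr_policy * g_tb

    state.baseline = _BASELINE_DECAY * state.baseline + (1 - _BASELINE_DECAY) * mean_r
    state.epoch_counter += 1
    return state


def candidate_rewards(s_comm: np.ndarray, s_phys: np.ndarray,
                      comm_labels: np.ndarray,
                      phys_labels: np.ndarray, phys_mask: np.ndarray,
                      alphas: np.ndarray) -> np.ndarray:
    """Reward of each candidate alpha on one calibration batch.

    The blended prediction is recomputed per candidate, so the reward
    depends on alpha both through the mixture weights and through the
    binarized prediction itself.
    """
    out = np.empty(len(alphas))
    for j, alpha in enumerate(np.asarray(alphas, dtype=np.float64)):
        p = to_probability(alpha * s_comm + (1.0 - alpha) * s_phys)
        out[j] = compute_reward(p, comm_labels, phys_labels, phys_mask, alpha)
    return out
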