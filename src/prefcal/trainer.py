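"""Training loop orchestration and held-out evaluation.

Each epoch: shuffle the training split; per batch, query the physician
subset, draw both endorsement streams' labels, and take one supervised step
on the shared predictor; after the batches, sample candidate alphas, score
each by endorsement agreement on a seeded calibration batch, and update the
Beta policy (no-op during warmup).  Evaluation uses the policy mean
alpha_hat (0.5 during warmup, or a caller-fixed alpha for offline sweeps)
and reports MSE/MAE against the true outcome plus stakeholder-specific MAE.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alpha_policy, calibrator, syngen
from .errors import ConfigError

WARMUP_ALPHA = 0.5


@dataclass
class RunConfig:
    """Settings of one training run; fully determines it together with seed."""

    epochs: int = 300
    batch_size: int = 128
    lr_net: float = 1e-3
    lr_policy: float = 0.2
    seed: int = 0
    generator: syngen.GeneratorConfig = field(default_factory=syngen.GeneratorConfig)
    feedback: syngen.FeedbackParams = field(default_factory=syngen.FeedbackParams)
    dropout_rate: float = 0.1
    lambda_reg: float = 0.05
    m_candidates: int = 8
    warmup_epochs: int = 100
    eval_window: int = 50

    def validate(self, policy_enabled: bool = True) -> None:
        if self.epochs < 1:
            raise ConfigError(f"epochs must be positive, got {self.epochs!r}")
        if policy_enabled and self.epochs <= self.warmup_epochs:
            raise ConfigError(
                f"epochs ({self.epochs}) must exceed warmup_epochs "
                f"({self.warmup_epochs}) for a policy run"
            )
        if self.batch_size < 1:
            raise ConfigError(f"batch_size must be positive, got {self.batch_size!r}")
        for name in ("lr_net", "lr_policy"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.eval_window < 1:
            raise ConfigError("eval_window must be positive")


METRIC_COLUMNS = ["epoch", "mse", "mae", "mae_comm", "mae_phys",
                  "reward", "alpha_hat", "loss", "a", "b", "baseline"]


@dataclass
class RunResult:
    """Per-epoch metrics plus final parameters of one run."""

    metrics: pd.DataFrame
    final_params: calibrator.NetParams
    final_policy: alpha_policy.PolicyState
    config: RunConfig

    def plateau(self, metric: str, window: int | None = None) -> float:
        """Mean of a metric over the trailing evaluation window."""
        w = window if window is not None else self.config.eval_window
        return float(self.metrics[metric].tail(w).mean())


def evaluate(params: calibrator.NetParams, alpha: float,
             sset: syngen.ScenarioSet) -> tuple[float, float]:
    """Held-out MSE and MAE of the blended probability vs the true outcome."""
    test = sset.test_idx
    if len(test) == 0:
        raise ConfigError("scenario set has an empty test split")
    p = predict(params, alpha, sset, test)
    y = sset.outcomes[test]
    return float(np.mean((p - y) ** 2)), float(np.mean(np.abs(p - y)))


def predict(params: calibrator.NetParams, alpha: float,
            sset: syngen.ScenarioSet, idx: np.ndarray) -> np.ndarray:
    """Eval-mode blended probability for the given case indices."""
    mode = params.mode
    params.mode = "eval"
    try:
        s_c = calibrator.stream_score(sset.comm_embed[idx], params)
        s_p = calibrator.stream_score(sset.phys_embed[idx], params)
    finally:
        params.mode = mode
    return calibrator.to_probability(calibrator.blend_scores(s_c, s_p, alpha))


def stakeholder_mae(p_blend: np.ndarray, labels: np.ndarray,
                    mask: np.ndarray | None = None) -> float:
    """Mean |p - label| over the (optionally masked) cases; NaN if none."""
    p_blend = np.asarray(p_blend, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return float("nan")
        p_blend, labels = p_blend[mask], labels[mask]
    return float(np.mean(np.abs(p_blend - labels)))


def train_run(cfg: RunConfig,
              scenarios: syngen.ScenarioSet | None = None,
              fixed_alpha: float | None = None) -> RunResult:
    """Run the full loop; deterministic given cfg (and cfg.generator.seed).

    ``fixed_alpha`` disables the policy and blends at that constant alpha
    throughout (used by offline alpha sweeps).
    """
    policy_enabled = fixed_alpha is None
    cfg.validate(policy_enabled=policy_enabled)
    if fixed_alpha is not None and not 0.0 <= fixed_alpha <= 1.0:
        raise ConfigError(f"fixed_alpha must lie in [0, 1], got {fixed_alpha!r}")

    sset = scenarios if scenarios is not None else syngen.generate_scenarios(cfg.generator)
    train_idx = sset.train_idx
    if cfg.batch_size > len(train_idx):
        raise ConfigError(
            f"batch_size ({cfg.batch_size}) exceeds training-set size ({len(train_idx)})"
        )

    ss = np.random.SeedSequence(cfg.seed)
    rng_init, rng_labels, rng_train, rng_policy, rng_cal = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    params = calibrator.init_params(cfg.generator.embed_dim, rng_init,
                                    dropout_rate=cfg.dropout_rate)
    opt = calibrator.AdamState()
    policy = alpha_policy.PolicyState(
        lambda_reg=cfg.lambda_reg, m_candidates=cfg.m_candidates,
        lr_policy=cfg.lr_policy, warmup_epochs=cfg.warmup_epochs,
    )

    # community labels are drawn once per case and fixed across epochs
    comm_labels = syngen.draw_community_labels(sset, cfg.feedback.sigma_comm, rng_labels)

    fb = cfg.feedback
    rows = []
    last_queried: np.ndarray | None = None
    for epoch in range(cfg.epochs):
        if fixed_alpha is not None:
            alpha_used = fixed_alpha
        elif policy.in_warmup:
            alpha_used = WARMUP_ALPHA
        else:
            alpha_used = alpha_policy.policy_mean(policy)

        # --- supervised phase ------------------------------------------
        perm = rng_train.permutation(train_idx)
        losses = []
        params.mode = "train"
        for start in range(0, len(perm), cfg.batch_size):
            batch = perm[start:start + cfg.batch_size]
            k = min(fb.k_queries, len(batch))
            queried = syngen.query_physician(batch, k, rng_train)
            mask = np.isin(batch, queried)
            phys_batch = np.zeros(len(batch), dtype=np.int64)
            phys_batch[mask] = syngen.draw_physician_labels(
                sset.labels[batch[mask]], fb.beta_phys, rng_train)
            params, loss = calibrator.supervised_step(
                params, sset.comm_embed[batch], sset.phys_embed[batch],
                comm_labels[batch], phys_batch, mask,
                cfg.lr_net, rng_train, opt)
            losses.append(loss)
            last_queried = batch[mask]

        # --- policy phase ----------------------------------------------
        cal = rng_cal.choice(train_idx, size=min(cfg.batch_size, len(train_idx)),
                             replace=False)
        params.mode = "eval"
        s_c = calibrator.stream_score(sset.comm_embed[cal], params)
        s_p = calibrator.stream_score(sset.phys_embed[cal], params)
        k = min(fb.k_queries, len(cal))
        cal_q = syngen.query_physician(cal, k, rng_cal)
        cal_mask = np.isin(cal, cal_q)
        cal_phys = np.zeros(len(cal), dtype=np.int64)
        cal_phys[cal_mask] = syngen.draw_physician_labels(
            sset.labels[cal[cal_mask]], fb.beta_phys, rng_cal)

        if policy_enabled and not policy.in_warmup:
            cands = alpha_policy.sample_candidates(policy, rng_policy)
        else:
            cands = np.array([alpha_used])
        rewards = alpha_policy.candidate_rewards(
            s_c, s_p, comm_labels[cal], cal_phys, cal_mask, cands)
        if policy_enabled:
            policy = alpha_policy.policy_update(policy, cands, rewards)

        # --- evaluation -------------------------------------------------
        if policy_enabled:
            alpha_eval = (WARMUP_ALPHA if policy.epoch_counter <= cfg.warmup_epochs
                          else alpha_policy.policy_mean(policy))
        else:
            alpha_eval = fixed_alpha
        mse, mae = evaluate(params, alpha_eval, sset)
        test = sset.test_idx
        p_test = predict(params, alpha_eval, sset, test)
        mae_comm = stakeholder_mae(p_test, comm_labels[test])
        if last_queried is not None and len(last_queried) > 0:
            p_q = predict(params, alpha_eval, sset, last_queried)
            mae_phys = stakeholder_mae(p_q, sset.labels[last_queried])
        else:
            mae_phys = float("nan")

        rows.append({
            "epoch": epoch, "mse": mse, "mae": mae,
            "mae_comm": mae_comm, "mae_phys": mae_phys,
            "reward": float(np.mean(rewards)),
            "alpha_hat": alpha_eval, "loss": float(np.mean(losses)),
            "a": policy.a, "b": policy.b, "baseline": policy.baseline,
        })

    params.mode = "eval"
    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    return RunResult(metrics=metrics, final_params=params,
                     final_policy=policy, config=cfg)


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    if "generator" in d and isinstance(d["generator"], dict):
        d["generator"] = syngen.GeneratorConfig(**d["generator"])
    if "feedback" in d and isinstance(d["feedback"], dict):
        d["feedback"] = syngen.FeedbackParams(**d["feedback"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown run-config key(s): {sorted(unknown)}")
    return RunConfig(**d)
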