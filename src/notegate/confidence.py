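"""Feature-level confidence: aggregation, adjustments, feedback, threshold.

A generative extractor emits per-token probabilities; training-time
regularization needs a single, well-behaved confidence per extracted
feature. Three adjustments make the raw softmax signal usable:

1. length-normalized averaging — the geometric mean of token
   probabilities, which is simultaneously an average and invariant to
   sequence length for constant per-token probability;
2. complexity adjustment — longer rubric features are harder, so
   confidence is shrunk as ``c ** (1 + n_tokens / lambda)`` with
   ``lambda = 20`` by default;
3. stochastic injection — seeded additive Gaussian noise with standard
   deviation ``beta * noise_base_sd`` (``beta = 0.2``) keeps the
   confidence distribution from collapsing to a narrow band during
   training; it is off at inference.

Epoch-level machinery: an EMA feedback loop (coefficient ``alpha = 0.7``)
smooths confidence across epochs, and a dynamic threshold ``tau`` rises
from 0.6 to 0.7 over training for curriculum-like penalty gating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class ConfidenceConfig:
    """Parameters of the confidence pipeline (defaults per the framework)."""

    beta_noise: float = 0.2
    noise_base_sd: float = 0.05
    lambda_complexity: float = 20.0
    alpha_feedback: float = 0.7
    tau_init: float = 0.6
    tau_final: float = 0.7
    clip_eps: float = 1e-4
    seed: int = 0
    use_geometric_mean: bool = True
    f1_coupled_threshold: bool = False

    def __post_init__(self) -> None:
        if self.beta_noise < 0:
            raise ValueError("beta_noise must be >= 0")
        if self.lambda_complexity <= 0:
            raise ValueError("lambda_complexity must be > 0")
        if not (0.0 <= self.alpha_feedback <= 1.0):
            raise ValueError("alpha_feedback must be in [0, 1]")
        if self.tau_init > self.tau_final:
            raise ValueError("tau_init must be <= tau_final")


@dataclass(frozen=True)
class EpochState:
    """Where training stands: epoch counter, last F1, smoothed confidence."""

    epoch_index: int = 0
    total_epochs: int = 1
    prev_f1: float | None = None
    smoothed_confidence: float | None = None

    def __post_init__(self) -> None:
        if self.total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")
        if not (0 <= self.epoch_index < self.total_epochs):
            raise ValueError("epoch_index must be in [0, total_epochs)")

    def advance(
        self, f1: float | None = None, smoothed_confidence: float | None = None
    ) -> "EpochState":
        """Next-epoch state (clamped at the final epoch)."""
        return replace(
            self,
            epoch_index=min(self.epoch_index + 1, self.total_epochs - 1),
            prev_f1=f1 if f1 is not None else self.prev_f1,
            smoothed_confidence=(
                smoothed_confidence
                if smoothed_confidence is not None
                else self.smoothed_confidence
            ),
        )


def aggregate_confidence(
    token_probs: list[float] | tuple[float, ...], *, geometric: bool = True
) -> float:
    """Length-normalized average of token probabilities.

    Geometric mean ``exp(mean(log p))`` by default; the arithmetic mean is
    available for sensitivity analysis. Requires a non-empty sequence with
    every value in (0, 1].
    """
    if len(token_probs) == 0:
        raise ValueError("token_probs must be non-empty")
    for p in token_probs:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"token probability {p} outside (0, 1]")
    if geometric:
        return float(math.exp(sum(math.log(p) for p in token_probs) / len(token_probs)))
    return float(sum(token_probs) / len(token_probs))


def complexity_adjust(c: float, feature_token_count: int, lambda_complexity: float = 20.0) -> float:
    """Shrink confidence for longer features: ``c ** (1 + count / lambda)``.

    Identity at count 0 and at c = 1; preserves ordering and (0, 1].
    """
    if lambda_complexity <= 0:
        raise ValueError("lambda_complexity must be > 0")
    if not (0.0 < c <= 1.0):
        raise ValueError(f"confidence {c} outside (0, 1]")
    if feature_token_count < 0:
        raise ValueError("feature_token_count must be >= 0")
    return float(c ** (1.0 + feature_token_count / lambda_complexity))


def inject_noise(
    c: float, cfg: ConfidenceConfig, rng: np.random.Generator | None
) -> float:
    """Add seeded Gaussian noise ``beta * noise_base_sd * z``, clipped.

    Identity when ``rng`` is None (inference) or ``beta_noise == 0``.
    Output clipped to ``[clip_eps, 1 - clip_eps]``.
    """
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"confidence {c} outside [0, 1]")
    if rng is None or cfg.beta_noise == 0.0:
        return c
    noisy = c + cfg.beta_noise * cfg.noise_base_sd * rng.standard_normal()
    return float(min(1.0 - cfg.clip_eps, max(cfg.clip_eps, noisy)))


def dynamic_threshold(state: EpochState, cfg: ConfidenceConfig) -> float:
    """Curriculum threshold tau for the overconfidence penalty gate.

    Linear-in-epoch by default: tau rises from ``tau_init`` at epoch 0 to
    ``tau_final`` at the last epoch. With ``f1_coupled_threshold`` and a
    recorded previous-epoch F1, tau interpolates on that F1 instead.
    Always within ``[tau_init, tau_final]``; a single-epoch schedule uses
    ``tau_final``.
    """
    lo, hi = cfg.tau_init, cfg.tau_final
    if cfg.f1_coupled_threshold and state.prev_f1 is not None:
        tau = lo + (hi - lo) * state.prev_f1
        return float(min(hi, max(lo, tau)))
    if state.total_epochs == 1:
        return hi
    frac = state.epoch_index / (state.total_epochs - 1)
    return float(lo + (hi - lo) * frac)


def ema_feedback(prev: float | None, current: float, alpha_feedback: float = 0.7) -> float:
    """Exponential-moving-average smoothing of confidence across epochs.

    ``alpha * prev + (1 - alpha) * current``; initializes to ``current``
    when there is no previous estimate.
    """
    if not (0.0 <= current <= 1.0):
        raise ValueError(f"confidence {current} outside [0, 1]")
    if prev is None:
        return float(current)
    if not (0.0 <= prev <= 1.0):
        raise ValueError(f"confidence {prev} outside [0, 1]")
    return float(alpha_feedback * prev + (1.0 - alpha_feedback) * current)


def feature_confidence(
    token_probs: list[float] | tuple[float, ...],
    feature_token_count: int,
    cfg: ConfidenceConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Full pipeline: aggregate, complexity-adjust, optionally inject noise."""
    c = aggregate_confidence(token_probs, geometric=cfg.use_geometric_mean)
    c = complexity_adjust(c, feature_token_count, cfg.lambda_complexity)
    return inject_noise(c, cfg, rng)
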