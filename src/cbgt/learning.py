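"""Plasticity: actor-critic reinforcement learning and Hebbian learning.

Two pathways are plastic, both restricted to the cognitive channel:

* **cortico-striatal** (cognitive cortex → cognitive striatum): gated by the
  reward prediction error RPE = R − V_i delivered by the (algorithmic)
  dopaminergic critic, with asymmetric LTP/LTD rates,

      dW = LTP_RL * RPE * U_B   if RPE > 0
      dW = LTD_RL * RPE * U_B   if RPE < 0

  where U_B is the postsynaptic striatal output at decision time;

* **cortico-cortical** (cognitive cortex → associative cortex): pure
  coactivity, reward-independent,

      dW = LTP_HL * U_A * U_B.

Every change passes through the soft-bounding map

    W <- W + dW * (W_max − W) * (W − W_min)

whose fixed points at the bounds keep all weights inside [W_min, W_max].
The critic tracks one value per cue, V_i <- V_i + alpha * RPE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LearningParams", "PlasticWeights", "CriticState",
    "reward_prediction_error", "critic_update", "corticostriatal_delta",
    "hebbian_delta", "bounded_update", "end_of_trial_learning",
]


@dataclass(frozen=True)
class LearningParams:
    w_min: float = 0.25
    w_max: float = 0.75
    ltp_rl: float = 0.050
    ltd_rl: float = 0.030
    ltp_hl: float = 0.005
    alpha: float = 0.025

    def __post_init__(self) -> None:
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be below w_max")
        if min(self.ltp_rl, self.ltd_rl, self.ltp_hl, self.alpha) <= 0:
            raise ValueError("all learning rates must be positive")


@dataclass
class PlasticWeights:
    """Cortico-striatal (per cue) and cortico-cortical (cue x location) weights."""

    cortico_striatal: np.ndarray
    cortico_cortical: np.ndarray

    @classmethod
    def initial(cls, rng: np.random.Generator, n_cues: int = 4, n_positions: int = 4,
                mean: float = 0.5, sd: float = 0.005) -> "PlasticWeights":
        """All weights start at 0.5 (SD 0.005) — a multiplier on the pathway gain."""
        return cls(
            cortico_striatal=rng.normal(mean, sd, size=n_cues),
            cortico_cortical=rng.normal(mean, sd, size=(n_cues, n_positions)),
        )

    def copy(self) -> "PlasticWeights":
        return PlasticWeights(self.cortico_striatal.copy(), self.cortico_cortical.copy())


@dataclass
class CriticState:
    """Per-cue values V_i maintained by the critic; start at zero."""

    values: np.ndarray

    @classmethod
    def initial(cls, n_cues: int = 4) -> "CriticState":
        return cls(values=np.zeros(n_cues))

    def copy(self) -> "CriticState":
        return CriticState(self.values.copy())


def reward_prediction_error(reward: int, value: float) -> float:
    """RPE = R − V_i."""
    return float(reward) - float(value)


def critic_update(state: CriticState, cue: int, rpe: float, alpha: float) -> None:
    """V_i <- V_i + alpha * RPE for the chosen cue only (in place)."""
    if not 0 <= cue < state.values.size:
        raise ValueError(f"unknown cue index {cue}")
    state.values[cue] += alpha * rpe


def corticostriatal_delta(rpe: float, u_striatal: float, params: LearningParams) -> float:
    """Reward-gated delta with asymmetric potentiation/depression rates."""
    if rpe > 0:
        return params.ltp_rl * rpe * u_striatal
    if rpe < 0:
        return params.ltd_rl * rpe * u_striatal
    return 0.0


def hebbian_delta(u_pre: float, u_post: float, params: LearningParams) -> float:
    """Reward-independent coactivity delta (nonnegative for rates >= 0)."""
    return params.ltp_hl * u_pre * u_post


def bounded_update(w, dw, params: LearningParams):
    """Soft-bounded one-step weight map; works elementwise on arrays."""
    w = np.asarray(w, dtype=float)
    if np.any(w < params.w_min - 1e-12) or np.any(w > params.w_max + 1e-12):
        raise ValueError("weight outside [w_min, w_max] before update")
    out = w + np.asarray(dw, dtype=float) * (params.w_max - w) * (w - params.w_min)
    return np.clip(out, params.w_min, params.w_max)


def end_of_trial_learning(
    *,
    chosen_cue: int | None,
    reward: int | None,
    u_ctx_cog: np.ndarray,
    u_ctx_ass: np.ndarray,
    u_str_cog: np.ndarray,
    weights: PlasticWeights,
    critic: CriticState,
    params: LearningParams,
    move_initiated: bool,
) -> None:
    """Apply all end-of-trial plasticity in place.

    Failed trials (no reward delivered) trigger neither the critic nor the
    reinforcement update.  The Hebbian update applies whenever a move was
    initiated, using decision-time cortical activities.  ``u_ctx_ass`` is the
    4x4 associative cortical output sheet.
    """
    if reward is not None and chosen_cue is not None:
        rpe = reward_prediction_error(reward, critic.values[chosen_cue])
        dw = corticostriatal_delta(rpe, float(u_str_cog[chosen_cue]), params)
        weights.cortico_striatal[chosen_cue] = bounded_update(
            weights.cortico_striatal[chosen_cue], dw, params
        )
        critic_update(critic, chosen_cue, rpe, params.alpha)
    if move_initiated:
        dcc = params.ltp_hl * u_ctx_cog[:, None] * u_ctx_ass
        weights.cortico_cortical = bounded_update(weights.cortico_cortical, dcc, params)
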