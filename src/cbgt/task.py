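"""The two-armed bandit task with dissociated cognitive and motor choices.

On each trial two of the cues are shown at two of four screen locations
(up/down/left/right).  The model must both pick a cue (cognitive choice) and
press a location (motor choice); only the motor choice counts for reward.
Choosing the location of cue i yields reward 1 with probability P_i, else 0.
A trial with no motor choice, or a motor choice pointing at an empty
location, is *failed*: no reward is delivered at all (which is different
from a reward of 0).

Performance is the fraction of trials on which the chosen cue was the one
with the higher reward probability of the two presented; failed trials count
in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

import numpy as np

from .connectivity import population_slice
from .populations import N_ASSEMBLIES

__all__ = [
    "CueSet", "Trial", "TrialOutcome", "sample_trial", "encode_stimuli",
    "read_decision", "draw_reward", "performance", "expected_reward_perfect_player",
    "N_POSITIONS", "STIMULUS_CURRENT",
]

N_POSITIONS = 4
#: external current injected into each stimulated cortical assembly, spikes/s
STIMULUS_CURRENT = 7.0


@dataclass(frozen=True)
class CueSet:
    """Cues and their fixed reward probabilities."""

    probabilities: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"C{i + 1}" for i in range(len(self.probabilities)))
            )
        if len(self.labels) != len(self.probabilities):
            raise ValueError("labels and probabilities must have equal length")
        if any(not 0.0 <= p <= 1.0 for p in self.probabilities):
            raise ValueError("reward probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.probabilities)


@dataclass(frozen=True)
class Trial:
    """Cue pair (indices into the cue set) at two distinct locations."""

    cues: tuple[int, int]
    positions: tuple[int, int]

    def __post_init__(self) -> None:
        if self.cues[0] == self.cues[1]:
            raise ValueError("the two presented cues must differ")
        if self.positions[0] == self.positions[1]:
            raise ValueError("the two locations must differ")
        if any(not 0 <= p < N_POSITIONS for p in self.positions):
            raise ValueError("locations must lie in {0,..,3}")

    def cue_at(self, position: int) -> int | None:
        """Cue shown at ``position``, or None if the location is empty."""
        for c, p in zip(self.cues, self.positions):
            if p == position:
                return c
        return None


@dataclass
class TrialOutcome:
    motor_choice: int | None = None
    cognitive_choice: int | None = None
    chosen_cue: int | None = None
    reward: int | None = None
    decision_time: float | None = None
    failed: bool = True


def sample_trial(cue_set: CueSet, rng: np.random.Generator) -> Trial:
    """Uniform draw of an unordered cue pair and an ordered distinct position pair."""
    if len(cue_set) < 2:
        raise ValueError("need at least two cues to form a trial")
    cues = tuple(int(c) for c in rng.choice(len(cue_set), size=2, replace=False))
    positions = tuple(int(p) for p in rng.choice(N_POSITIONS, size=2, replace=False))
    return Trial(cues=cues, positions=positions)


def encode_stimuli(trial: Trial | None) -> np.ndarray:
    """External-current vector for a trial (72 assemblies).

    7 spikes/s to the two cognitive-cortex assemblies coding the cues, the
    two motor-cortex assemblies coding the locations, and the two
    associative-cortex assemblies coding the veridical (cue, location)
    bindings — the latter disambiguate [C1/L1, C2/L2] from [C1/L2, C2/L1].
    """
    I = np.zeros(N_ASSEMBLIES)
    if trial is None:
        return I
    cog = population_slice("CTX_cog").start
    mot = population_slice("CTX_mot").start
    ass = population_slice("CTX_ass").start
    for c, p in zip(trial.cues, trial.positions):
        I[cog + c] += STIMULUS_CURRENT
        I[mot + p] += STIMULUS_CURRENT
        I[ass + 4 * c + p] += STIMULUS_CURRENT
    return I


def _race_winner(U: np.ndarray, pair: tuple[int, int], threshold: float) -> int | None:
    """Winner of a two-assembly race: the one leading by >= threshold, else None."""
    a, b = pair
    diff = float(U[a]) - float(U[b])
    if abs(diff) >= threshold:
        return a if diff > 0 else b
    return None


def read_decision(motor_U: np.ndarray, trial: Trial, threshold: float = 40.0) -> int | None:
    """Decode a motor choice from motor-cortex output rates.

    The decision criterion is a 40 spikes/s *difference* between the two
    stimulated motor assemblies; whichever leads wins.  A non-stimulated
    assembly that is globally maximal and leads every other assembly by the
    threshold also counts (an illegal choice, failed upstream).  Otherwise
    no decision.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    motor_U = np.asarray(motor_U, dtype=float)
    winner = _race_winner(motor_U, trial.positions, threshold)
    if winner is not None:
        return winner
    best = int(np.argmax(motor_U))
    if best not in trial.positions:
        others = np.delete(motor_U, best)
        if motor_U[best] - others.max() >= threshold:
            return best
    return None


def draw_reward(chosen_cue: int | None, cue_set: CueSet, rng: np.random.Generator) -> int | None:
    """Bernoulli reward draw for the chosen cue; None on a failed trial."""
    if chosen_cue is None:
        return None
    p = cue_set.probabilities[chosen_cue]
    return int(rng.uniform(0.0, 1.0) <= p)


def performance(records) -> float:
    """Fraction of best-cue choices over all trials (failed trials count against)."""
    records = list(records)
    if not records:
        raise ValueError("performance of an empty record list is undefined")
    return float(np.mean([1.0 if r.best_chosen else 0.0 for r in records]))


def expected_reward_perfect_player(cue_set: CueSet) -> Fraction:
    """Mean expected reward of a full-knowledge player under uniform pair sampling.

    Exact rational arithmetic: the average over all unordered cue pairs of
    max(P_i, P_j).
    """
    pairs = list(combinations(range(len(cue_set)), 2))
    total = Fraction(0)
    for i, j in pairs:
        total += max(
            Fraction(cue_set.probabilities[i]).limit_denominator(10**9),
            Fraction(cue_set.probabilities[j]).limit_denominator(10**9),
        )
    return total / len(pairs)
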