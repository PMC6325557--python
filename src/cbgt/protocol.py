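"""Trial and session runner, and the covert-learning protocol.

A trial: reset the circuit, let it settle for 500 ms, switch on the stimulus
currents, integrate until the motor cortex crosses the decision threshold (or
a timeout elapses — a failed trial), draw the reward, apply end-of-trial
plasticity, log everything.

The covert-learning experiment runs, for each of 12 independently seeded
sessions:

* **C0** — intact model, stimulus set 1, P = (0.75, 0.25), 60 trials;
* **C1** — GPi→thalamus output cut (the muscimol analogue), fresh weights and
  critic for stimulus set 2 (same probabilities), 60 trials;
* **C2** — output restored, *keeping* the weights and critic learned during
  C1, 60 more trials on stimulus set 2.

The model's claim: during C1 behaviour is random (the cortex alone decides)
while the striatum silently learns the cue values; restoring the output in C2
reveals the covert learning as an immediate above-chance performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import (GainTable, apply_lesion, build_default_gain_table,
                           population_slice)
from .learning import CriticState, LearningParams, PlasticWeights, end_of_trial_learning
from .network import Network
from .populations import default_populations
from .task import (CueSet, Trial, draw_reward, encode_stimuli, sample_trial,
                   _race_winner, read_decision)

__all__ = [
    "TrialRecord", "SessionConfig", "SessionLog", "ProtocolResult",
    "run_trial", "run_session", "run_covert_learning_protocol", "summarize",
    "DEFAULT_CUE_SET",
]

#: the experimental stimulus sets: two cues with P = 0.75 / 0.25
DEFAULT_CUE_SET = CueSet(probabilities=(0.75, 0.25), labels=("A", "B"))

SETTLE_MS = 500.0
TIMEOUT_MS = 2500.0
DECISION_THRESHOLD = 40.0
#: decision-time activities are expressed in units of this reference rate
#: (spikes/s) before entering the plasticity rules, so that the per-trial
#: weight steps stay small against the soft bounds over a 60-trial session.
#: The calibration of this reference is documented in the methods note.
LEARNING_ACTIVITY_REF = 8.0


@dataclass
class TrialRecord:
    session_id: int
    condition: str
    trial_index: int
    cue_A: int
    cue_B: int
    pos_A: int
    pos_B: int
    motor_choice: int | None
    cognitive_choice: int | None
    chosen_cue: int | None
    best_chosen: bool
    reward: int | None
    decision_time_ms: float | None
    failed: bool


@dataclass(frozen=True)
class SessionConfig:
    condition: str = "C0"
    n_trials: int = 60
    cue_set: CueSet = DEFAULT_CUE_SET
    lesion: str = "none"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.condition == "C1" and self.lesion != "gpi_output_off":
            raise ValueError("condition C1 requires lesion='gpi_output_off'")


@dataclass
class SessionLog:
    records: list[TrialRecord]
    weights: PlasticWeights
    critic: CriticState
    #: per-trial learning traces: cortico-striatal weights, critic values and
    #: mean Hebbian row weight for each cue of the active pair
    traces: list[dict] = field(default_factory=list)

    def performance(self, trials: slice = slice(None)) -> float:
        recs = self.records[trials]
        return float(np.mean([r.best_chosen for r in recs]))

    def traces_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.traces)


@dataclass
class ProtocolResult:
    """All session logs per condition plus the run's provenance."""

    sessions: dict[str, list[SessionLog]]
    master_seed: int

    CONDITIONS = ("C0", "C1", "C2")

    def pooled_sample(self, condition: str, which: str) -> np.ndarray:
        """Success indicators pooled over sessions: first or last 10 trials."""
        sl = slice(0, 10) if which == "start" else slice(-10, None)
        vals = []
        for log in self.sessions[condition]:
            vals.extend(1 if r.best_chosen else 0 for r in log.records[sl])
        return np.asarray(vals)

    def session_means(self, condition: str, which: str) -> np.ndarray:
        sl = slice(0, 10) if which == "start" else slice(-10, None)
        return np.asarray([log.performance(sl) for log in self.sessions[condition]])

    def summary(self) -> pd.DataFrame:
        """Six samples: mean +/- SD (over sessions) of first/last-10 performance."""
        rows = []
        for cond in self.CONDITIONS:
            if cond not in self.sessions:
                continue
            for which in ("start", "end"):
                m = self.session_means(cond, which)
                n_pooled = self.pooled_sample(cond, which).size
                rows.append((cond, which, m.mean(), m.std(ddof=1), m.size, n_pooled))
        return pd.DataFrame(
            rows, columns=["condition", "window", "mean", "sd", "n_sessions", "n_pooled"]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond in self.CONDITIONS:
            for log in self.sessions.get(cond, []):
                rows.extend(vars(r) for r in log.records)
        return pd.DataFrame(rows)


def run_trial(
    net: Network,
    weights: PlasticWeights,
    critic: CriticState,
    trial: Trial,
    cue_set: CueSet,
    rng: np.random.Generator,
    params: LearningParams,
    *,
    settle_ms: float = SETTLE_MS,
    timeout_ms: float = TIMEOUT_MS,
    threshold: float = DECISION_THRESHOLD,
    learn: bool = True,
) -> TrialRecord:
    """Run one trial on an initialized network and apply end-of-trial learning."""
    net.reset()
    net.set_weights(weights.cortico_striatal, weights.cortico_cortical)
    net.settle(settle_ms)

    net.I_ext = encode_stimuli(trial)
    n_steps = int(round(timeout_ms / net.dt))
    motor_choice = None
    cognitive_choice = None
    decision_time = None
    u_snapshot = None
    for _ in range(n_steps):
        net.step()
        if cognitive_choice is None:
            cognitive_choice = _race_winner(net.output("CTX_cog"), trial.cues, threshold)
        motor_choice = read_decision(net.output("CTX_mot"), trial, threshold)
        if motor_choice is not None:
            decision_time = net.t - settle_ms
            u_snapshot = net.U.copy()
            break

    chosen_cue = trial.cue_at(motor_choice) if motor_choice is not None else None
    failed = chosen_cue is None
    reward = None if failed else draw_reward(chosen_cue, cue_set, rng)
    p = cue_set.probabilities
    best = max(trial.cues, key=lambda c: p[c])
    best_chosen = (not failed) and chosen_cue == best

    if learn and motor_choice is not None:
        u = u_snapshot / LEARNING_ACTIVITY_REF
        end_of_trial_learning(
            chosen_cue=chosen_cue,
            reward=reward,
            u_ctx_cog=u[population_slice("CTX_cog")],
            u_ctx_ass=u[population_slice("CTX_ass")].reshape(4, 4),
            u_str_cog=u[population_slice("STR_cog")],
            weights=weights,
            critic=critic,
            params=params,
            move_initiated=True,
        )

    return TrialRecord(
        session_id=-1, condition="", trial_index=-1,
        cue_A=trial.cues[0], cue_B=trial.cues[1],
        pos_A=trial.positions[0], pos_B=trial.positions[1],
        motor_choice=motor_choice, cognitive_choice=cognitive_choice,
        chosen_cue=chosen_cue, best_chosen=best_chosen, reward=reward,
        decision_time_ms=decision_time, failed=failed,
    )


def run_session(
    config: SessionConfig,
    *,
    weights: PlasticWeights | None = None,
    critic: CriticState | None = None,
    gain_table: GainTable | None = None,
    learning_params: LearningParams | None = None,
    rng: np.random.Generator | None = None,
    dt: float = 1.0,
) -> SessionLog:
    """Run one condition (default 60 trials); returns the log with final state."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    params = learning_params if learning_params is not None else LearningParams()
    table = gain_table if gain_table is not None else build_default_gain_table()
    table = apply_lesion(table, config.lesion)
    net = Network(default_populations(), table, rng=rng, dt=dt)
    weights = weights if weights is not None else PlasticWeights.initial(rng)
    critic = critic if critic is not None else CriticState.initial()

    records = []
    traces = []
    for k in range(config.n_trials):
        trial = sample_trial(config.cue_set, rng)
        rec = run_trial(net, weights, critic, trial, config.cue_set, rng, params)
        rec.condition = config.condition
        rec.trial_index = k
        records.append(rec)
        traces.append({
            "trial_index": k,
            **{f"w_cs_{c}": weights.cortico_striatal[c] for c in range(2)},
            **{f"value_{c}": critic.values[c] for c in range(2)},
            **{f"w_cc_{c}": float(weights.cortico_cortical[c].mean()) for c in range(2)},
        })
    return SessionLog(records=records, weights=weights, critic=critic, traces=traces)


def run_covert_learning_protocol(
    n_sessions: int = 12,
    master_seed: int = 0,
    *,
    n_trials: int = 60,
    conditions: tuple[str, ...] = ("C0", "C1", "C2"),
    carry_c1_to_c2: bool = True,
    gain_table: GainTable | None = None,
    learning_params: LearningParams | None = None,
    dt: float = 1.0,
) -> ProtocolResult:
    """The full covert-learning experiment over independently seeded sessions.

    ``carry_c1_to_c2=False`` is the no-carryover control: C2 then starts from
    fresh weights and critic, which abolishes the covert head start.
    """
    ss = np.random.SeedSequence(master_seed)
    session_seeds = ss.spawn(n_sessions)
    sessions: dict[str, list[SessionLog]] = {c: [] for c in conditions}
    for s, child in enumerate(session_seeds):
        streams = {c: np.random.default_rng(sub) for c, sub in zip(("C0", "C1", "C2"), child.spawn(3))}
        if "C0" in conditions:
            log0 = run_session(
                SessionConfig("C0", n_trials, DEFAULT_CUE_SET, "none"),
                rng=streams["C0"], gain_table=gain_table,
                learning_params=learning_params, dt=dt,
            )
            _stamp(log0, s)
            sessions["C0"].append(log0)
        log1 = run_session(
            SessionConfig("C1", n_trials, DEFAULT_CUE_SET, "gpi_output_off"),
            rng=streams["C1"], gain_table=gain_table,
            learning_params=learning_params, dt=dt,
        )
        _stamp(log1, s)
        if "C1" in conditions:
            sessions["C1"].append(log1)
        if "C2" in conditions:
            carry_w = log1.weights.copy() if carry_c1_to_c2 else None
            carry_v = log1.critic.copy() if carry_c1_to_c2 else None
            log2 = run_session(
                SessionConfig("C2", n_trials, DEFAULT_CUE_SET, "none"),
                weights=carry_w, critic=carry_v,
                rng=streams["C2"], gain_table=gain_table,
                learning_params=learning_params, dt=dt,
            )
            _stamp(log2, s)
            sessions["C2"].append(log2)
    return ProtocolResult(sessions=sessions, master_seed=master_seed)


def _stamp(log: SessionLog, session_id: int) -> None:
    for r in log.records:
        r.session_id = session_id


def summarize(result: ProtocolResult, window: int = 10) -> dict:
    """Pooled six-sample table plus sliding-window success curves.

    Returns ``{"summary": DataFrame, "sliding": {condition: (mean, sd)}}``
    where each curve has n_trials − window + 1 points (mean and SD over
    sessions of the windowed success rate).
    """
    sliding = {}
    for cond, logs in result.sessions.items():
        if not logs:
            continue
        mat = np.array([[1.0 if r.best_chosen else 0.0 for r in log.records] for log in logs])
        n = mat.shape[1]
        idx = np.arange(n - window + 1)
        win = np.array([mat[:, i:i + window].mean(axis=1) for i in idx]).T
        sliding[cond] = (win.mean(axis=0), win.std(axis=0, ddof=1))
    return {"summary": result.summary(), "sliding": sliding}
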