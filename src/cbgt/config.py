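"""Run configuration: structured-text (YAML) config with validated schema.

An empty file (or ``RunConfig()``) reproduces the default model: population
parameters, pathway gains, learning parameters, the two-cue task with
P = (0.75, 0.25), and the covert-learning protocol dimensions (12 sessions
x 60 trials).  Any override is recorded and surfaced in the run metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .connectivity import GainTable, build_default_gain_table
from .learning import LearningParams
from .populations import default_populations
from .task import CueSet

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised on malformed configuration input, naming the offending key."""


_SCHEMA: dict[str, set[str]] = {
    "populations": {"gpi_threshold", "thalamus_threshold"},
    "gains": {
        "cortex_thalamus_gain", "gpi_thalamus_gain", "lateral_magnitude",
        "stn_gpi_pattern", "corticostriatal_weight_gain", "hebbian_gain",
        "striatum_ass_gpi_gain", "stn_gpi_gain",
    },
    "learning": {"w_min", "w_max", "ltp_rl", "ltd_rl", "ltp_hl", "alpha"},
    "task": {"probabilities", "labels"},
    "protocol": {"n_sessions", "n_trials", "settle_ms", "timeout_ms", "threshold"},
    "run": {"dt", "seed", "out"},
}


@dataclass
class RunConfig:
    populations: dict = field(default_factory=dict)
    gains: dict = field(default_factory=dict)
    learning: dict = field(default_factory=dict)
    task: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    run: dict = field(default_factory=dict)

    # -- factories ---------------------------------------------------------
    def build_populations(self):
        return default_populations(**self.populations)

    def build_gain_table(self) -> GainTable:
        return build_default_gain_table(**self.gains)

    def learning_params(self) -> LearningParams:
        return LearningParams(**self.learning)

    def cue_set(self) -> CueSet:
        if not self.task:
            from .protocol import DEFAULT_CUE_SET
            return DEFAULT_CUE_SET
        return CueSet(
            probabilities=tuple(self.task.get("probabilities", (0.75, 0.25))),
            labels=tuple(self.task.get("labels", ())),
        )

    @property
    def dt(self) -> float:
        return float(self.run.get("dt", 1.0))

    @property
    def seed(self) -> int:
        return int(self.run.get("seed", 0))

    def overrides(self) -> dict:
        """Every key that departs from the defaults, for the run metadata."""
        return {
            section: dict(values)
            for section, values in asdict(self).items() if values
        }


def load_config(path: str | Path | None) -> RunConfig:
    """Parse and validate a YAML config file; None or empty file → defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    cfg = RunConfig()
    for section, values in data.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if values is None:
            continue
        if not isinstance(values, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key in values:
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown key {section}.{key}")
        getattr(cfg, section).update(values)
    # fail fast on bad values
    cfg.build_populations()
    cfg.build_gain_table()
    cfg.learning_params()
    return cfg
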