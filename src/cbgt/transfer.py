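"""Firing-rate transfer functions.

Every assembly converts its activation ``V`` (which may be negative) into a
nonnegative output rate ``U`` through a transfer function.  Cortical, thalamic,
pallidal and subthalamic assemblies use a threshold-linear ramp; striatal
assemblies — silent at rest and requiring coordinated input to fire — use a
sigmoid of Boltzmann form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SigmoidParams", "ramp_transfer", "boltzmann_transfer"]


@dataclass(frozen=True)
class SigmoidParams:
    """Boltzmann sigmoid parameters, all in spikes/s.

    ``v_min``/``v_max`` are the floor and ceiling output rates, ``v_h`` the
    half-activation input and ``v_c`` the slope parameter.
    """

    v_min: float = 1.0
    v_max: float = 20.0
    v_h: float = 16.0
    v_c: float = 3.0

    def __post_init__(self) -> None:
        if not self.v_max > self.v_min:
            raise ValueError(f"v_max ({self.v_max}) must exceed v_min ({self.v_min})")
        if not self.v_c > 0:
            raise ValueError(f"v_c must be positive, got {self.v_c}")


def ramp_transfer(x):
    """Threshold-linear transfer f(x) = max(x, 0), elementwise.

    Raises ``ValueError`` on non-finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("ramp_transfer requires finite input")
    return np.maximum(x, 0.0)


def boltzmann_transfer(x, params: SigmoidParams):
    """Boltzmann sigmoid: v_min + (v_max - v_min) / (1 + exp((v_h - x)/v_c)).

    Strictly increasing in ``x``; output lies in (v_min, v_max).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("boltzmann_transfer requires finite input")
    span = params.v_max - params.v_min
    # clip exponent to avoid overflow for very negative activations
    z = np.clip((params.v_h - x) / params.v_c, -500.0, 500.0)
    return params.v_min + span / (1.0 + np.exp(z))
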