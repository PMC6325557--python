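"""Population definitions for the cortex-basal ganglia-thalamus network.

The circuit is organised into three segregated loops sharing the basal
ganglia:

* the **cognitive** loop (cortex, striatum, STN, GPi, thalamus) chooses which
  cue to take,
* the **motor** loop (same five structures) chooses which location to press,
* the **associative** loop (cortex + striatum only) binds cue identity to
  location, providing the cross-talk that lets the cognitive decision steer
  the motor one.

That makes 12 populations.  Cognitive and motor channel populations hold 4
assemblies (one per cue, resp. one per location); associative populations
hold a 4x4 sheet indexed (cue, location).  Geometries are kept as metadata —
connectivity is defined on assembly indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .transfer import SigmoidParams

__all__ = ["PopulationParams", "default_populations", "POPULATION_ORDER", "N_ASSEMBLIES"]

#: canonical ordering of the 12 populations in the flattened state vector
POPULATION_ORDER = (
    "CTX_cog", "CTX_mot", "CTX_ass",
    "STR_cog", "STR_mot", "STR_ass",
    "STN_cog", "STN_mot",
    "GPI_cog", "GPI_mot",
    "THL_cog", "THL_mot",
)

#: total number of assemblies across all populations (3x4 + 3x4 + 2x16 + ...)
N_ASSEMBLIES = 72


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of one population of rate-coded assemblies.

    ``tau`` is the membrane/synaptic time constant in ms, ``threshold`` the
    baseline input h in spikes/s (added to the net input, so a negative value
    means the population is silent at rest), ``noise_level`` the standard
    deviation of the multiplicative output noise (dimensionless fraction),
    and ``transfer_kind`` selects ramp or Boltzmann output.
    """

    name: str
    geometry: tuple[int, int]
    tau: float = 10.0
    threshold: float = -3.0
    noise_level: float = 0.01
    transfer_kind: str = "ramp"
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"{self.name}: tau must be positive")
        if self.geometry[0] < 1 or self.geometry[1] < 1:
            raise ValueError(f"{self.name}: geometry dims must be >= 1")
        if self.noise_level < 0:
            raise ValueError(f"{self.name}: noise_level must be >= 0")
        if self.transfer_kind not in ("ramp", "boltzmann"):
            raise ValueError(f"{self.name}: unknown transfer {self.transfer_kind!r}")
        striatal = self.name.startswith("STR")
        if striatal != (self.transfer_kind == "boltzmann"):
            raise ValueError(
                f"{self.name}: Boltzmann transfer is used exactly for striatal populations"
            )

    @property
    def size(self) -> int:
        return self.geometry[0] * self.geometry[1]


def default_populations(
    *,
    gpi_threshold: float = 39.0,
    thalamus_threshold: float = 40.0,
    sigmoid: SigmoidParams | None = None,
) -> dict[str, PopulationParams]:
    """The 12 populations with their default parameters.

    Time constants are 10 ms everywhere.  Cortex rests at -3 spikes/s with 1%
    multiplicative noise, striatum at 0 with 0.1% noise, STN at -10 with
    0.1%, and GPi carries the largest noise (3%).  The GPi and thalamic
    baselines are positive and mutually balanced: the pallidum fires
    tonically at rest (as pallidal cells do in vivo) and its inhibition just
    cancels the thalamic drive, so striatal input *dis*-inhibits the
    thalamus — the disinhibition gate the direct pathway requires.  The
    calibration of this operating point is documented in the methods note.
    """
    sg = sigmoid if sigmoid is not None else SigmoidParams()

    def P(name, geometry, threshold, noise, kind="ramp"):
        return PopulationParams(
            name=name, geometry=geometry, tau=10.0, threshold=threshold,
            noise_level=noise, transfer_kind=kind, sigmoid=sg,
        )

    pops = {
        "CTX_ass": P("CTX_ass", (4, 4), -3.0, 0.010),
        "CTX_cog": P("CTX_cog", (4, 1), -3.0, 0.010),
        "CTX_mot": P("CTX_mot", (1, 4), -3.0, 0.010),
        "STR_ass": P("STR_ass", (4, 4), 0.0, 0.001, "boltzmann"),
        "STR_cog": P("STR_cog", (4, 1), 0.0, 0.001, "boltzmann"),
        "STR_mot": P("STR_mot", (4, 1), 0.0, 0.001, "boltzmann"),
        "GPI_cog": P("GPI_cog", (4, 1), gpi_threshold, 0.030),
        "GPI_mot": P("GPI_mot", (1, 4), gpi_threshold, 0.030),
        "STN_cog": P("STN_cog", (4, 1), -10.0, 0.001),
        "STN_mot": P("STN_mot", (1, 4), -10.0, 0.001),
        "THL_cog": P("THL_cog", (4, 1), thalamus_threshold, 0.001),
        "THL_mot": P("THL_mot", (1, 4), thalamus_threshold, 0.001),
    }
    return {name: pops[name] for name in POPULATION_ORDER}
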