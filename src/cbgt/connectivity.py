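"""Connectivity: pathway gains, expansion patterns, lesions.

Each pathway between two populations is described by a :class:`ConnectionSpec`
carrying a scalar gain and an expansion *pattern* that maps population-level
wiring onto per-assembly connections:

``one-to-one``
    assembly i projects to assembly i (channel-preserving).
``one-to-all``
    every assembly projects to every assembly of the target channel — used for
    the hyperdirect STN→GPi divergence, which spreads one channel's "no-go"
    signal over all assemblies of that loop.
``broadcast-rows`` / ``broadcast-cols``
    a 4-vector channel fans out onto a 4x4 associative sheet, row-wise
    (cognitive cue i → cells (i, *)) or column-wise (motor location j →
    cells (*, j)) — the cortico-striatal divergence.
``collect-rows`` / ``collect-cols``
    a 4x4 sheet reconverges onto a 4-vector channel by row (cells (i, *) →
    cognitive i) or column — the striato-pallidal reconvergence that lets the
    associative territory couple the cognitive and motor competitions.
``lateral``
    intra-cortical competition: short-range excitation (+gain to self),
    long-range inhibition (−gain to every other assembly of the population).

Lesion operators zero targeted gains without touching anything else, and are
reversible by rebuilding the table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from io import StringIO

import numpy as np
import pandas as pd

from .populations import POPULATION_ORDER, N_ASSEMBLIES

__all__ = [
    "ConnectionSpec", "GainTable", "build_default_gain_table",
    "expand_pattern", "lateral_gain", "apply_lesion", "LESIONS",
]

PATTERNS = (
    "one-to-one", "one-to-all",
    "broadcast-rows", "broadcast-cols",
    "collect-rows", "collect-cols",
    "lateral",
)

#: recognised lesion tokens
LESIONS = ("none", "gpi_output_off", "cortical_lateral_off")

# global index offsets of each population in the 72-assembly state vector
_OFFSETS: dict[str, int] = {}
_SIZES: dict[str, int] = {}
_off = 0
for _name in POPULATION_ORDER:
    _SIZES[_name] = 16 if _name.endswith("ass") else 4
    _OFFSETS[_name] = _off
    _off += _SIZES[_name]
assert _off == N_ASSEMBLIES


def population_slice(name: str) -> slice:
    """Slice of a population's assemblies in the flattened 72-vector."""
    return slice(_OFFSETS[name], _OFFSETS[name] + _SIZES[name])


@dataclass(frozen=True)
class ConnectionSpec:
    """One pathway: presynaptic population → postsynaptic population."""

    pre: str
    post: str
    pattern: str
    gain: float
    plastic: bool = False

    def __post_init__(self) -> None:
        if self.pre not in POPULATION_ORDER or self.post not in POPULATION_ORDER:
            raise ValueError(f"unknown population in {self.pre}->{self.post}")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern token {self.pattern!r}")


def expand_pattern(spec: ConnectionSpec) -> list[tuple[int, int, float]]:
    """Expand a pathway into per-assembly (pre_local, post_local, gain) triples.

    Associative sheets are indexed row-major: cell (cue i, location j) is
    ``4*i + j``.
    """
    n_pre, n_post = _SIZES[spec.pre], _SIZES[spec.post]
    g = spec.gain
    out: list[tuple[int, int, float]] = []
    if spec.pattern == "one-to-one":
        if n_pre != n_post:
            raise ValueError(f"one-to-one needs equal sizes: {spec.pre}->{spec.post}")
        out = [(i, i, g) for i in range(n_pre)]
    elif spec.pattern == "one-to-all":
        out = [(i, j, g) for i in range(n_pre) for j in range(n_post)]
    elif spec.pattern == "broadcast-rows":
        if n_pre != 4 or n_post != 16:
            raise ValueError(f"broadcast-rows needs 4->16: {spec.pre}->{spec.post}")
        out = [(i, 4 * i + j, g) for i in range(4) for j in range(4)]
    elif spec.pattern == "broadcast-cols":
        if n_pre != 4 or n_post != 16:
            raise ValueError(f"broadcast-cols needs 4->16: {spec.pre}->{spec.post}")
        out = [(j, 4 * i + j, g) for j in range(4) for i in range(4)]
    elif spec.pattern == "collect-rows":
        if n_pre != 16 or n_post != 4:
            raise ValueError(f"collect-rows needs 16->4: {spec.pre}->{spec.post}")
        out = [(4 * i + j, i, g) for i in range(4) for j in range(4)]
    elif spec.pattern == "collect-cols":
        if n_pre != 16 or n_post != 4:
            raise ValueError(f"collect-cols needs 16->4: {spec.pre}->{spec.post}")
        out = [(4 * i + j, j, g) for i in range(4) for j in range(4)]
    elif spec.pattern == "lateral":
        if spec.pre != spec.post:
            raise ValueError("lateral pattern requires pre == post")
        for i in range(n_pre):
            for j in range(n_post):
                out.append((i, j, lateral_gain(i, j, abs(g))))
    return out


def lateral_gain(pre_assembly: int, post_assembly: int, magnitude: float) -> float:
    """Signed lateral gain inside one cortical population.

    Short-range excitation: +magnitude to self; long-range inhibition:
    −magnitude to every other assembly.
    """
    return magnitude if pre_assembly == post_assembly else -magnitude


class GainTable:
    """The full pathway table plus its per-assembly expansion.

    ``matrix()`` returns the dense 72x72 gain matrix M with M[post, pre]
    (plastic entries at their *base* gain — the network multiplies in the
    synaptic weights).  ``plastic_entries()`` lists the expanded plastic
    connections so the network can refresh them as weights change.
    """

    def __init__(self, specs: list[ConnectionSpec]):
        self.specs = list(specs)

    def matrix(self) -> np.ndarray:
        M = np.zeros((N_ASSEMBLIES, N_ASSEMBLIES))
        for spec in self.specs:
            o_pre, o_post = _OFFSETS[spec.pre], _OFFSETS[spec.post]
            for i, j, g in expand_pattern(spec):
                M[o_post + j, o_pre + i] += g
        return M

    def plastic_entries(self) -> list[tuple[str, str, int, int, float]]:
        """(pre_pop, post_pop, pre_global, post_global, base_gain) per synapse."""
        out = []
        for spec in self.specs:
            if not spec.plastic:
                continue
            o_pre, o_post = _OFFSETS[spec.pre], _OFFSETS[spec.post]
            for i, j, g in expand_pattern(spec):
                out.append((spec.pre, spec.post, o_pre + i, o_post + j, g))
        return out

    def find(self, pre: str, post: str) -> list[ConnectionSpec]:
        return [s for s in self.specs if s.pre == pre and s.post == post]

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.pre, s.post, s.pattern, s.gain, s.plastic) for s in self.specs],
            columns=["pop_A", "pop_B", "pattern", "gain", "plastic"],
        )

    def to_csv(self) -> str:
        return self.to_frame().to_csv(index=False)

    @classmethod
    def from_csv(cls, text: str) -> "GainTable":
        df = pd.read_csv(StringIO(text))
        specs = [
            ConnectionSpec(r.pop_A, r.pop_B, r.pattern, float(r.gain), bool(r.plastic))
            for r in df.itertuples()
        ]
        return cls(specs)

    def __eq__(self, other) -> bool:
        return isinstance(other, GainTable) and self.specs == other.specs


def build_default_gain_table(
    *,
    cortex_thalamus_gain: float = 0.05,
    gpi_thalamus_gain: float = -1.5,
    lateral_magnitude: float = 0.5,
    stn_gpi_pattern: str = "one-to-all",
    corticostriatal_weight_gain: float = 2.0,
    hebbian_gain: float = 0.025,
    striatum_ass_gpi_gain: float = -2.0,
    stn_gpi_gain: float = 1.0,
) -> GainTable:
    """Default pathway table of the intact model.

    The two plastic pathways are the cognitive cortico-striatal projection
    (reinforcement-gated) and the cognitive→associative cortico-cortical
    projection (Hebbian).  ``stn_gpi_pattern`` switches the hyperdirect
    STN→GPi divergence between one-to-all (default: the broadcast "no-go"
    required for a within-loop competition) and one-to-one.
    """
    C = ConnectionSpec
    specs = [
        # cortico-striatal divergence (direct pathway entry)
        C("CTX_cog", "STR_cog", "one-to-one", corticostriatal_weight_gain, plastic=True),
        C("CTX_mot", "STR_mot", "one-to-one", 1.0),
        C("CTX_ass", "STR_ass", "one-to-one", 1.0),
        C("CTX_cog", "STR_ass", "broadcast-rows", 0.2),
        C("CTX_mot", "STR_ass", "broadcast-cols", 0.2),
        # hyperdirect pathway entry
        C("CTX_cog", "STN_cog", "one-to-one", 1.0),
        C("CTX_mot", "STN_mot", "one-to-one", 1.0),
        # cortico-thalamic drive
        C("CTX_cog", "THL_cog", "one-to-one", cortex_thalamus_gain),
        C("CTX_mot", "THL_mot", "one-to-one", cortex_thalamus_gain),
        # intra-cortical competition
        C("CTX_cog", "CTX_cog", "lateral", lateral_magnitude),
        C("CTX_mot", "CTX_mot", "lateral", lateral_magnitude),
        C("CTX_ass", "CTX_ass", "lateral", lateral_magnitude),
        # cortico-cortical binding
        C("CTX_ass", "CTX_mot", "collect-cols", 0.025),
        C("CTX_ass", "CTX_cog", "collect-rows", 0.01),
        C("CTX_cog", "CTX_ass", "broadcast-rows", hebbian_gain, plastic=True),
        C("CTX_mot", "CTX_ass", "broadcast-cols", 0.01),
        # striato-pallidal reconvergence
        C("STR_cog", "GPI_cog", "one-to-one", -2.0),
        C("STR_mot", "GPI_mot", "one-to-one", -2.0),
        C("STR_ass", "GPI_cog", "collect-rows", striatum_ass_gpi_gain),
        C("STR_ass", "GPI_mot", "collect-cols", striatum_ass_gpi_gain),
        # hyperdirect divergence
        C("STN_cog", "GPI_cog", stn_gpi_pattern, stn_gpi_gain),
        C("STN_mot", "GPI_mot", stn_gpi_pattern, stn_gpi_gain),
        # pallido-thalamic output and thalamo-cortical closure
        C("GPI_cog", "THL_cog", "one-to-one", gpi_thalamus_gain),
        C("GPI_mot", "THL_mot", "one-to-one", gpi_thalamus_gain),
        C("THL_cog", "CTX_cog", "one-to-one", 1.0),
        C("THL_mot", "CTX_mot", "one-to-one", 1.0),
    ]
    return GainTable(specs)


def apply_lesion(table: GainTable, lesion: str) -> GainTable:
    """Return a new table with the lesioned gains set to zero.

    ``gpi_output_off`` cuts the GPi→thalamus projection (the muscimol
    analogue); ``cortical_lateral_off`` zeroes all intra-cortical lateral
    gains.  Idempotent; ``none`` is the identity.
    """
    if lesion not in LESIONS:
        raise ValueError(f"unknown lesion token {lesion!r}")
    if lesion == "none":
        return GainTable(list(table.specs))
    new = []
    for s in table.specs:
        if lesion == "gpi_output_off" and s.pre.startswith("GPI") and s.post.startswith("THL"):
            s = replace(s, gain=0.0)
        elif lesion == "cortical_lateral_off" and s.pattern == "lateral":
            s = replace(s, gain=0.0)
        new.append(s)
    return GainTable(new)
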