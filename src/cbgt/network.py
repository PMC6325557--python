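"""Rate-model network: synaptic integration and time stepping.

Every assembly obeys

    tau dV/dt = -V + I_syn + I_ext + h
    U = f(V + V*n)

with ``I_syn`` the gain-weighted sum of presynaptic outputs, ``h`` the
population baseline, ``f`` a ramp (Boltzmann for striatum) and ``n`` a fresh
zero-mean Gaussian drawn per assembly per step (multiplicative output noise).
Integration is forward Euler; with tau = 10 ms, dt = 1 ms is comfortably
stable and refines cleanly.

The 72 assemblies of the 12 populations live in one flat state vector so a
step is a single dense matrix-vector product.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import GainTable, build_default_gain_table, population_slice
from .populations import POPULATION_ORDER, N_ASSEMBLIES, PopulationParams, default_populations
from .transfer import boltzmann_transfer

__all__ = ["Network", "synaptic_input"]


def synaptic_input(gain_matrix: np.ndarray, outputs: np.ndarray) -> np.ndarray:
    """Per-assembly synaptic current: I_syn[b] = sum_a G[b,a] * U[a].

    Plastic-pathway entries of ``gain_matrix`` are expected to already carry
    gain x weight.
    """
    outputs = np.asarray(outputs, dtype=float)
    if gain_matrix.shape != (outputs.size, outputs.size):
        raise ValueError(
            f"gain matrix {gain_matrix.shape} does not match {outputs.size} assemblies"
        )
    return gain_matrix @ outputs


class Network:
    """The 12-population circuit with pluggable gain table and weights."""

    def __init__(
        self,
        populations: dict[str, PopulationParams] | None = None,
        gain_table: GainTable | None = None,
        rng: np.random.Generator | None = None,
        dt: float = 1.0,
    ):
        self.populations = populations if populations is not None else default_populations()
        self.gain_table = gain_table if gain_table is not None else build_default_gain_table()
        self.rng = rng if rng is not None else np.random.default_rng()

        # flatten per-population parameters
        self.tau = np.empty(N_ASSEMBLIES)
        self.h = np.empty(N_ASSEMBLIES)
        self.noise_sd = np.empty(N_ASSEMBLIES)
        self._striatal = np.zeros(N_ASSEMBLIES, dtype=bool)
        for name in POPULATION_ORDER:
            p = self.populations[name]
            sl = population_slice(name)
            self.tau[sl] = p.tau
            self.h[sl] = p.threshold
            self.noise_sd[sl] = p.noise_level
            self._striatal[sl] = p.transfer_kind == "boltzmann"
        self._sigmoid = next(iter(self.populations.values())).sigmoid

        if dt <= 0:
            raise ValueError("dt must be positive")
        if dt > float(np.min(self.tau)) / 5.0:
            raise ValueError(f"dt={dt} too large for tau={np.min(self.tau)} (need dt <= tau/5)")
        self.dt = dt

        # base matrix without plastic weights; plastic entries patched separately
        self._M_static = np.zeros((N_ASSEMBLIES, N_ASSEMBLIES))
        self._plastic: list[tuple[str, str, int, int, float]] = []
        static_table = GainTable([s for s in self.gain_table.specs if not s.plastic])
        self._M_static = static_table.matrix()
        self._plastic = self.gain_table.plastic_entries()
        self._M = self._M_static.copy()
        self.set_weights(None, None)

        self.V = np.zeros(N_ASSEMBLIES)
        self.U = np.zeros(N_ASSEMBLIES)
        self.I_ext = np.zeros(N_ASSEMBLIES)
        self.t = 0.0
        self.reset()

    # -- weights -----------------------------------------------------------
    def set_weights(self, cortico_striatal, cortico_cortical) -> None:
        """Patch plastic entries with gain x weight.

        ``cortico_striatal``: 4-vector over cues (CTX_cog→STR_cog, one-to-one).
        ``cortico_cortical``: 4x4 matrix (cue, location) for CTX_cog→CTX_ass.
        ``None`` means weight 1 (raw printed gain).
        """
        cs = np.ones(4) if cortico_striatal is None else np.asarray(cortico_striatal, float)
        cc = np.ones((4, 4)) if cortico_cortical is None else np.asarray(cortico_cortical, float)
        ctx_cog0 = population_slice("CTX_cog").start
        ctx_ass0 = population_slice("CTX_ass").start
        M = self._M
        M[:, :] = self._M_static
        for pre_pop, post_pop, pre_g, post_g, base in self._plastic:
            if post_pop == "STR_cog":
                w = cs[pre_g - ctx_cog0]
            else:  # CTX_cog -> CTX_ass, assembly (i, j) at 4*i + j
                cell = post_g - ctx_ass0
                w = cc[cell // 4, cell % 4]
            M[post_g, pre_g] = base * w

    # -- state -------------------------------------------------------------
    def reset(self) -> None:
        """Zero activations, outputs re-derived noiselessly, clock to 0."""
        self.V[:] = 0.0
        self.I_ext[:] = 0.0
        self.t = 0.0
        self._update_outputs(noise=False)

    def _update_outputs(self, noise: bool = True) -> None:
        v = self.V
        if noise:
            n = self.rng.standard_normal(N_ASSEMBLIES)
            v = v * (1.0 + n * self.noise_sd)
        self.U = np.where(
            self._striatal,
            boltzmann_transfer(v, self._sigmoid),
            np.maximum(v, 0.0),
        )

    def step(self) -> None:
        """One forward-Euler step of length dt (ms) with a fresh noise draw."""
        I_syn = self._M @ self.U
        self.V += (self.dt / self.tau) * (-self.V + I_syn + self.I_ext + self.h)
        self._update_outputs(noise=True)
        self.t += self.dt

    def settle(self, duration: float) -> None:
        """Run for ``duration`` ms with no external currents applied."""
        for _ in range(int(round(duration / self.dt))):
            self.step()

    def run(self, duration: float, stop=None, record: list[str] | None = None):
        """Integrate for up to ``duration`` ms.

        ``stop(net)`` is evaluated after every step and ends the run early.
        ``record`` lists population names whose V and U trajectories are
        returned as a dict of (n_steps, n_assemblies) arrays, plus "t".
        """
        n_steps = int(round(duration / self.dt))
        traces = None
        if record is not None:
            traces = {"t": []}
            for name in record:
                traces[f"{name}.V"] = []
                traces[f"{name}.U"] = []
        for _ in range(n_steps):
            self.step()
            if traces is not None:
                traces["t"].append(self.t)
                for name in record:
                    sl = population_slice(name)
                    traces[f"{name}.V"].append(self.V[sl].copy())
                    traces[f"{name}.U"].append(self.U[sl].copy())
            if stop is not None and stop(self):
                break
        if traces is not None:
            return {k: np.asarray(v) for k, v in traces.items()}
        return None

    # -- views -------------------------------------------------------------
    def output(self, population: str) -> np.ndarray:
        return self.U[population_slice(population)]

    def activation(self, population: str) -> np.ndarray:
        return self.V[population_slice(population)]

    def state_frame(self) -> pd.DataFrame:
        """Snapshot as tidy CSV-ready table."""
        rows = []
        for name in POPULATION_ORDER:
            p = self.populations[name]
            sl = population_slice(name)
            nrow, ncol = p.geometry
            for k in range(sl.stop - sl.start):
                rows.append((name, k // ncol, k % ncol, self.t,
                             self.V[sl.start + k], self.U[sl.start + k]))
        return pd.DataFrame(
            rows, columns=["population", "assembly_row", "assembly_col", "t_ms", "V", "U"]
        )
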