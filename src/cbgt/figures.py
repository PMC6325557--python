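"""Figure reproduction: single-trial dynamics, protocol performance, traces.

Three figure families mirror the model's main displays:

* ``fig_dynamics`` — motor-loop activity in one trial under the three
  competition regimes (BG loop alone, cortex alone, intact/dual);
* ``fig_protocol`` — start/end performance histograms, the per-trial success
  dot matrix over sessions, and the sliding-window success curves;
* ``fig_session_traces`` — chosen cues, rewards, critic values and plastic
  weights over one session.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .connectivity import apply_lesion, build_default_gain_table
from .network import Network
from .populations import default_populations
from .protocol import DEFAULT_CUE_SET, ProtocolResult, SessionLog, summarize
from .task import Trial, encode_stimuli, read_decision

__all__ = ["fig_dynamics", "fig_protocol", "fig_session_traces"]

_REGIMES = (
    ("cortical_lateral_off", "BG competition only"),
    ("gpi_output_off", "cortical competition only (GPi off)"),
    ("none", "dual competition (intact)"),
)


def fig_dynamics(path: str | Path, seed: int = 0, threshold: float = 40.0):
    """One trial per regime: stimulated motor-cortex activities vs time."""
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6), sharey=True)
    trial = Trial(cues=(0, 1), positions=(0, 1))
    for ax, (lesion, title) in zip(axes, _REGIMES):
        table = apply_lesion(build_default_gain_table(), lesion)
        net = Network(default_populations(), table,
                      rng=np.random.default_rng(seed))
        net.set_weights(np.full(4, 0.5), np.full((4, 4), 0.5))
        net.settle(500)
        net.I_ext = encode_stimuli(trial)
        ts, u0, u1 = [], [], []
        decided_at = None
        for _ in range(2500):
            net.step()
            u = net.output("CTX_mot")
            ts.append(net.t); u0.append(u[0]); u1.append(u[1])
            if decided_at is None and read_decision(u, trial, threshold) is not None:
                decided_at = net.t
        sel = u0 if u0[-1] >= u1[-1] else u1
        oth = u1 if sel is u0 else u0
        ax.plot(ts, sel, "k-", lw=1.2, label="selected")
        ax.plot(ts, oth, "k--", lw=1.0, label="non-selected")
        ax.axvline(500, color="0.7", lw=0.8)
        if decided_at is not None:
            ax.axvline(decided_at, color="C3", lw=0.8, ls=":")
            ax.set_xlabel(f"time (ms) — decision at {decided_at - 500:.0f} ms")
        else:
            ax.set_xlabel("time (ms) — no decision")
        ax.set_title(title, fontsize=10)
    axes[0].set_ylabel("motor cortex U (spikes/s)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def fig_protocol(result: ProtocolResult, path: str | Path, window: int = 10):
    """Histograms, success dot matrix and sliding-window curves per condition."""
    summ = summarize(result, window=window)
    conds = [c for c in ("C0", "C1", "C2") if result.sessions.get(c)]
    fig = plt.figure(figsize=(11, 7))

    ax = fig.add_subplot(2, 2, 1)
    labels, means, sds = [], [], []
    for cond in conds:
        for which in ("start", "end"):
            m = result.session_means(cond, which)
            labels.append(f"{cond}\n{which}")
            means.append(m.mean()); sds.append(m.std(ddof=1))
    ax.bar(range(len(means)), means, yerr=sds, color="0.6", capsize=3)
    ax.set_xticks(range(len(labels)), labels, fontsize=8)
    ax.axhline(0.5, color="0.3", lw=0.8, ls="--")
    ax.set_ylabel("mean performance (first/last 10 trials)")

    ax = fig.add_subplot(2, 2, 2)
    mat = []
    for s in range(len(result.sessions[conds[-1]])):
        row = []
        for cond in conds[1:] if len(conds) > 2 else conds:
            row.extend(1.0 if r.best_chosen else 0.0
                       for r in result.sessions[cond][s].records)
        mat.append(row)
    mat = np.asarray(mat)
    ys, xs = np.nonzero(mat)
    ax.scatter(xs, ys, s=4, c="k", marker="o")
    ys0, xs0 = np.nonzero(1 - mat)
    ax.scatter(xs0, ys0, s=4, facecolors="none", edgecolors="0.6", marker="o")
    ax.axvline(mat.shape[1] / 2 - 0.5, color="C3", lw=0.8)
    ax.set_xlabel("trial (conditions concatenated)")
    ax.set_ylabel("session")
    ax.invert_yaxis()

    ax = fig.add_subplot(2, 1, 2)
    offset = 0
    for cond in conds:
        mean, sd = summ["sliding"][cond]
        x = np.arange(mean.size) + offset
        ax.fill_between(x, mean - sd, mean + sd, alpha=0.25, color="0.5")
        ax.plot(x, mean, "k-", lw=1.4)
        ax.text(offset + mean.size / 2, 1.02, cond, ha="center", fontsize=9)
        offset += mean.size + 8
    ax.axhline(0.5, color="0.3", lw=0.8, ls="--")
    ax.set_ylim(0, 1.1)
    ax.set_ylabel(f"success rate ({window}-trial window)")
    ax.set_xlabel("window position")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def fig_session_traces(log: SessionLog, path: str | Path,
                       cue_labels=("A", "B")):
    """Choices, rewards, critic values and plastic weights over one session."""
    df = log.traces_frame()
    fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=True)

    ax = axes[0]
    for r in log.records:
        if r.chosen_cue is None:
            continue
        y = 1 - r.chosen_cue  # cue A on top
        ax.plot(r.trial_index, y, "o", ms=4,
                color="C3" if r.reward else "k",
                mfc="C3" if r.reward else "none")
    ax.set_yticks([0, 1], [cue_labels[1], cue_labels[0]])
    ax.set_ylabel("chosen cue\n(red = rewarded)")

    ax = axes[1]
    for c, lab in enumerate(cue_labels):
        ax.plot(df.trial_index, df[f"value_{c}"], label=f"value {lab}")
    ax.axhline(DEFAULT_CUE_SET.probabilities[0], color="0.7", lw=0.6, ls=":")
    ax.axhline(DEFAULT_CUE_SET.probabilities[1], color="0.7", lw=0.6, ls=":")
    ax.legend(fontsize=8); ax.set_ylabel("critic value")

    ax = axes[2]
    for c, lab in enumerate(cue_labels):
        ax.plot(df.trial_index, df[f"w_cs_{c}"], label=f"cortico-striatal {lab}")
        ax.plot(df.trial_index, df[f"w_cc_{c}"], "--", label=f"Hebbian {lab}")
    ax.legend(fontsize=8, ncol=2); ax.set_ylabel("weight")
    ax.set_xlabel("trial")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
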