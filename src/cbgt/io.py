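"""Result serialization: trial-log CSVs, summary tables, seed manifests.

One directory per run: a trial-log CSV per (session, condition), a pooled
summary CSV, the statistics report, a config snapshot and a seed manifest
sufficient for a bit-exact rerun.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .protocol import ProtocolResult, SessionLog, TrialRecord
from .stats import analyze_protocol

__all__ = ["write_outputs", "read_trial_logs", "TRIAL_COLUMNS"]

TRIAL_COLUMNS = [
    "session_id", "condition", "trial_index", "cue_A", "cue_B", "pos_A",
    "pos_B", "motor_choice", "cognitive_choice", "chosen_cue", "best_chosen",
    "reward", "decision_time_ms", "failed",
]


def _log_frame(log: SessionLog) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in log.records], columns=TRIAL_COLUMNS)


def write_outputs(result: ProtocolResult, out_dir: str | Path,
                  config_overrides: dict | None = None) -> list[Path]:
    """Write the full protocol result; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for cond, logs in result.sessions.items():
        for log in logs:
            sid = log.records[0].session_id if log.records else 0
            p = out / f"trials_s{sid:02d}_{cond}.csv"
            _log_frame(log).to_csv(p, index=False)
            written.append(p)
            if log.traces:
                p = out / f"traces_s{sid:02d}_{cond}.csv"
                log.traces_frame().to_csv(p, index=False)
                written.append(p)
    p = out / "summary.csv"
    result.summary().to_csv(p, index=False)
    written.append(p)

    report = analyze_protocol(result)
    p = out / "stats.csv"
    report["planned"].to_csv(p, index=False)
    written.append(p)
    p = out / "posthoc.csv"
    report["posthoc"].to_csv(p, index=False)
    written.append(p)

    manifest = {
        "master_seed": result.master_seed,
        "n_sessions": {c: len(v) for c, v in result.sessions.items()},
        "kruskal_H": report["kruskal"][0],
        "kruskal_p": report["kruskal"][1],
        "config_overrides": config_overrides or {},
    }
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2))
    written.append(p)
    return written


def read_trial_logs(out_dir: str | Path) -> pd.DataFrame:
    """Load all trial-log CSVs of a run directory into one tidy frame."""
    out = Path(out_dir)
    frames = [pd.read_csv(p) for p in sorted(out.glob("trials_s*_*.csv"))]
    if not frames:
        raise FileNotFoundError(f"no trial logs under {out}")
    return pd.concat(frames, ignore_index=True)
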