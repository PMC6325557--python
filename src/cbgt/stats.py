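"""Nonparametric analysis of protocol results.

The behavioural samples are six pools of binary success indicators (first/
last 10 trials x three conditions, pooled over sessions).  Analysis follows
the standard rank-based pipeline: a Kruskal-Wallis rank-sum test across the
samples, Dunn's pairwise post hoc z-tests on the pooled ranks (tie-corrected
— essential with 0/1 data), and Benjamini-Hochberg false-discovery-rate
adjustment of the pairwise p values, with significance declared at p < 0.01.

Kruskal-Wallis is delegated to scipy and the BH step to statsmodels; Dunn's
test is implemented here (no installed package provides it).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kruskal_wallis", "dunn_posthoc", "benjamini_hochberg",
    "analyze_protocol", "make_fixture", "SAMPLE_LABELS",
]

SAMPLE_LABELS = ("C0_start", "C0_end", "C1_start", "C1_end", "C2_start", "C2_end")

#: the three planned comparisons of the covert-learning analysis
PLANNED_COMPARISONS = (
    ("C0_start", "C2_start"),
    ("C1_start", "C2_start"),
    ("C1_end", "C2_start"),
)


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.size == 0:
            raise ValueError("empty group")
    return gs


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p value (k-1 df).

    Identical constant groups give H = 0 (scipy raises on all-identical
    data; that degenerate case is mapped to H = 0, p = 1).
    """
    gs = _check_groups(groups)
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*gs)
    return float(H), float(p)


def dunn_posthoc(groups, labels=None, alpha: float = 0.01) -> pd.DataFrame:
    """Dunn's pairwise post hoc test with BH adjustment over all pairs.

    For pooled ranks with tie correction, the pairwise statistic is

        z_ij = (Rbar_i − Rbar_j) / sqrt((N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j))

    with ``T = sum(t^3 − t)`` over tie groups.  Two-sided normal p values are
    BH-adjusted across all pairs.  Returns one row per pair: statistic, raw
    p, adjusted p, significance flag at ``alpha``.
    """
    gs = _check_groups(groups)
    k = len(gs)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    pooled = np.concatenate(gs)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in gs]
    edges = np.cumsum([0] + sizes)
    mean_ranks = [ranks[edges[i]:edges[i + 1]].mean() for i in range(k)]

    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_term = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))

    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((labels[i], labels[j], z, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["group_A", "group_B", "statistic", "p_raw"])
    df["p_adj"] = benjamini_hochberg(df["p_raw"].to_numpy())
    df["significant"] = df["p_adj"] < alpha
    return df


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="fdr_bh")[1]


def analyze_protocol(result, alpha: float = 0.01) -> dict:
    """Full analysis of a covert-learning protocol run.

    Builds the six pooled samples, runs KW across them, Dunn's post hoc over
    all 15 pairs with BH adjustment, and extracts the three planned
    comparisons (C0 start vs C2 start, C1 start vs C2 start, C1 end vs C2
    start).  Returns ``{"kruskal": (H, p), "posthoc": DataFrame,
    "planned": DataFrame, "samples": dict}``.
    """
    samples = {}
    for label in SAMPLE_LABELS:
        cond, which = label.split("_")
        if cond in result.sessions and result.sessions[cond]:
            samples[label] = result.pooled_sample(cond, which)
    labels = list(samples)
    groups = [samples[l] for l in labels]
    H, p = kruskal_wallis(groups)
    posthoc = dunn_posthoc(groups, labels=labels, alpha=alpha)

    planned_rows = []
    for a, b in PLANNED_COMPARISONS:
        hit = posthoc[
            ((posthoc.group_A == a) & (posthoc.group_B == b))
            | ((posthoc.group_A == b) & (posthoc.group_B == a))
        ]
        if len(hit):
            r = hit.iloc[0]
            planned_rows.append((f"{a} = {b}", abs(r.statistic), r.p_adj, r.significant, len(samples[a])))
    planned = pd.DataFrame(
        planned_rows, columns=["H0", "statistic", "p_adj", "significant", "n_per_sample"]
    )
    return {"kruskal": (H, p), "posthoc": posthoc, "planned": planned, "samples": samples}


def make_fixture(p_success, n_sessions: int = 12, n_per: int = 10,
                 seed: int | None = None) -> dict[str, np.ndarray]:
    """Synthetic Bernoulli session logs emulating the six pooled samples.

    ``p_success`` gives one success probability per sample label; each sample
    pools ``n_sessions`` x ``n_per`` independent draws.  Lets the statistics
    stage be exercised without the simulator.
    """
    p_success = list(p_success)
    if len(p_success) != len(SAMPLE_LABELS):
        raise ValueError(f"need {len(SAMPLE_LABELS)} probabilities")
    rng = np.random.default_rng(seed)
    return {
        label: rng.binomial(1, p, size=n_sessions * n_per).astype(float)
        for label, p in zip(SAMPLE_LABELS, p_success)
    }
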