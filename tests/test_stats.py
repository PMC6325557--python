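import math
from itertools import combinations

import numpy as np
import pytest

from cbgt.stats import (SAMPLE_LABELS, analyze_protocol, benjamini_hochberg,
                        dunn_posthoc, kruskal_wallis, make_fixture)

# ---------------------------------------------------------------------------
# independent brute-force oracles (plain-python rank arithmetic; no scipy)
# ---------------------------------------------------------------------------

def _ranks(values):
    """Average ranks with ties, computed by explicit sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kw_oracle(groups):
    pooled = [float(x) for g in groups for x in g]
    n = len(pooled)
    ranks = _ranks(pooled)
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += sum(r) ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for x in pooled:
        counts[x] = counts.get(x, 0) + 1
    t = sum(c**3 - c for c in counts.values())
    corr = 1.0 - t / (n**3 - n)
    return h / corr if corr > 0 else 0.0


def dunn_oracle(groups):
    """Textbook Dunn z statistics with tie correction."""
    pooled = [float(x) for g in groups for x in g]
    n = len(pooled)
    ranks = _ranks(pooled)
    sizes = [len(g) for g in groups]
    means, start = [], 0
    for s in sizes:
        means.append(sum(ranks[start:start + s]) / s)
        start += s
    counts = {}
    for x in pooled:
        counts[x] = counts.get(x, 0) + 1
    ties = sum(c**3 - c for c in counts.values())
    var = n * (n + 1) / 12.0 - ties / (12.0 * (n - 1))
    zs = []
    for i, j in combinations(range(len(groups)), 2):
        se = math.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        zs.append((means[i] - means[j]) / se)
    return zs


def bh_oracle(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_identical_constant_groups(self):
        H, p = kruskal_wallis([[1, 1, 1], [1, 1], [1, 1, 1, 1]])
        assert H == 0.0 and p == 1.0

    def test_matches_rank_formula(self):
        groups = [[1, 2, 3], [4, 5, 6]]
        H, _ = kruskal_wallis(groups)
        assert H == pytest.approx(kw_oracle(groups), abs=1e-12)

    def test_monotone_invariance(self, rng):
        groups = [rng.normal(size=8), rng.normal(1, 1, size=6), rng.normal(2, 1, 5)]
        H1, _ = kruskal_wallis(groups)
        H2, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert H1 == pytest.approx(H2)
        assert H1 >= 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    def test_permutation_null_invariance(self, rng):
        """H is a rank statistic: permuting the pooled data among groups of
        fixed sizes leaves the Monte-Carlo null distribution unchanged."""
        pooled = rng.integers(0, 2, size=30).astype(float)

        def null_mean(perm_rng):
            hs = []
            for _ in range(200):
                p = perm_rng.permutation(pooled)
                hs.append(kruskal_wallis([p[:10], p[10:20], p[20:]])[0])
            return np.mean(hs)

        m1 = null_mean(np.random.default_rng(0))
        m2 = null_mean(np.random.default_rng(99))
        # both estimate the same null mean (~k-1 = 2)
        assert abs(m1 - m2) < 0.4


class TestDunn:
    def test_identical_groups_not_significant(self, rng):
        g = rng.normal(size=30)
        table = dunn_posthoc([g, g.copy()])
        assert table.p_adj.iloc[0] > 0.9
        assert not table.significant.iloc[0]

    def test_matches_textbook_formula(self, rng):
        groups = [rng.normal(0, 1, 7), rng.normal(0.5, 1, 9), rng.normal(2, 1, 6)]
        table = dunn_posthoc(groups)
        expect = dunn_oracle(groups)
        assert np.allclose(table.statistic.to_numpy(), expect, atol=1e-10)

    def test_adjusted_not_below_raw(self, rng):
        groups = [rng.normal(size=10) for _ in range(4)]
        table = dunn_posthoc(groups)
        assert np.all(table.p_adj.to_numpy() >= table.p_raw.to_numpy() - 1e-15)
        assert np.all(table.p_adj.to_numpy() <= 1.0)


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_monotone_and_bounded(self, rng):
        p = rng.random(20)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0)

    def test_matches_oracle(self, rng):
        p = rng.random(15)
        assert np.allclose(benjamini_hochberg(p), bh_oracle(list(p)), atol=1e-12)


class TestOracleEquivalence:
    def test_fifty_random_datasets(self):
        """KW statistic, Dunn z and BH adjustment all agree with the
        brute-force oracles to 1e-8 on 50 random small datasets (including
        heavily tied binary data)."""
        rng = np.random.default_rng(2024)
        for k in range(50):
            n_groups = int(rng.integers(2, 6))
            if k % 2:
                groups = [rng.integers(0, 2, rng.integers(4, 12)).astype(float)
                          for _ in range(n_groups)]
            else:
                groups = [np.round(rng.normal(size=rng.integers(4, 12)), 1)
                          for _ in range(n_groups)]
            if all(np.all(g == groups[0][0]) for g in groups):
                continue
            H, _ = kruskal_wallis(groups)
            assert abs(H - kw_oracle(groups)) < 1e-8
            table = dunn_posthoc(groups)
            assert np.allclose(table.statistic.to_numpy(), dunn_oracle(groups), atol=1e-8)
            assert np.allclose(table.p_adj.to_numpy(),
                               bh_oracle(list(table.p_raw)), atol=1e-8)


class _StubResult:
    """Minimal ProtocolResult stand-in built from a six-sample fixture."""

    def __init__(self, samples):
        self._samples = samples
        self.sessions = {lbl.split("_")[0]: True for lbl in samples}

    def pooled_sample(self, condition, which):
        return self._samples[f"{condition}_{which}"]


class TestAnalyzeProtocol:
    def test_covert_pattern_detected_on_fixture(self):
        samples = make_fixture([0.5, 0.9, 0.5, 0.5, 0.75, 0.9], seed=7)
        report = analyze_protocol(_StubResult(samples))
        planned = report["planned"]
        assert len(planned) == 3
        assert (planned.n_per_sample == 120).all()
        # C1 start vs C2 start separates at 0.5 vs 0.75
        row = planned[planned.H0 == "C1_start = C2_start"].iloc[0]
        assert row.significant

    def test_null_fixture_type_I_control(self):
        """With all six samples at chance, the planned comparisons should
        almost never reach the 0.01 level (nominal FDR control)."""
        hits = 0
        for rep in range(120):
            samples = make_fixture([0.5] * 6, seed=10_000 + rep)
            planned = analyze_protocol(_StubResult(samples))["planned"]
            hits += int(planned.significant.any())
        assert hits / 120 <= 0.05

    def test_fixture_shapes(self):
        samples = make_fixture([0.5] * 6, n_sessions=12, n_per=10, seed=0)
        assert set(samples) == set(SAMPLE_LABELS)
        for v in samples.values():
            assert v.shape == (120,)
            assert set(np.unique(v)) <= {0.0, 1.0}

    def test_fixture_wrong_length(self):
        with pytest.raises(ValueError):
            make_fixture([0.5, 0.5], seed=0)
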