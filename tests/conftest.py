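import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mirpath as mp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_table():
    """4 miRNAs x 3 cell lines with one missing cell (hand-checkable)."""
    dx = np.array(
        [
            [2.0, 1.5, -0.2],
            [0.0, 0.0, 0.0],
            [-1.2, np.nan, -2.0],
            [1.0, 1.0, 1.0],
        ]
    )
    return mp.DifferentialTable(
        ["mA", "mB", "mC", "mD"], ["CL1", "CL2", "CL3"], dx
    )


@pytest.fixture(scope="session")
def default_battery():
    """20 seeded end-to-end runs at the default study conditions.

    Shared by the planted-recovery checks; each entry is the metrics dict
    of one run plus the per-set results needed for set-level assertions.
    """
    runs = []
    for seed in range(1, 21):
        res = mp.run_all(mp.SimulationConfig(seed=seed))
        runs.append(
            {
                "metrics": res.metrics,
                "planted_sets": set(res.truth.planted_sets),
                "selected": {r.name for r in res.selected},
                "config": res.config,
            }
        )
    return runs


def brute_force_binomial_tail(n: int, k: int, p: float) -> float:
    """Enumerate all 2^n per-line outcome vectors and sum tail mass."""
    total = 0.0
    for mask in range(2**n):
        ones = bin(mask).count("1")
        if ones >= k:
            total += p**ones * (1 - p) ** (n - ones)
    return total


def brute_force_hypergeom_tail(m_l: int, n_l: int, m_total: int, M: int) -> float:
    """Direct hypergeometric upper-tail summation with exact integers."""
    import math

    denom = math.comb(M, n_l)
    num = sum(
        math.comb(m_total, i) * math.comb(M - m_total, n_l - i)
        for i in range(m_l, min(n_l, m_total) + 1)
    )
    return num / denom


def naive_average_linkage(d: np.ndarray) -> list[float]:
    """O(n^3) UPGMA on a square dissimilarity matrix; returns merge heights.

    Cluster-to-cluster distance is the mean of all pairwise original
    dissimilarities between members (average linkage).
    """
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                dist = float(
                    np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                )
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights
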