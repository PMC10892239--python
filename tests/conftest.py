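"""Shared fixtures: oracle implementations and synthetic-table builders."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import olfalert as oa
from olfalert.pipeline import simulate_cohort_metrics
from olfalert.stats import BAND_NAMES, METRIC_NAMES

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# --- Brute-force graph-metric oracle (independent of the implementation) ----


def _bfs_distances(adj: list[list[int]], start: int) -> list[float]:
    n = len(adj)
    dist = [float("inf")] * n
    dist[start] = 0
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if dist[v] == float("inf"):
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _all_shortest_paths(adj, dist_from, j, h):
    """Enumerate every shortest path j -> h by DFS along decreasing distance."""
    d = dist_from[j]
    if d[h] == float("inf"):
        return []
    paths = []

    def walk(node, path):
        if node == h:
            paths.append(path)
            return
        for v in adj[node]:
            if d[v] == d[node] + 1 and dist_from[h][v] == d[h] - d[v]:
                walk(v, path + [v])

    walk(j, [j])
    return paths


def brute_force_metrics(A: np.ndarray, normalization: str = "printed") -> dict:
    """Exhaustive nodal metrics on a small binary graph (n <= ~9)."""
    n = A.shape[0]
    adj = [list(np.flatnonzero(A[i])) for i in range(n)]
    dist_from = [_bfs_distances(adj, i) for i in range(n)]

    nd = A.sum(axis=1).astype(float)
    ne = np.array(
        [
            sum(1.0 / dist_from[i][j] for j in range(n)
                if j != i and dist_from[i][j] != float("inf"))
            / max(n - 1, 1)
            for i in range(n)
        ]
    )
    cc = np.zeros(n)
    for i in range(n):
        nbrs = adj[i]
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if A[a, b]
        )
        if len(nbrs) >= 2:
            cc[i] = 2.0 * links / (len(nbrs) * (len(nbrs) - 1))
    raw = np.zeros(n)
    for j, h in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(adj, dist_from, j, h)
        if not paths:
            continue
        for i in range(n):
            if i in (j, h):
                continue
            through = sum(1 for p in paths if i in p)
            raw[i] += through / len(paths)
    if normalization == "printed":
        norm = 2.0 / (n * (n - 1))
    else:
        norm = 2.0 / ((n - 1) * (n - 2))
    return {"ND": nd, "NB": norm * raw, "NE": ne, "CC": cc}


def random_graph(rng: np.random.Generator, n: int, p: float = 0.4) -> np.ndarray:
    A = (rng.random((n, n)) < p).astype(int)
    A = np.triu(A, 1)
    return A + A.T


# --- Synthetic long-format tables (no EEG needed) ---------------------------


def synthetic_std_table(
    n_subjects: int = 30,
    epochs=(6, 7, 8),
    rng: np.random.Generator | None = None,
    effect: dict | None = None,
) -> pd.DataFrame:
    """Standardized metric table over the full 475-triple grid.

    Values are lognormal ratios around 1; ``effect`` maps a condition to
    a dict of multiplicative shifts keyed by (metric, band, channel).
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for k in range(n_subjects):
        for cond in oa.CONDITIONS:
            for e in epochs:
                noise = np.exp(rng.normal(0, 0.1, size=475))
                i = 0
                for metric in METRIC_NAMES:
                    for band in BAND_NAMES:
                        for ch in oa.CHANNELS_1020:
                            v = noise[i]
                            if effect and cond in effect:
                                v *= effect[cond].get((metric, band, ch), 1.0)
                            rows.append(
                                {
                                    "subject_id": f"S{k:02d}",
                                    "condition": cond,
                                    "epoch_group": e,
                                    "channel": ch,
                                    "band": band,
                                    "metric": metric,
                                    "value_raw": v,
                                    "value_std": v,
                                }
                            )
                            i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def table2():
    return oa.load_table2()


@pytest.fixture(scope="session")
def std_table_30():
    """Null standardized table: 30 subjects x 3 epochs x 2 conditions."""
    return synthetic_std_table(n_subjects=30, rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def engineered_cohort():
    """Strong-effect, low-noise cohort with all five metric types.

    8 subjects, alpha_suppression = 0.5, artifacts off; epochs 5-8 at
    2 trials/epoch via the trial-window fast path (the scaled-down
    replicate-cohort conditions).
    """
    sim = oa.SimConfig(
        n_subjects=8, fs_hz=125.0, alpha_suppression=0.5,
        artifacts_enabled=False, seed=42,
    )
    std_table, events = simulate_cohort_metrics(
        sim, epochs=(5, 6, 7, 8), trials_per_epoch=2, metrics="all"
    )
    return std_table, events
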