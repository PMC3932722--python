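"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from math import comb

import networkx as nx
import pytest

from addnet.records import DrugRecord
from addnet.simulate import SimulationConfig, simulate_drug_target_data


def make_drug(drug_id, targets=(), category="none", atc=(), name=None):
    return DrugRecord(
        drug_id=drug_id,
        name=name or drug_id,
        nida_category=category,
        targets=set(targets),
        atc_codes=set(atc),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset, shared read-only across tests."""
    config = SimulationConfig(seed=7)
    addictive, pool, targets = simulate_drug_target_data(config)
    return config, addictive, pool, targets


# ---------------------------------------------------------------------------
# betweenness oracle: BFS distances + path-count DP, no networkx algorithms


def brute_force_betweenness(graph: nx.Graph, normalized: bool = True) -> dict:
    """Betweenness via sigma_sv * sigma_vt products over BFS shortest paths."""
    nodes = list(graph.nodes)
    n = len(nodes)
    adj = {u: list(graph.neighbors(u)) for u in nodes}

    def bfs(source):
        dist = {source: 0}
        sigma = {source: 1}
        queue = deque([source])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        return dist, sigma

    info = {u: bfs(u) for u in nodes}
    score = {u: 0.0 for u in nodes}
    for s in nodes:
        dist_s, sigma_s = info[s]
        for t in nodes:
            if t is s or t not in dist_s:
                continue
            dist_t, sigma_t = info[t]
            for v in nodes:
                if v is s or v is t or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == dist_s[t]:
                    score[v] += sigma_s[v] * sigma_t[v] / sigma_s[t]
    for v in score:
        score[v] /= 2.0  # each unordered pair counted twice
    if normalized and n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        for v in score:
            score[v] *= scale
    return score


# ---------------------------------------------------------------------------
# Fisher oracle: exact rational enumeration of all tables with fixed margins


def enumerate_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Sum of point probabilities <= that of the observed table (exact)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p <= p_obs:
            total += p
    return float(total)


def enumerate_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """Exact upper tail P(X >= a) with X hypergeometric over the margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    total = Fraction(0)
    for x in range(a, min(r1, c1) + 1):
        total += Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    return float(total)
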