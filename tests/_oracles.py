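"""Independent reference implementations used across the test suite.

Each oracle is deliberately naive (exact rationals, brute-force deletion,
direct formulas) and shares no code with the package.
"""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np


def fisher_exact_oracle(nf, n, Nf, N):
    """Exact-rational two-sided Fisher p by full hypergeometric enumeration."""
    if n == 0 or Nf == 0 or n == N or Nf == N:
        return Fraction(1)
    denom = comb(N, n)
    observed = Fraction(comb(Nf, nf) * comb(N - Nf, n - nf), denom)
    total = Fraction(0)
    for x in range(max(0, n + Nf - N), min(n, Nf) + 1):
        px = Fraction(comb(Nf, x) * comb(N - Nf, n - x), denom)
        if px <= observed:
            total += px
    return total


def valid_tables(max_N):
    """All consistent (nf, n, Nf, N) category tables with N <= max_N."""
    for N in range(1, max_N + 1):
        for n in range(N + 1):
            for Nf in range(N + 1):
                for nf in range(max(0, n + Nf - N), min(n, Nf) + 1):
                    yield nf, n, Nf, N


def kcore_oracle(graph):
    """Brute-force core indices: for each k, repeatedly delete nodes of
    degree < k; a node's core index is the largest k it survives."""
    core = {node: 0 for node in graph.nodes}
    max_deg = max((d for _, d in graph.degree()), default=0)
    for k in range(1, max_deg + 1):
        g = graph.copy()
        while True:
            victims = [n for n, d in g.degree() if d < k]
            if not victims:
                break
            g.remove_nodes_from(victims)
        for node in g.nodes:
            core[node] = k
    return core


def random_graph(seed, max_nodes=12):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, max_nodes + 1))
    p = float(rng.uniform(0.05, 0.9))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g


def correlation_oracle(x, y):
    """Pearson r straight from the covariance formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
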