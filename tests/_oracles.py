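"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths (igraph, numpy
vectorization) so they can certify it: betweenness by exhaustive simple-path
enumeration, Pearson r by the textbook sum formula.
"""

import numpy as np


def brute_force_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness by enumerating every simple path.

    For each unordered node pair, all simple paths are generated, the
    geodesics (minimum-length paths) kept, and each interior node credited
    with its fraction of geodesics.  Exponential — only for tiny graphs.
    """
    n = adj.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_simple_paths(adj, s, t)
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            geos = [p for p in paths if len(p) == shortest]
            for p in geos:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(geos)
    return bc


def _all_simple_paths(adj: np.ndarray, s: int, t: int) -> list[list[int]]:
    out: list[list[int]] = []
    stack = [[s]]
    while stack:
        path = stack.pop()
        u = path[-1]
        if u == t:
            out.append(path)
            continue
        for v in np.nonzero(adj[u])[0]:
            if v not in path:
                stack.append(path + [int(v)])
    return out


def pearson_by_hand(x, y) -> float:
    """Textbook Pearson formula with explicit sums."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x * x).sum() - sx**2) * np.sqrt(n * (y * y).sum() - sy**2)
    return float(num / den)
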