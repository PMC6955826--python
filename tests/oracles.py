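"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration, dense eigendecomposition) and shares no code with the
package, so agreement is a genuine two-route check.
"""

from __future__ import annotations

import itertools
from math import sqrt

import numpy as np


def naive_distance_correlation(x, y) -> float:
    """Biased V-statistic dCor by explicit double centering with loops."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)

    def centered(v):
        d = [[abs(v[i] - v[j]) for j in range(n)] for i in range(n)]
        rm = [sum(row) / n for row in d]
        cm = [sum(d[i][j] for i in range(n)) / n for j in range(n)]
        gm = sum(rm) / n
        return [[d[i][j] - rm[i] - cm[j] + gm for j in range(n)] for i in range(n)]

    A, B = centered(x), centered(y)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    dvx = sum(A[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    dvy = sum(B[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    return sqrt(max(dcov2, 0.0) / sqrt(dvx * dvy))


def _all_paths(adj: dict[int, dict[int, float]], s: int, t: int):
    """All simple paths s -> t with their total lengths, by DFS."""
    out = []

    def walk(node, visited, length, path):
        if node == t:
            out.append((length, list(path)))
            return
        for nbr, w in adj[node].items():
            if nbr not in visited:
                visited.add(nbr)
                path.append(nbr)
                walk(nbr, visited, length + w, path)
                path.pop()
                visited.remove(nbr)

    walk(s, {s}, 0.0, [s])
    return out


def brute_betweenness(weights: np.ndarray, retained: np.ndarray) -> np.ndarray:
    """Betweenness by exhaustive geodesic enumeration on 1/w lengths.

    Fractional credit for tied geodesics; normalized by (n-1)(n-2)/2.
    """
    n = weights.shape[0]
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    for i in range(n):
        for j in range(n):
            if i != j and retained[i, j]:
                adj[i][j] = 1.0 / weights[i, j]
    score = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_paths(adj, s, t)
        if not paths:
            continue
        best = min(length for length, _ in paths)
        geodesics = [p for length, p in paths if length <= best * (1 + 1e-12)]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in geodesics if v in p)
            score[v] += through / len(geodesics)
    if n > 2:
        score /= (n - 1) * (n - 2) / 2
    return score


def dense_eigencentrality(weights: np.ndarray, retained: np.ndarray) -> np.ndarray:
    """Leading eigenvector by full symmetric eigendecomposition."""
    a = np.where(retained, weights, 0.0)
    evals, evecs = np.linalg.eigh(a)
    v = np.abs(evecs[:, np.argmax(evals)])
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else v


def exhaustive_assignment(score: np.ndarray) -> tuple[float, tuple[int, ...]]:
    """Best injective rows -> columns assignment by enumerating all of them."""
    n_rows, n_cols = score.shape
    best_total, best_perm = -np.inf, None
    for perm in itertools.permutations(range(n_cols), n_rows):
        total = sum(score[r, c] for r, c in enumerate(perm))
        if total > best_total:
            best_total, best_perm = total, perm
    return best_total, best_perm
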