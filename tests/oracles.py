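"""Independent brute-force oracles used to cross-check the package's
metric and turning-score implementations.

Each oracle takes a deliberately different computational route from the
implementation it checks (pair counting instead of contingency algebra,
plain Python loops instead of vectorized matrices)."""

import math
from itertools import combinations

import numpy as np


def ari_pair_counting(u, v) -> float:
    """ARI via exhaustive enumeration of sample pairs.

    Counts the four pair categories (together in both partitions,
    together in one only, apart in both) and applies the pair-count form
    of the adjusted Rand index.
    """
    u = list(u)
    v = list(v)
    s11 = s10 = s01 = s00 = 0
    for i, j in combinations(range(len(u)), 2):
        same_u = u[i] == u[j]
        same_v = v[i] == v[j]
        if same_u and same_v:
            s11 += 1
        elif same_u:
            s10 += 1
        elif same_v:
            s01 += 1
        else:
            s00 += 1
    num = 2.0 * (s11 * s00 - s10 * s01)
    den = (s11 + s10) * (s10 + s00) + (s11 + s01) * (s01 + s00)
    if den == 0:  # both partitions trivial
        return 1.0
    return num / den


def nmi_loops(x, y) -> float:
    """NMI 2I/(H+H) via dictionary counting and scalar logs."""
    x = list(x)
    y = list(y)
    n = len(x)
    cx: dict = {}
    cy: dict = {}
    cxy: dict = {}
    for a, b in zip(x, y):
        cx[a] = cx.get(a, 0) + 1
        cy[b] = cy.get(b, 0) + 1
        cxy[(a, b)] = cxy.get((a, b), 0) + 1
    hx = -sum((c / n) * math.log(c / n) for c in cx.values())
    hy = -sum((c / n) * math.log(c / n) for c in cy.values())
    if hx == 0 and hy == 0:
        return 1.0
    if hx == 0 or hy == 0:
        return 0.0
    mi = 0.0
    for (a, b), c in cxy.items():
        mi += (c / n) * math.log(n * c / (cx[a] * cy[b]))
    return 2.0 * mi / (hx + hy)


def knn_impute_bruteforce(values: np.ndarray, f: int, s: int, k: int) -> float:
    """Fill value for missing entry (f, s) by explicit loops: Euclidean
    distance to every other feature over co-observed samples, keep the k
    nearest among features observed at s, average their values at s."""
    n_feat = values.shape[0]
    cands = []
    for g in range(n_feat):
        if g == f or np.isnan(values[g, s]):
            continue
        both = ~np.isnan(values[f]) & ~np.isnan(values[g])
        if not both.any():
            continue
        d = math.sqrt(float(((values[f, both] - values[g, both]) ** 2).sum()))
        cands.append((d, g))
    cands.sort(key=lambda t: t[0])
    nearest = [g for _, g in cands[:k]]
    return float(np.mean([values[g, s] for g in nearest]))


def turning_score_two_forms(dims, ev, i: int, delta: float) -> tuple[float, float]:
    """Both printed forms of the turning score at 0-based index i,
    evaluated with scalar loops."""

    def h(a: int, b: int) -> float:
        if dims[a] == dims[b]:
            return 0.0
        return (ev[b] - ev[a]) / abs(dims[b] - dims[a]) ** delta

    n = len(dims)
    form1 = sum(h(k, i) for k in range(0, i)) - sum(h(i, k) for k in range(i + 1, n))
    form2 = sum(h(k, i) for k in range(n))
    return form1, form2


def random_partition(rng: np.random.Generator, n: int, max_k: int) -> np.ndarray:
    """A uniform random labelling of n samples into at most max_k groups."""
    k = int(rng.integers(1, max_k + 1))
    return rng.integers(1, k + 1, size=n)


def random_monotone_curve(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """A random non-decreasing EV curve on dims 1..n with values in (0, 1]."""
    incs = rng.random(n)
    ev = np.cumsum(incs)
    ev = ev / ev[-1] * rng.uniform(0.5, 1.0)
    return np.arange(1, n + 1), ev
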