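"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library's own code paths: medians by
per-pixel sorting, matchings by exhaustive search, signed-rank p-values
by full sign-pattern enumeration, orientations by dense angle scanning.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_median_stack(stack: np.ndarray) -> np.ndarray:
    """Per-pixel median via explicit sort (mean of central two if even)."""
    n, h, w = stack.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            v = np.sort(stack[:, r, c])
            out[r, c] = v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2])
    return out


def brute_min_cost_matching(cost: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Exhaustive maximum-cardinality, minimum-total-cost matching.

    ``cost`` may contain ``inf`` for infeasible pairs.  Searches every
    injective assignment of clusters to tracks (including leaving any
    subset unmatched) by recursion.
    """
    nt, nc = cost.shape
    best: dict = {"pairs": [], "card": 0, "cost": 0.0}

    def rec(i: int, used: set, pairs: list, total: float) -> None:
        if i == nt:
            card = len(pairs)
            if card > best["card"] or (card == best["card"] and total < best["cost"] - 1e-12):
                best["pairs"], best["card"], best["cost"] = list(pairs), card, total
            return
        rec(i + 1, used, pairs, total)  # leave track i unmatched
        for j in range(nc):
            if j in used or math.isinf(cost[i, j]):
                continue
            used.add(j)
            pairs.append((i, j))
            rec(i + 1, used, pairs, total + cost[i, j])
            pairs.pop()
            used.discard(j)

    rec(0, set(), [], 0.0)
    return best["pairs"], best["cost"]


def brute_wilcoxon(values_off, values_on) -> tuple[int, float, float]:
    """Exact two-sided signed-rank test by full 2^n enumeration."""
    d = np.asarray(values_on, dtype=float) - np.asarray(values_off, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0, 0.0, 1.0
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sv = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w = float(ranks[d > 0].sum())
    s = float(ranks.sum())
    dev = abs(w - s / 2)
    count = sum(1 for signs in itertools.product((0, 1), repeat=n)
                if abs(sum(r for r, sg in zip(ranks, signs) if sg) - s / 2) >= dev - 1e-12)
    return n, w, count / 2 ** n


def brute_principal_axis(coords: np.ndarray, n_angles: int = 3600) -> float:
    """Orientation maximising the projected variance, by dense angle scan."""
    rows, cols = coords[:, 0].astype(float), coords[:, 1].astype(float)
    dx, dy = cols - cols.mean(), rows - rows.mean()
    best_theta, best_var = 0.0, -1.0
    for theta in np.linspace(0, np.pi, n_angles, endpoint=False):
        p = dx * np.cos(theta) + dy * np.sin(theta)
        v = float(np.var(p))
        if v > best_var:
            best_var, best_theta = v, theta
    return best_theta


def angle_diff_mod_pi(a: float, b: float) -> float:
    d = abs(a - b) % np.pi
    return min(d, np.pi - d)
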