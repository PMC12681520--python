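"""Independent brute-force oracles used only by the test suite.

These implement the textbook definitions directly (enumeration, literal
step-down/step-up formulas) so the package implementations are checked
against a path they do not share.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def holm_sidak_brute(p: np.ndarray) -> np.ndarray:
    """Literal Holm-Sidak step-down: sort ascending, adjusted p_i =
    max_{j<=i} [1 - (1 - p_(j))^(m - j + 1)], clipped to 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):  # rank 0-based => j = rank + 1
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj


def bh_brute(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: sorted ascending, adjusted
    p_(i) = min_{j>=i} [p_(j) * m / j], clipped to 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):  # from largest p down
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = min(1.0, running)
    return adj


def mannwhitney_exact_brute(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration of group
    assignments of the pooled (tie-free) sample."""
    a = list(a)
    b = list(b)
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    n_a = len(a)

    def u_stat(group_a):
        rest = [x for x in pooled if x not in group_a]
        return sum(1 for x in group_a for y in rest if x > y)

    u_obs = u_stat(a)
    mean_u = n_a * len(b) / 2
    arrangements = list(combinations(pooled, n_a))
    u_all = np.array([u_stat(set(g)) for g in arrangements], dtype=float)
    p = np.mean(np.abs(u_all - mean_u) >= abs(u_obs - mean_u))
    return (float(u_obs), float(p))
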