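"""Brute-force Mann-Whitney oracle: full enumeration over rank assignments.

Independent of the implementation path (which delegates to scipy): the
two-sided p-value is computed by enumerating every C(n_x + n_y, n_x)
assignment of pooled ranks to the first sample and counting U statistics.
Only valid for tie-free pooled samples.
"""

from itertools import combinations

import numpy as np


def mann_whitney_u(x, y) -> float:
    """U statistic of x vs y: number of (x_i, y_j) pairs with x_i > y_j."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float((x[:, None] > y[None, :]).sum())


def exact_two_sided_p(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    ranks = pooled.argsort().argsort()  # 0-based ranks, tie-free
    u_obs = mann_whitney_u(x, y)

    # U depends on the ranks assigned to x only: U = sum(ranks_x) - n_x(n_x-1)/2
    all_idx = range(n_x + n_y)
    us = []
    for combo in combinations(all_idx, n_x):
        r = sum(sorted(ranks)[i] for i in combo)
        us.append(r - n_x * (n_x - 1) / 2)
    us = np.asarray(us)
    p_le = float((us <= u_obs).mean())
    p_ge = float((us >= u_obs).mean())
    return min(1.0, 2.0 * min(p_le, p_ge))
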