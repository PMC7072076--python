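"""Independent brute-force oracles shared by the statistics tests."""

import itertools
import math

import numpy as np


def mw_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney by enumerating all group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    mn = n1 * len(y)
    u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1 for a in g1 for b in g2 if a > b)
                  + 0.5 * sum(1 for a in g1 for b in g2 if a == b))
    us = np.array(us)
    extreme = np.abs(us - mn / 2.0) >= abs(u_obs - mn / 2.0) - 1e-12
    return u_obs, extreme.mean()


def table_prob(table):
    """Exact conditional probability of a 2xk table (rational arithmetic)."""
    t = np.asarray(table, int)
    cols = t.sum(axis=0)
    n = int(t.sum())
    r1 = int(t[0].sum())
    num = 1
    for j, c in enumerate(cols):
        num *= math.comb(int(c), int(t[0, j]))
    return num / math.comb(n, r1)


def exact_2xk_oracle(table):
    """Two-sided exact independence test by direct table enumeration."""
    t = np.asarray(table, int)
    cols = t.sum(axis=0).tolist()
    r1 = int(t[0].sum())
    p_obs = table_prob(t)
    total = 0.0
    for cells in itertools.product(*[range(c + 1) for c in cols]):
        if sum(cells) != r1:
            continue
        cand = np.array([list(cells), [c - a for c, a in zip(cols, cells)]])
        p = table_prob(cand)
        if p <= p_obs * (1 + 1e-10):
            total += p
    return min(1.0, total)
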