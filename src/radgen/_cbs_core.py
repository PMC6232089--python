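"""JIT-compiled inner kernel for circular binary segmentation.

The kernel scans every circular arc split of an ordered interval and returns
the maximal two-sample t statistic between arc and complement. Enumerating
linear sub-arcs [i, j) suffices: a wrap-around arc is the complement of a
linear one and the statistic is symmetric under swapping the two groups.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_INF = np.inf


@njit(cache=True)
def max_arc_tstat(x: np.ndarray, min_seg: int):
    """Maximal |t| over arcs [i, j) with both groups >= min_seg probes.

    Returns (stat, i, j); ties resolve to the lexicographically first (i, j).
    A zero pooled within-group variance with distinct means yields stat=inf
    (an exact change point).
    """
    n = x.shape[0]
    if n < 2 * min_seg:
        return 0.0, 0, n
    s = np.empty(n + 1)
    q = np.empty(n + 1)
    s[0] = 0.0
    q[0] = 0.0
    for a in range(n):
        s[a + 1] = s[a] + x[a]
        q[a + 1] = q[a] + x[a] * x[a]
    total = s[n]
    total_sq = q[n]
    best = 0.0
    bi = 0
    bj = n
    df = n - 2
    for i in range(0, n - min_seg + 1):
        jmax = min(n, i + (n - min_seg)) + 1
        for j in range(i + min_seg, jmax):
            k = j - i
            l = n - k
            if l < min_seg:
                continue
            s1 = s[j] - s[i]
            m1 = s1 / k
            m2 = (total - s1) / l
            ss_within = total_sq - k * m1 * m1 - l * m2 * m2
            if ss_within < 0.0:
                ss_within = 0.0
            if df > 0 and ss_within > 1e-12 * max(total_sq, 1.0):
                sp2 = ss_within / df
                t = abs(m1 - m2) / np.sqrt(sp2 * (1.0 / k + 1.0 / l))
            else:
                t = _INF if abs(m1 - m2) > 1e-12 else 0.0
            if t > best:
                best = t
                bi = i
                bj = j
    return best, bi, bj
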