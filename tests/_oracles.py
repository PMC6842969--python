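"""Independent brute-force reference implementations.

Deliberately written as plain Python loops over samples, with no shared
code with the package, so they can serve as oracles for the vectorized
implementations.
"""

from __future__ import annotations

import cmath
import math
from itertools import combinations


def mvl_oracle(phi, a):
    s = 0j
    for p, amp in zip(phi, a):
        s += amp * cmath.exp(1j * p)
    return abs(s / len(phi))


def plhg_oracle(phi, a, phi_env, baseline_mean):
    s = 0j
    for p, amp, pe in zip(phi, a, phi_env):
        s += (amp / baseline_mean) * cmath.exp(1j * (p - pe))
    return abs(s / len(phi))


def plv_oracle(phi, phi_env):
    s = 0j
    for p, pe in zip(phi, phi_env):
        s += cmath.exp(1j * (p - pe))
    return abs(s / len(phi))


def hfo_power_oracle(a):
    return sum(a) / len(a)


def mi_oracle(phi, a, n_bins=18, phase_correction=True):
    width = 2.0 * math.pi / n_bins
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for p, amp in zip(phi, a):
        i = int((p + math.pi) // width)
        i = min(max(i, 0), n_bins - 1)
        sums[i] += amp
        counts[i] += 1
    if not any(s > 0 for s in sums):
        return 0.0
    mean_amp = [s / c if c else 0.0 for s, c in zip(sums, counts)]
    total = sum(mean_amp)
    p_dist = [m / total for m in mean_amp]
    if phase_correction:
        n = len(phi)
        q = [c / n for c in counts]
        p_dist = [max(pi - qi + 1.0 / n_bins, 0.0) for pi, qi in zip(p_dist, q)]
        tot = sum(p_dist)
        p_dist = [pi / tot for pi in p_dist] if tot > 0 else [0.0] * n_bins
    dkl = 0.0
    for pi in p_dist:
        if pi > 0:
            dkl += pi * math.log(pi * n_bins)
    return dkl / math.log(n_bins)


def mannwhitney_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p-value by full enumeration.

    Enumerates every assignment of the pooled observations to the two
    groups, computes the U statistic of the first group for each, and
    reports 2 * min(P(U <= u), P(U >= u)) capped at 1.  Valid for
    tie-free data.
    """

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi) + 0.5 * sum(
            1 for xi in xs for yi in ys if xi == yi
        )

    u_obs = u_stat(x, y)
    pooled = list(x) + list(y)
    n = len(x)
    us = []
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(xs, ys))
    le = sum(1 for u in us if u <= u_obs) / len(us)
    ge = sum(1 for u in us if u >= u_obs) / len(us)
    return min(1.0, 2.0 * min(le, ge))
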