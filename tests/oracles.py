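"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results with naive loops and exhaustive
enumeration, sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def dive_runs(depth, threshold=3.0, eps=0.5):
    """Naive scan for dives: samples > threshold grouped into runs, each
    extended outward sample by sample until depth <= eps."""
    n = len(depth)
    above = [d > threshold for d in depth]
    runs = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    out = []
    prev_end = 0
    for s, e in runs:
        while s > prev_end and depth[s - 1] > eps:
            s -= 1
        while e < n and depth[e] > eps:
            e += 1
        if e < n:
            e += 1
        if out and s < out[-1][1]:
            s = out[-1][1]
        out.append((s, e))
        prev_end = e
    return out


def slow_runs(depth, rate=0.4):
    """Maximal runs of |1-s rate| < threshold, as (start, end) rate indices."""
    r = [depth[i + 1] - depth[i] for i in range(len(depth) - 1)]
    runs = []
    i = 0
    while i < len(r):
        if abs(r[i]) < rate:
            j = i
            while j < len(r) and abs(r[j]) < rate:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def transit_steps(depth, max_depth, rate=0.4, max_s=8, frac=0.6):
    count = 0
    for s, e in slow_runs(depth, rate):
        length = e - s
        mean_depth = float(np.mean(depth[s:e + 1]))
        if 1 <= length < max_s and mean_depth < frac * max_depth:
            count += 1
    return count


def bottom_steps(depth, rate=0.4, max_s=8):
    """(descending, ascending) interval lists via naive same-sign fast runs."""
    r = [depth[i + 1] - depth[i] for i in range(len(depth) - 1)]
    desc, asc = [], []
    for sign, sink in ((1, desc), (-1, asc)):
        i = 0
        while i < len(r):
            if sign * r[i] > rate:
                j = i
                while j < len(r) and sign * r[j] > rate:
                    j += 1
                if 1 <= j - i < max_s:
                    sink.append((i, j))
                i = j
            else:
                i += 1
    return desc, asc


def max_wiggles(asc, desc, gap=3.0):
    """Maximum number of disjoint (ascending, next descending) pairs with
    separation < gap, by exhaustive recursion over pairing choices."""
    asc = sorted(asc)
    desc = sorted(desc)

    def rec(ai, used):
        if ai == len(asc):
            return 0
        best = rec(ai + 1, used)  # skip this ascending step
        a_end = asc[ai][1]
        for di, (ds, de) in enumerate(desc):
            if di in used or ds < a_end:
                continue
            if ds - a_end < gap:
                best = max(best, 1 + rec(ai + 1, used | {di}))
            break  # only the next descending step can follow "in succession"
        return best

    return rec(0, frozenset())


def cindex(obs, pred):
    """O(n^2) concordance index: pairs with unequal observations; tied
    predictions score one half."""
    num = 0.0
    den = 0
    n = len(obs)
    for i in range(n):
        for j in range(i + 1, n):
            if obs[i] == obs[j]:
                continue
            den += 1
            if pred[i] == pred[j]:
                num += 0.5
            elif (obs[i] < obs[j]) == (pred[i] < pred[j]):
                num += 1.0
    return num / den


def random_profile(rng):
    """A random 1-Hz dive-like depth profile mixing fast/slow/flat segments
    (for exact-count comparison between detectors and oracles)."""
    deltas = []
    for _ in range(rng.integers(5, 25)):
        kind = rng.integers(0, 4)
        length = int(rng.integers(1, 9))
        if kind == 0:
            rate = 0.0
        elif kind == 1:
            rate = float(rng.uniform(0.45, 1.5))
        elif kind == 2:
            rate = float(-rng.uniform(0.45, 1.5))
        else:
            rate = float(rng.uniform(-0.39, 0.39))
        deltas.extend([rate] * length)
    depth = 20.0 + np.cumsum(deltas)
    return np.asarray(depth)
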