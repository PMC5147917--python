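"""Independently coded brute-force oracles used by the test suite.

Each function re-derives a quantity from its definition with the most naive
algorithm available (full scans, explicit loops, exhaustive enumeration),
sharing no code path with the package implementation.
"""

from __future__ import annotations

import itertools
import math


def swarii_oracle(timestamps, values, rate, window, n_out):
    """Collect-window-then-average-then-interpolate, one grid point at a time."""
    t0 = timestamps[0]
    half = window / 2.0
    means = []
    for k in range(n_out):
        g = t0 + k / rate
        bucket = [v for t, v in zip(timestamps, values) if g - half <= t <= g + half]
        means.append(sum(bucket) / len(bucket) if bucket else None)
    # linear interpolation across empty windows; constant extension at ends
    known = [k for k, m in enumerate(means) if m is not None]
    out = []
    for k, m in enumerate(means):
        if m is not None:
            out.append(m)
            continue
        left = max((j for j in known if j < k), default=None)
        right = min((j for j in known if j > k), default=None)
        if left is None:
            out.append(means[right])
        elif right is None:
            out.append(means[left])
        else:
            w = (k - left) / (right - left)
            out.append(means[left] * (1 - w) + means[right] * w)
    return out


def percentile_oracle(values, q):
    """Linear interpolation at sorted position (n - 1) * q."""
    s = sorted(values)
    pos = (len(s) - 1) * q
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def radius_oracle(ml, ap):
    mml = sum(ml) / len(ml)
    map_ = sum(ap) / len(ap)
    return [math.sqrt((x - mml) ** 2 + (y - map_) ** 2) for x, y in zip(ml, ap)]


def acceleration_oracle(ml, ap, rate):
    out = []
    for k in range(1, len(ml) - 1):
        axx = (ml[k + 1] - 2 * ml[k] + ml[k - 1]) * rate * rate
        ayy = (ap[k + 1] - 2 * ap[k] + ap[k - 1]) * rate * rate
        out.append(math.sqrt(axx * axx + ayy * ayy))
    return out


def sway_density_oracle(ml, ap, dt, radius):
    """Quadratic first-exit scan over all (i, j) pairs."""
    n = len(ml)
    dwell = []
    for i in range(n):
        steps = n - i
        for j in range(i + 1, n):
            d = math.sqrt((ml[j] - ml[i]) ** 2 + (ap[j] - ap[i]) ** 2)
            if d > radius:
                steps = j - i
                break
        dwell.append(steps * dt)
    return dwell


def variance_oracle(values):
    """Unbiased (n - 1) variance from the definition."""
    n = len(values)
    mean = sum(values) / n
    return sum((v - mean) ** 2 for v in values) / (n - 1)


def local_maxima_oracle(values):
    """Indices of strict local maxima of a sequence."""
    return [i for i in range(1, len(values) - 1)
            if values[i] > values[i - 1] and values[i] > values[i + 1]]


def auc_pairwise_oracle(scores, labels):
    """Positive-negative pair statistic with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def mannwhitney_exact_oracle(a, b):
    """Two-tailed exact p by exhaustive enumeration of rank assignments."""
    combined = sorted(a) + sorted(b)
    n, m = len(a), len(b)
    ranks = {v: r for r, v in enumerate(sorted(combined), start=1)}
    u_obs = sum(ranks[v] for v in a) - n * (n + 1) / 2
    u_all = []
    all_ranks = list(range(1, n + m + 1))
    for comb in itertools.combinations(all_ranks, n):
        u_all.append(sum(comb) - n * (n + 1) / 2)
    total = len(u_all)
    lo = sum(1 for u in u_all if u <= u_obs) / total
    hi = sum(1 for u in u_all if u >= u_obs) / total
    return min(1.0, 2.0 * min(lo, hi))


def cross_entropy_oracle(labels):
    """Node impurity from the definition, natural log."""
    n = len(labels)
    k = sum(labels)
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return -(p * math.log(p) + (1 - p) * math.log(1 - p))


def best_split_oracle(X, y):
    """Exhaustive (feature, midpoint threshold) search minimising the
    size-weighted child cross-entropy; ties keep the first in
    (feature, threshold) scan order."""
    n = len(y)
    best = None
    best_imp = float("inf")
    for f in range(len(X[0])):
        vals = sorted(set(row[f] for row in X))
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2
            left = [y[i] for i in range(n) if X[i][f] <= thr]
            right = [y[i] for i in range(n) if X[i][f] > thr]
            imp = (len(left) * cross_entropy_oracle(left)
                   + len(right) * cross_entropy_oracle(right)) / n
            if imp < best_imp - 1e-15:
                best_imp = imp
                best = (f, thr)
    return best
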