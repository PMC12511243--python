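"""Independent naive reference implementations used only by the tests.

Everything here is written with explicit loops and textbook formulas,
deliberately sharing no code with the package, so that each package
operation can be checked against an implementation that could not have
inherited its bugs.
"""

from __future__ import annotations

import math

import numpy as np


# -- moments / quantiles ----------------------------------------------------

def naive_moments(x):
    """(mean, median, sd, var, skew, kurt) with population (1/n) moments."""
    n = len(x)
    mean = sum(x) / n
    xs = sorted(x)
    if n % 2 == 1:
        median = xs[n // 2]
    else:
        median = (xs[n // 2 - 1] + xs[n // 2]) / 2
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    if sd == 0:
        return mean, median, sd, var, 0.0, 0.0
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    return mean, median, sd, var, m3 / sd**3, m4 / sd**4


def naive_quantile(x, q):
    """Type-7 (linear interpolation) quantile."""
    xs = sorted(x)
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def naive_iqr(x):
    return naive_quantile(x, 0.75) - naive_quantile(x, 0.25)


# -- signal statistics ------------------------------------------------------

def naive_zcr(x):
    """Strict sign changes per adjacent pair; zeros carry the last sign."""
    last = 0
    signs = []
    for v in x:
        s = int(v > 0) - int(v < 0)
        if s == 0:
            s = last
        signs.append(s)
        if s != 0:
            last = s
    count = 0
    for a, b in zip(signs[:-1], signs[1:]):
        if a != 0 and b != 0 and a != b:
            count += 1
    return count / (len(x) - 1)


def naive_entropy(x, bins=16):
    """-sum p log2 p over an equal-width histogram spanning [min, max]."""
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    # equal-width edge values as linspace computes them (edge placement is
    # part of the histogram definition); the counting below stays naive
    edges = list(np.linspace(lo, hi, bins + 1))
    counts = [0] * bins
    for v in x:
        for b in range(bins):
            # last bin is closed on the right (numpy histogram convention)
            if edges[b] <= v < edges[b + 1] or (b == bins - 1 and v == edges[-1]):
                counts[b] += 1
                break
    h = 0.0
    for c in counts:
        if c:
            p = c / len(x)
            h -= p * math.log2(p)
    return h


def naive_kte(x):
    return [x[i] ** 2 - x[i - 1] * x[i + 1] for i in range(1, len(x) - 1)]


def naive_savgol_smoothed_diff(x, window=9, order=3):
    """First difference followed by Savitzky-Golay smoothing, implemented
    as local least-squares polynomial fits (with polynomial extrapolation
    from the first/last full window at the edges)."""
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    n = len(d)
    m = window // 2
    out = [0.0] * n
    for i in range(m, n - m):
        t = np.arange(-m, m + 1, dtype=float)
        coef = np.polyfit(t, d[i - m : i + m + 1], order)
        out[i] = float(np.polyval(coef, 0.0))
    t = np.arange(window, dtype=float)
    head = np.polyfit(t, d[:window], order)
    for i in range(m):
        out[i] = float(np.polyval(head, float(i)))
    tail = np.polyfit(t, d[n - window :], order)
    for i in range(n - m, n):
        out[i] = float(np.polyval(tail, float(i - (n - window))))
    return out


# -- selection --------------------------------------------------------------

def naive_anova_f(groups):
    """One-way ANOVA F = (SSB/(g-1)) / (SSW/(n-g)) via explicit sums."""
    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    g = len(groups)
    grand = sum(all_vals) / n
    ssb = sum(len(grp) * (sum(grp) / len(grp) - grand) ** 2 for grp in groups)
    ssw = sum(
        sum((v - sum(grp) / len(grp)) ** 2 for v in grp) for grp in groups
    )
    return (ssb / (g - 1)) / (ssw / (n - g))


def naive_pearson(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    if va == 0 or vb == 0:
        return 0.0
    return cov / math.sqrt(va * vb)


def naive_mrmr_order(X: dict, y, tie_names=None):
    """Full greedy mRMR (difference form) recomputed from scratch at every
    step.  X maps feature name -> sequence."""
    names = sorted(X)
    relevance = {f: abs(naive_pearson(X[f], y)) for f in names}
    order = []
    while len(order) < len(names):
        best, best_score = None, None
        for f in names:
            if f in order:
                continue
            if not order:
                score = relevance[f]
            else:
                red = sum(abs(naive_pearson(X[f], X[s])) for s in order) / len(order)
                score = relevance[f] - red
            if best is None or score > best_score + 1e-15 or (
                abs(score - best_score) <= 1e-15 and f < best
            ):
                best, best_score = f, score
        order.append(best)
    return order


def naive_rrelieff(X, y, n_neighbors=10, sigma=50.0):
    """O(n^2) loop implementation of RReliefF weights (all instances used,
    Manhattan distance on min-max scaled features, exponential rank
    influence normalized to sum one)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xs = np.empty_like(X)
    for j in range(p):
        lo, hi = X[:, j].min(), X[:, j].max()
        Xs[:, j] = 0.0 if hi == lo else (X[:, j] - lo) / (hi - lo)
    y_span = y.max() - y.min()
    w_rank = [math.exp(-(((r + 1) / sigma) ** 2)) for r in range(n_neighbors)]
    tot = sum(w_rank)
    w_rank = [w / tot for w in w_rank]
    n_dc = 0.0
    n_df = [0.0] * p
    n_dcdf = [0.0] * p
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            dists.append((sum(abs(Xs[i, k] - Xs[j, k]) for k in range(p)), j))
        dists.sort(key=lambda t: (t[0], t[1]))
        for r in range(n_neighbors):
            _, j = dists[r]
            dy = abs(y[i] - y[j]) / y_span
            n_dc += dy * w_rank[r]
            for f in range(p):
                df = abs(Xs[i, f] - Xs[j, f])
                n_df[f] += df * w_rank[r]
                n_dcdf[f] += dy * df * w_rank[r]
    return [
        n_dcdf[f] / n_dc - (n_df[f] - n_dcdf[f]) / (n - n_dc) for f in range(p)
    ]


# -- regression -------------------------------------------------------------

def gp_posterior_mean(kernel, X_train, y_train, X_test, alpha=1e-10):
    """GP posterior mean by direct kernel-matrix solve, with the training
    targets centred/scaled the way a constant-mean GP with normalized
    targets does it."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    ym = y_train.mean()
    ys = y_train.std()
    if ys == 0:
        ys = 1.0
    yn = (y_train - ym) / ys
    K = kernel(X_train) + alpha * np.eye(len(X_train))
    a = np.linalg.solve(K, yn)
    Ks = kernel(np.asarray(X_test, dtype=float), X_train)
    return ym + ys * (Ks @ a)
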