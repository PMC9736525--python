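"""Independent brute-force implementations of every scalar definition used
by the feature extractor, written directly from the definitions without
numpy/scipy statistical helpers. These are the reference the production
code is checked against; they must stay independent of it."""

import math


def _mean(x):
    return sum(x) / len(x)


def _sorted_quantile(x, q):
    """Linear-interpolation quantile of a sample (the 'linear' convention)."""
    s = sorted(x)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    if lo == hi:
        return s[lo]
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def _central_moment(x, k):
    m = _mean(x)
    return sum((v - m) ** k for v in x) / len(x)


def brute_force_stats(x, mode_resolution=4.0):
    """The 16 interval statistics, each from its definition."""
    x = list(map(float, x))
    n = len(x)
    m = _mean(x)
    diffs = [x[i + 1] - x[i] for i in range(n - 1)]
    counts = {}
    for v in x:
        key = round(v / mode_resolution) * mode_resolution
        counts[key] = counts.get(key, 0) + 1
    top = max(counts.values())
    mode = min(k for k, c in counts.items() if c == top)
    m2 = _central_moment(x, 2)
    var = sum((v - m) ** 2 for v in x) / (n - 1)
    return {
        "mean": m,
        "median": _sorted_quantile(x, 0.5),
        "mode": mode,
        "std": math.sqrt(var),
        "var": var,
        "abs_dev": _mean([abs(v - m) for v in x]),
        "p25": _sorted_quantile(x, 0.25),
        "p75": _sorted_quantile(x, 0.75),
        "iqr": _sorted_quantile(x, 0.75) - _sorted_quantile(x, 0.25),
        "kurtosis": _central_moment(x, 4) / m2**2 if m2 > 0 else 0.0,
        "skewness": _central_moment(x, 3) / m2**1.5 if m2 > 0 else 0.0,
        "geometric_mean": math.exp(_mean([math.log(v) for v in x])),
        "harmonic_mean": n / sum(1.0 / v for v in x),
        "median_diff": _sorted_quantile([abs(d) for d in diffs], 0.5),
        "nn50": float(sum(1 for d in diffs if abs(d) > 50.0)),
        "rmssd": math.sqrt(_mean([d**2 for d in diffs])),
    }


def brute_force_explained_variance(X):
    """Explained-variance fractions of principal components via an explicit
    eigendecomposition of the sample covariance matrix."""
    import numpy as np

    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    return eigvals / eigvals.sum()
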