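"""Independent brute-force oracles used to pin feature implementations.

Everything here is written straight from the defining formulas in plain
Python (no shared code with the package), deliberately naive: nested
loops for template counting, the statistics module for moments.
"""

from __future__ import annotations

import math
import statistics


def sample_entropy_oracle(x, m: int = 2, r: float = 0.2) -> float:
    """Naive O(N^2) template-counting sample entropy.

    Counts unordered template pairs (self-matches excluded) within
    Chebyshev tolerance r*SD at lengths m and m+1, both over the first
    N-m templates, and returns -ln(A/B).
    """
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)  # population SD
    tol = r * sd

    def count(length: int) -> int:
        c = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                match = True
                for k in range(length):
                    if abs(x[i + k] - x[j + k]) > tol:
                        match = False
                        break
                if match:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("inf")
    return -math.log(a / b)


def hrv_features_oracle(nn) -> dict:
    """Direct textbook evaluation of the time-domain HRV definitions."""
    nn = list(map(float, nn))
    diffs = [b - a for a, b in zip(nn, nn[1:])]
    abs_diffs = [abs(d) for d in diffs]
    hr = [60000.0 / v for v in nn]
    nni_50 = sum(1 for d in abs_diffs if d > 50.0)
    nni_20 = sum(1 for d in abs_diffs if d > 20.0)
    mean_nni = statistics.fmean(nn)
    sdnn = statistics.stdev(nn)
    rmssd = math.sqrt(statistics.fmean([d * d for d in diffs]))
    return {
        "mean_nni": mean_nni,
        "sdnn": sdnn,
        "sdsd": statistics.stdev(diffs) if len(diffs) >= 2 else 0.0,
        "nni_50": nni_50,
        "pnni_50": 100.0 * nni_50 / len(diffs),
        "nni_20": nni_20,
        "pnni_20": 100.0 * nni_20 / len(diffs),
        "rmssd": rmssd,
        "median_nni": statistics.median(nn),
        "range_nni": max(nn) - min(nn),
        "cvsd": rmssd / mean_nni,
        "cvnni": sdnn / mean_nni,
        "mean_hr": statistics.fmean(hr),
        "max_hr": max(hr),
    }


def higuchi_fd_oracle(x, kmax: int = 10) -> float:
    """Plain-loop Higuchi curve-length estimator with least-squares slope."""
    x = list(map(float, x))
    n = len(x)
    pts = []
    for k in range(1, kmax + 1):
        lengths = []
        for m0 in range(k):
            idx = list(range(m0, n, k))
            if len(idx) < 2:
                continue
            raw = sum(abs(x[idx[i]] - x[idx[i - 1]]) for i in range(1, len(idx)))
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(raw * norm / k)
        pts.append((math.log(1.0 / k), math.log(sum(lengths) / len(lengths))))
    # least squares slope
    mx = statistics.fmean(p[0] for p in pts)
    my = statistics.fmean(p[1] for p in pts)
    num = sum((px - mx) * (py - my) for px, py in pts)
    den = sum((px - mx) ** 2 for px, py in pts)
    return num / den
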