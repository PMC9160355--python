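"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's vectorized code paths: plain Python
loops over string slices, so agreement with the package is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

import math


def brute_profile(seq: str, window: int, step: int):
    """Per-window (%C, %G, diff) by slicing and str.count."""
    out = []
    start = 0
    while start + window <= len(seq):
        win = seq[start : start + window]
        pc = 100.0 * win.count("C") / window
        pg = 100.0 * win.count("G") / window
        out.append((start, pc, pg, pc - pg))
        start += step
    return out


def brute_bubbles(seq: str, window: int, step: int, threshold: float = 0.0,
                  extent: str = "footprint"):
    """Maximal diff>threshold runs as (first, last, start, end, length, area,
    max_diff, max_pctC, avg_diff) tuples."""
    prof = brute_profile(seq, window, step)
    n = len(prof)
    runs = []
    k = 0
    while k < n:
        if prof[k][3] > threshold:
            j = k
            while j + 1 < n and prof[j + 1][3] > threshold:
                j += 1
            runs.append((k, j))
            k = j + 1
        else:
            k += 1
    out = []
    for (i, j) in runs:
        if extent == "footprint":
            start = prof[i][0]
            end = prof[j][0] + window
        else:  # center: step-length segments, clamped at profile edges
            start = 0 if i == 0 else prof[i][0] + (window - step) // 2
            end = prof[j][0] + window if j == n - 1 else prof[j][0] + (window + step) // 2
        diffs = [prof[t][3] for t in range(i, j + 1)]
        pcs = [prof[t][1] for t in range(i, j + 1)]
        out.append(
            (i, j, start, end, end - start, step * sum(diffs),
             max(diffs), max(pcs), sum(diffs) / len(diffs))
        )
    return out


def brute_yc(seq: str, lo: int = 9, hi: int = 13):
    """Exhaustive (yc1, yc2, yc3) enumeration with end->start gap spacing.

    Chains of order 2/3 are counted by distinct start offset: a dimer
    begins at most one counted chain of each order.
    """
    positions = [
        i for i in range(len(seq) - 1) if seq[i] in "CT" and seq[i + 1] == "C"
    ]
    yc1 = len(positions)
    starts2 = set()
    starts3 = set()
    for a in positions:
        for b in positions:
            if b <= a or not (lo <= b - (a + 2) <= hi):
                continue
            starts2.add(a)
            for c in positions:
                if c > b and lo <= c - (b + 2) <= hi:
                    starts3.add(a)
    return yc1, len(starts2), len(starts3)


def brute_descriptors(seq: str, window: int = 78, step: int = 10):
    """All 13 descriptors recomputed from scratch; returns a dict."""
    L_t = len(seq)
    bubbles = brute_bubbles(seq, window, step)
    yc_full = brute_yc(seq)[0]
    if not bubbles:
        return {
            "L1_longest_bubble_len": 0, "cum_len_all_bubbles": 0,
            "density_len": 0.0, "S1_longest_bubble_area": 0.0,
            "cum_area_all_bubbles": 0.0, "density_area": 0.0,
            "max_pctC_longest": 0.0, "max_diff_longest": 0.0,
            "avg_diff_longest": 0.0, "yc1_longest": 0, "yc2_longest": 0,
            "yc3_longest": 0, "yc_density": yc_full / L_t,
        }
    # longest bubble: max length, ties by larger area then 5'-most
    best = sorted(bubbles, key=lambda b: (-b[4], -b[5], b[2]))[0]
    yc1, yc2, yc3 = brute_yc(seq[best[2] : best[3]])
    cum_len = sum(b[4] for b in bubbles)
    cum_area = sum(b[5] for b in bubbles)
    return {
        "L1_longest_bubble_len": best[4],
        "cum_len_all_bubbles": cum_len,
        "density_len": cum_len / L_t,
        "S1_longest_bubble_area": best[5],
        "cum_area_all_bubbles": cum_area,
        "density_area": cum_area / L_t,
        "max_pctC_longest": best[7],
        "max_diff_longest": best[6],
        "avg_diff_longest": best[8],
        "yc1_longest": yc1,
        "yc2_longest": yc2,
        "yc3_longest": yc3,
        "yc_density": yc_full / L_t,
    }


def brute_quantile(values, q: float) -> float:
    """Linear-interpolation percentile computed from first principles."""
    v = sorted(values)
    if len(v) == 1:
        return float(v[0])
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def brute_ols(x, y):
    """Closed-form OLS slope/intercept/r2 from sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    syy = sum((b - my) ** 2 for b in y)
    slope = sxy / sxx
    intercept = my - slope * mx
    r2 = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return slope, intercept, r2
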