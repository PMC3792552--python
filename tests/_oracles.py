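"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and where feasible the library
calls) used by the implementation under test.
"""

import numpy as np


def midranks(x):
    """Midranks implemented from first principles (sort + tie runs)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    sx = x[order]
    ranks = np.empty(x.size)
    i, pos = 0, 1
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        avg = (2 * pos + (j - i)) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        pos += j - i + 1
        i = j + 1
    return ranks


def kcc_bruteforce(series_set):
    """Kendall's W via the deviation form 12*sum((R_i - Rbar)^2) / (K^2 (n^3 - n))."""
    series = np.atleast_2d(np.asarray(series_set, dtype=float))
    ranks = np.array([midranks(s) for s in series])
    k, n = ranks.shape
    r_i = ranks.sum(axis=0)
    rbar = r_i.mean()
    return 12.0 * ((r_i - rbar) ** 2).sum() / (k**2 * (n**3 - n))


def pooled_t_bruteforce(a, b):
    """Closed-form pooled-variance two-sample t, computed long-hand.

    Returned with the sign of mean(b) - mean(a), i.e. positive when the
    second sample is larger.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    sp2 = (
        ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    ) / (n1 + n2 - 2)
    return (b.mean() - a.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def degree_bruteforce(data, mask, offsets, r_threshold):
    """All-pairs Pearson degree count with explicit loops."""
    dims = mask.shape
    out = np.full(dims, np.nan)
    for idx in np.ndindex(dims):
        if not mask[idx]:
            continue
        x = data[idx]
        if x.std() == 0:
            continue
        count = 0
        for off in offsets:
            if not any(off):
                continue
            nb = tuple(i + o for i, o in zip(idx, off))
            if any(c < 0 or c >= d for c, d in zip(nb, dims)):
                continue
            if not mask[nb]:
                continue
            y = data[nb]
            if y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r > r_threshold:
                count += 1
        out[idx] = count
    return out
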