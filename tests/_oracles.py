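"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-implementations (direct formula
evaluation, from-scratch window scans) kept separate from the package
so that each check compares two independent routes to the same number.
"""

import numpy as np
from scipy import stats as sps


def welch_oracle(a, b):
    """Welch statistic, Welch–Satterthwaite df and two-tailed p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


def midrank(x):
    """Midrank assignment without scipy.rankdata."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of midranks."""
    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def brute_force_idt(seg_x, seg_y, thr_mm, w):
    """Greedy dispersion-window fixation oracle.

    Recomputes the dispersion (x extent + y extent) of every candidate
    window from scratch; returns half-open (start, stop) index pairs.
    """
    out = []
    n = len(seg_x)

    def disp(a, b):
        return (seg_x[a:b].max() - seg_x[a:b].min()
                + seg_y[a:b].max() - seg_y[a:b].min())

    i = 0
    while i + w <= n:
        if disp(i, i + w) > thr_mm:
            i += 1
            continue
        j = i + w
        while j < n and disp(i, j + 1) <= thr_mm:
            j += 1
        out.append((i, j))
        i = j
    return out


def brute_force_collisions(s, y, obstacles, lengths,
                           car_length=4.5, margin=1.6):
    """Per-sample scan collision oracle."""
    flags = []
    for pos, olen in zip(obstacles, lengths):
        hit = False
        for si, yi in zip(s, y):
            if abs(si - pos) <= (car_length + olen) / 2 and abs(yi) < margin:
                hit = True
        flags.append(hit)
    return flags
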