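"""Independent brute-force oracles used only by the test suite.

Deliberately naive: exhaustive pair/run enumeration with explicit loops,
direct moment sums, and pair-counting survival metrics.  They share no code
with the implementation they check.
"""

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(levels, mask, distance=1, directions=(0, 45, 90, 135)):
    """Symmetric co-occurrence probabilities by exhaustive pair enumeration."""
    g = int(levels[mask].max())
    counts = np.zeros((g, g))
    h, w = levels.shape
    for d in directions:
        dr, dc = OFFSETS[d]
        dr, dc = dr * distance, dc * distance
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    i, j = levels[r, c] - 1, levels[r2, c2] - 1
                    counts[i, j] += 1
                    counts[j, i] += 1
    total = counts.sum()
    return counts / total if total else counts


def glcm_stats_bruteforce(P):
    """(cluster_shade, maximum_probability) by direct double sums."""
    g = P.shape[0]
    mu_i = sum((i + 1) * P[i, j] for i in range(g) for j in range(g))
    mu_j = sum((j + 1) * P[i, j] for i in range(g) for j in range(g))
    shade = sum(
        ((i + 1) + (j + 1) - mu_i - mu_j) ** 3 * P[i, j]
        for i in range(g)
        for j in range(g)
    )
    return shade, P.max()


def glrlm_bruteforce(levels, mask, direction):
    """Run counts by scanning each line pixel-by-pixel."""
    h, w = levels.shape
    g = int(levels[mask].max()) if mask.any() else 1
    R = np.zeros((g, max(h, w)), dtype=int)
    dr, dc = OFFSETS[direction]

    starts = []
    for r in range(h):
        for c in range(w):
            rp, cp = r - dr, c - dc
            if not (0 <= rp < h and 0 <= cp < w):
                starts.append((r, c))
    for r0, c0 in starts:
        r, c = r0, c0
        run_level, run_len = None, 0
        while 0 <= r < h and 0 <= c < w:
            if not mask[r, c]:
                if run_len:
                    R[run_level - 1, run_len - 1] += 1
                run_level, run_len = None, 0
            elif levels[r, c] == run_level:
                run_len += 1
            else:
                if run_len:
                    R[run_level - 1, run_len - 1] += 1
                run_level, run_len = levels[r, c], 1
            r, c = r + dr, c + dc
        if run_len:
            R[run_level - 1, run_len - 1] += 1
    return R


def run_length_stats_bruteforce(R):
    """(LRE, LRHGE) by direct sums over the run matrix."""
    n_r = R.sum()
    lre = sum(
        R[i, j] * (j + 1) ** 2 for i in range(R.shape[0]) for j in range(R.shape[1])
    ) / n_r
    lrhge = sum(
        R[i, j] * (j + 1) ** 2 * (i + 1) ** 2
        for i in range(R.shape[0])
        for j in range(R.shape[1])
    ) / n_r
    return lre, lrhge


def first_order_bruteforce(level_list):
    """Variance, Pearson kurtosis and energy straight from the level sample."""
    x = np.asarray(level_list, dtype=float)
    mu = x.mean()
    m2 = ((x - mu) ** 2).mean()
    m4 = ((x - mu) ** 4).mean()
    vals, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    return m2, m4 / m2**2, float((p**2).sum())


def concordance_bruteforce(scores, times, events):
    """Harrell's C by explicit pair loops (shorter time must be an event)."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def auc_bruteforce(scores, times, t):
    """Pair-counting AUC at horizon t, valid when there is no censoring."""
    num = den = 0.0
    for i in range(len(scores)):
        if times[i] > t:
            continue
        for j in range(len(scores)):
            if times[j] <= t:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


def spearman_midrank_bruteforce(x, y):
    """Spearman rho via explicit midranking then the Pearson formula."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v)
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))
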