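"""Independent brute-force / textbook-formula oracles used to cross-check the
package implementations.  These deliberately share no code with the package:
nested loops and direct formula transcriptions only."""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sstats


def pairwise_fleiss_kappa(counts) -> float:
    """Fleiss' kappa via explicit agreeing-pair enumeration per item."""
    counts = np.asarray(counts, dtype=int)
    per_item = []
    for row in counts:
        labels = []
        for j, c in enumerate(row):
            labels.extend([j] * int(c))
        pairs = 0
        agree = 0
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                pairs += 1
                if labels[a] == labels[b]:
                    agree += 1
        per_item.append(agree / pairs)
    p_bar = float(np.mean(per_item))
    p_j = counts.sum(axis=0) / counts.sum()
    p_e = float((p_j ** 2).sum())
    return (p_bar - p_e) / (1.0 - p_e)


def windowed_index(n_pos, n_neg, n_total, window) -> tuple[list, list]:
    """Sentiment index and activity by explicit truncated window sums."""
    half = window // 2
    n = len(n_pos)
    s_out, a_out = [], []
    for d in range(n):
        lo, hi = max(0, d - half), min(n, d + half + 1)
        P = sum(n_pos[lo:hi])
        N = sum(n_neg[lo:hi])
        s_out.append((P - N) / (P + N) if P + N > 0 else math.nan)
        a_out.append(sum(n_total[lo:hi]) / (hi - lo))
    return s_out, a_out


def textbook_welch(a, b) -> tuple[float, float, float]:
    """Welch's t, Welch-Satterthwaite df and two-sided p from the formulas."""
    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return t, df, p


def brute_force_peaks(x, rel_min=0.2) -> list[tuple[int, float, float]]:
    """Local maxima with topographic prominence by scanning all saddles.

    Returns (leftmost index, height, prominence) of peaks whose prominence
    normalized by the series range reaches ``rel_min``.  Plateau maxima are
    treated as one peak at their leftmost index.
    """
    x = [float(v) for v in x]
    n = len(x)
    rng = max(x) - min(x)
    # candidate peaks: strictly greater than neighbours, plateaus allowed
    candidates = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                candidates.append(i)  # leftmost plateau index
            i = j + 1
        else:
            i += 1
    out = []
    for p in candidates:
        h = x[p]
        # walk left until a strictly higher value or the series start
        left_min = h
        k = p - 1
        while k >= 0 and x[k] <= h:
            left_min = min(left_min, x[k])
            k -= 1
        left_base = left_min if k >= 0 else min(x[: p + 1])
        # walk right likewise
        right_min = h
        k = p + 1
        while k < n and x[k] <= h:
            right_min = min(right_min, x[k])
            k += 1
        right_base = right_min if k < n else min(x[p:])
        prom = h - max(left_base, right_base)
        if rng > 0 and prom / rng >= rel_min:
            out.append((p, h, prom))
    return out
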