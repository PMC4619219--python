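"""Independent brute-force oracles used to cross-check the package.

Everything here is written with plain double loops and Python arithmetic
on purpose: these implementations must stay independent of the vectorized
code paths they verify.
"""

from __future__ import annotations

import math


def oracle_labels(coords, freq, contact_d2):
    """Per-pair satisfaction labels via an explicit double loop."""
    n = len(coords)
    labels = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d2 = sum((coords[i][k] - coords[j][k]) ** 2 for k in range(3))
            if freq[i][j] > 0:
                labels[i][j] = 1 if d2 <= contact_d2 else 2
            else:
                labels[i][j] = 3 if d2 > contact_d2 else 4
    return labels


def oracle_cs(labels):
    sat = total = 0
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i][j] == 1:
                sat += 1
                total += 1
            elif labels[i][j] == 2:
                total += 1
    return sat * 100.0 / total if total else None


def oracle_ns(labels):
    sat = total = 0
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i][j] == 3:
                sat += 1
                total += 1
            elif labels[i][j] == 4:
                total += 1
    return sat * 100.0 / total if total else None


def oracle_if(labels, freq):
    sat_if = 0.0
    total_if = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if freq[i][j] > 0:
                total_if += freq[i][j]
                if labels[i][j] == 1:
                    sat_if += freq[i][j]
    return sat_if * 100.0 / total_if if total_if else None


def oracle_ms(coords, min_d2, max_d2):
    n = len(coords)
    if n < 2:
        return None
    sat = 0
    for k in range(n - 1):
        d2 = sum((coords[k][x] - coords[k + 1][x]) ** 2 for x in range(3))
        if min_d2 <= d2 <= max_d2:
            sat += 1
    return sat * 100.0 / n


def oracle_total(scores, weights):
    """Weighted average over the non-None scores."""
    num = den = 0.0
    for s, w in zip(scores, weights):
        if s is not None:
            num += w * s
            den += w
    if den == 0:
        raise ValueError("no applicable scores")
    return num / den


def oracle_unsat_means(coords, labels):
    dc, dn = [], []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            d = math.sqrt(
                sum((coords[i][k] - coords[j][k]) ** 2 for k in range(3))
            )
            if labels[i][j] == 2:
                dc.append(d)
            elif labels[i][j] == 4:
                dn.append(d)
    mean = lambda xs: sum(xs) / len(xs) if xs else None  # noqa: E731
    return mean(dc), mean(dn)


def oracle_range_cs(labels, cutoff):
    """Short/long-range contact satisfaction split at |i-j| <= cutoff."""
    short_sat = short_tot = long_sat = long_tot = 0
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i][j] not in (1, 2):
                continue
            if j - i <= cutoff:
                short_tot += 1
                short_sat += labels[i][j] == 1
            else:
                long_tot += 1
                long_sat += labels[i][j] == 1
    short = short_sat * 100.0 / short_tot if short_tot else None
    long_ = long_sat * 100.0 / long_tot if long_tot else None
    return short, long_


def random_instance(rng, n_max=25, n_min=4):
    """A random (coords, freq) pair with integer frequencies and zeros."""
    import numpy as np

    n = int(rng.integers(n_min, n_max + 1))
    scale = float(rng.uniform(0.5, 4.0))
    coords = rng.normal(scale=scale, size=(n, 3))
    upper = rng.integers(0, 6, size=(n, n)) * (rng.random((n, n)) < 0.5)
    freq = np.triu(upper, k=1)
    freq = freq + freq.T
    freq[np.diag_indices(n)] = rng.integers(0, 3, size=n)
    return coords, freq.astype(int)
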