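"""Shared fixtures and independent brute-force oracles.

The oracle functions are deliberately naive (explicit loops over every
candidate) so they stay independent of the vectorized implementations
they validate.
"""

from __future__ import annotations

import numpy as np
import pytest


def brute_otsu(counts, centers):
    """Exhaustive argmax of between-class variance over histogram cuts."""
    best, best_k = -1.0, 0
    total = sum(counts)
    for k in range(len(counts) - 1):
        w0 = sum(counts[: k + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(c * x for c, x in zip(counts[: k + 1], centers[: k + 1])) / w0
        mu1 = sum(c * x for c, x in zip(counts[k + 1:], centers[k + 1:])) / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best:
            best, best_k = v, k
    return centers[best_k]


def brute_li(counts, centers):
    """Exhaustive argmin of Li's cross-entropy over histogram cuts."""
    offset = 0.0
    if centers[0] <= 0:
        offset = -centers[0] + (centers[1] - centers[0])
    g = [c + offset for c in centers]
    best, best_k = np.inf, 0
    for k in range(len(counts) - 1):
        n0 = sum(counts[: k + 1])
        n1 = sum(counts[k + 1:])
        if n0 == 0 or n1 == 0:
            continue
        s0 = sum(c * x for c, x in zip(counts[: k + 1], g[: k + 1]))
        s1 = sum(c * x for c, x in zip(counts[k + 1:], g[k + 1:]))
        mu0, mu1 = s0 / n0, s1 / n1
        crit = -(s0 * np.log(mu0) + s1 * np.log(mu1))
        if crit < best:
            best, best_k = crit, k
    return centers[best_k]


def brute_bh(p):
    """Hand Benjamini-Hochberg step-up."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def brute_median_mad(values):
    """Sort-based median and raw MAD."""
    v = sorted(values)
    n = len(v)
    med = v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2.0
    dev = sorted(abs(x - med) for x in v)
    mad = dev[n // 2] if n % 2 else (dev[n // 2 - 1] + dev[n // 2]) / 2.0
    return med, mad


def brute_es(stats_in_rank_order, hit_flags, weight=1.0):
    """Explicit running-sum enumeration of the enrichment score."""
    total_hit = sum(abs(s) ** weight for s, h in zip(stats_in_rank_order, hit_flags) if h)
    n_miss = sum(1 for h in hit_flags if not h)
    running, best = 0.0, 0.0
    for s, h in zip(stats_in_rank_order, hit_flags):
        if h:
            running += abs(s) ** weight / total_hit
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
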