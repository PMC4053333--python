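"""Independent brute-force oracles: naive triple-loop filter implementations
and an exhaustive threshold sweep.  Deliberately slow and simple so they
share no code path with the production implementations they check."""

from __future__ import annotations

import numpy as np


def naive_filter1(frames) -> list:
    """d(t) vs the average frame, by explicit Python loops."""
    T = len(frames)
    H = len(frames[0])
    W = len(frames[0][0])
    mean = [[sum(frames[t][y][x] for t in range(T)) / T for x in range(W)]
            for y in range(H)]
    out = []
    for t in range(T):
        s = 0.0
        for y in range(H):
            for x in range(W):
                diff = frames[t][y][x] - mean[y][x]
                s += diff * diff
        out.append(s)
    return out


def naive_filter2(frames) -> list:
    """d(t) between consecutive frames, by explicit Python loops."""
    T = len(frames)
    H = len(frames[0])
    W = len(frames[0][0])
    out = []
    for t in range(T - 1):
        s = 0.0
        for y in range(H):
            for x in range(W):
                diff = frames[t + 1][y][x] - frames[t][y][x]
                s += diff * diff
        out.append(s)
    return out


def naive_rates_at_threshold(d_values, labels, threshold):
    """(tp_rate, fp_rate) with positive = non-target, discard iff D < thr."""
    tp = sum(1 for d, l in zip(d_values, labels) if l == "non-target" and d < threshold)
    fp = sum(1 for d, l in zip(d_values, labels) if l == "target" and d < threshold)
    n_nt = sum(1 for l in labels if l == "non-target")
    n_t = len(labels) - n_nt
    return tp / n_nt, fp / n_t


def naive_block_mean_1d(values, factor):
    """Average-pool a 1-D list with a partial tail block."""
    out = []
    for start in range(0, len(values), factor):
        block = values[start : start + factor]
        out.append(sum(block) / len(block))
    return out
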