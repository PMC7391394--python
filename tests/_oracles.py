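"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities the package computes, using the
most literal formulation possible (per-window loops, explicit sums), so
they stay independent of the implementation paths they check.
"""

from __future__ import annotations

import numpy as np


def naive_accumulate_and_trend(target_deltas, w_short: int, w_long: int):
    """O(n·w) literal recomputation of summed delta and short-minus-long trend."""
    target_deltas = list(target_deltas)
    n = len(target_deltas)
    summed = []
    acc = 0.0
    for d in target_deltas:
        acc += d
        summed.append(acc)
    trend = []
    for k in range(n):
        short = summed[max(0, k - w_short + 1) : k + 1]
        long = summed[max(0, k - w_long + 1) : k + 1]
        trend.append(np.mean(short) - np.mean(long))
    return np.array(summed), np.array(trend)


def naive_rmssd(intervals):
    diffs = [b - a for a, b in zip(intervals, intervals[1:])]
    return float(np.sqrt(sum(d * d for d in diffs) / len(diffs)))
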