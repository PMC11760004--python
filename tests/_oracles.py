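"""Independent brute-force oracles used to check the implementation."""

from __future__ import annotations

import numpy as np


def otsu_brute_force(counts: np.ndarray) -> int:
    """Exhaustive between-class-variance maximization over t in [0, 254].

    Plain Python loop over every candidate threshold; classes are
    {level <= t} and {level > t}, ties broken toward the smallest t.
    """
    counts = np.asarray(counts, dtype=float)
    levels = np.arange(counts.size, dtype=float)
    best_t, best_sigma = 0, -1.0
    for t in range(255):
        w0 = counts[: t + 1].sum()
        w1 = counts[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            sigma = 0.0
        else:
            mu0 = (counts[: t + 1] * levels[: t + 1]).sum() / w0
            mu1 = (counts[t + 1 :] * levels[t + 1 :]).sum() / w1
            sigma = w0 * w1 * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_t, best_sigma = t, sigma
    return best_t


def cumulative_half_brute_force(values: list[int]) -> tuple[int, int, int]:
    """(value at 50% cumulation, 1-based rank, count below 50%).

    Sorts ascending, walks the running sum, and returns the first element
    whose cumulative fraction reaches one half of the total.
    """
    ordered = sorted(values)
    total = sum(ordered)
    running = 0
    for rank, v in enumerate(ordered, start=1):
        running += v
        if running / total >= 0.5:
            return v, rank, rank - 1
    raise AssertionError("unreachable: cumulative sum reaches total")
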