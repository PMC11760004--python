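"""Group comparisons, bootstrap uncertainty, and the step-size sweep.

Fineness groups (fine / medium / coarse, optionally within a marbling
grade) are compared with a two-sided Welch t test (fine vs. coarse) and a
one-way ANOVA (all three). No multiple-testing correction is applied.
The step-size sweep recomputes F7 at each tiles-per-axis value and picks
the step where the fine-vs-coarse Welch p value is smallest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientSample, ZeroWithinVariance
from .indices import build_tile_grid, compute_f7
from .segmentation import MarblingMask

FINENESS_LABELS = ("fine", "medium", "coarse")
#: Tiles-per-axis values scanned by the sweep: 5, 10, ..., 95.
DEFAULT_SWEEP_STEPS = tuple(range(5, 100, 5))


@dataclass(frozen=True)
class ComparisonResult:
    test: str  # "welch_t" or "anova"
    statistic: float
    p_value: float
    df: float | tuple[float, float]
    group_means: dict
    degenerate: bool = False


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lo: float
    hi: float
    b: int
    seed: int


@dataclass(frozen=True)
class SweepResult:
    steps: tuple[int, ...]
    p_values: tuple[float, ...]
    optimal_step: int
    f7_by_step: dict  # step -> per-image F7 array


def welch_t(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Two-sided Welch unequal-variance t test.

    Degenerate inputs are handled explicitly: two zero-variance samples
    with equal means report t = 0, p = 1; with distinct means the test is
    flagged degenerate with p = 0 (the p -> 0 limit).

    Raises
    ------
    InsufficientSample
        If either sample has fewer than two values.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise InsufficientSample("each sample needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    means = {"a": float(a.mean()), "b": float(b.mean())}
    if va == 0 and vb == 0:
        if means["a"] == means["b"]:
            return ComparisonResult("welch_t", 0.0, 1.0, float("nan"), means,
                                    degenerate=True)
        sign = 1.0 if means["a"] > means["b"] else -1.0
        return ComparisonResult("welch_t", sign * float("inf"), 0.0,
                                float("nan"), means, degenerate=True)
    sa, sb = va / a.size, vb / b.size
    t = (means["a"] - means["b"]) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult("welch_t", float(t), float(p), float(df), means)


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> ComparisonResult:
    """One-way fixed-effects ANOVA, F = MSB/MSW with df (k-1, N-k).

    Raises
    ------
    InsufficientSample
        Fewer than two groups, or any group with fewer than two values.
    ZeroWithinVariance
        All within-group sums of squares are zero.
    """
    if len(groups) < 2:
        raise InsufficientSample("ANOVA needs >= 2 groups")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    if any(v.size < 2 for v in arrays.values()):
        raise InsufficientSample("each group needs >= 2 values")
    all_values = np.concatenate(list(arrays.values()))
    grand = all_values.mean()
    k, n_total = len(arrays), all_values.size
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    if ssw == 0:
        raise ZeroWithinVariance("within-group variance is zero")
    df_b, df_w = k - 1, n_total - k
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    means = {key: float(v.mean()) for key, v in arrays.items()}
    return ComparisonResult("anova", float(f), p, (float(df_b), float(df_w)), means)


def bootstrap_ci(
    values: Sequence[float], b: int = 1000, seed: int = 0
) -> BootstrapCI:
    """Nonparametric percentile 95% CI of the mean from b resamples.

    Deterministic for a fixed seed; the point estimate is the plain sample
    mean and is never altered by the resampling.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise InsufficientSample("bootstrap needs >= 2 values")
    if b < 1:
        raise ValueError("b must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(b, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return BootstrapCI(float(values.mean()), float(lo), float(hi), b, seed)


def f7_multi_step(
    mask: MarblingMask | np.ndarray,
    roi: np.ndarray,
    steps: Sequence[int],
    min_coverage: float = 0.5,
) -> dict[int, float]:
    """F7 of one image at several step sizes (one grid build per step)."""
    return {
        s: compute_f7(build_tile_grid(mask, roi, step=s, min_coverage=min_coverage))
        for s in steps
    }


def step_size_sweep(
    masks: Sequence[MarblingMask | np.ndarray],
    rois: Sequence[np.ndarray],
    labels: Sequence[str],
    steps: Sequence[int] = DEFAULT_SWEEP_STEPS,
    min_coverage: float = 0.5,
) -> SweepResult:
    """Fine-vs-coarse Welch p value of F7 at every step size.

    The optimal step minimizes the p value; ties go to the smallest step
    (cheaper grids). Requires at least two images labeled ``fine`` and two
    labeled ``coarse``; other labels contribute F7 values but not to the
    contrast.
    """
    steps = tuple(int(s) for s in steps)
    if len(steps) != len(set(steps)) or list(steps) != sorted(steps):
        raise ValueError("steps must be strictly increasing")
    labels = list(labels)
    if len(masks) != len(rois) or len(masks) != len(labels):
        raise ValueError("masks, rois and labels must align")
    fine_idx = [i for i, l in enumerate(labels) if l == "fine"]
    coarse_idx = [i for i, l in enumerate(labels) if l == "coarse"]
    if len(fine_idx) < 2 or len(coarse_idx) < 2:
        raise InsufficientSample("need >= 2 fine and >= 2 coarse images")
    f7_by_step: dict[int, np.ndarray] = {s: np.empty(len(masks)) for s in steps}
    for i, (m, r) in enumerate(zip(masks, rois)):
        per_step = f7_multi_step(m, r, steps, min_coverage=min_coverage)
        for s, v in per_step.items():
            f7_by_step[s][i] = v
    p_values = []
    for s in steps:
        res = welch_t(f7_by_step[s][fine_idx], f7_by_step[s][coarse_idx])
        p_values.append(res.p_value)
    optimal = steps[int(np.argmin(p_values))]  # argmin -> first = smallest step
    return SweepResult(steps, tuple(float(p) for p in p_values), optimal, f7_by_step)
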