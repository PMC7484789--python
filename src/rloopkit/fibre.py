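"""DNA-fibre fork speed and sister-fork symmetry analysis.

Fork speed converts a labelled tract length (µm) into kb/min using the
standard 2.59 kb/µm stretching factor: speed = length * 2.59 / pulse.
Sister-fork pairs from one origin are classified as symmetric when the two
arms differ by less than 25 % of the longer arm, and fork stalling is
summarized by the longer/shorter arm ratio and by the fraction of pairs
exceeding a fold-difference cutoff (2-fold by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KB_PER_UM",
    "TukeySummary",
    "GroupComparison",
    "fork_speed",
    "classify_symmetry",
    "asymmetry_ratio",
    "fraction_fold_asymmetric",
    "summarize_speeds",
    "summarize_pairs",
    "compare_groups",
]

logger = logging.getLogger(__name__)

KB_PER_UM = 2.59  # kb of DNA per µm of stretched fibre


@dataclass(frozen=True)
class TukeySummary:
    """Five-number summary with 1.5*IQR whiskers clipped to observed data."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    pvalue: float
    flags: tuple[str, ...] = ()


def fork_speed(length_um: float, pulse_min: float, kb_per_um: float = KB_PER_UM) -> float:
    """Fork speed in kb/min for a tract of ``length_um`` laid in ``pulse_min``."""
    if pulse_min <= 0:
        raise ValueError("pulse_min must be > 0")
    if length_um < 0:
        raise ValueError("length_um must be >= 0")
    if kb_per_um <= 0:
        raise ValueError("kb_per_um must be > 0")
    return length_um * kb_per_um / pulse_min


def classify_symmetry(left_um: float, right_um: float, threshold: float = 0.25) -> str:
    """Classify a sister-fork pair as ``"symmetric"`` or ``"asymmetric"``.

    Symmetric iff (longer - shorter) / longer < threshold, i.e. the arms
    differ by less than a 25 % length difference at the default.  The
    denominator is the longer arm, making the criterion invariant to the
    order of the arms.  Raises if both arms are zero (undefined).
    """
    if left_um < 0 or right_um < 0:
        raise ValueError("arm lengths must be >= 0")
    longer, shorter = max(left_um, right_um), min(left_um, right_um)
    if longer == 0:
        raise ValueError("symmetry undefined for a pair with both arms of length 0")
    return "symmetric" if (longer - shorter) / longer < threshold else "asymmetric"


def asymmetry_ratio(left_um: float, right_um: float) -> float:
    """Ratio of the longer sister arm to the shorter one (>= 1).

    Returns ``inf`` when the shorter arm is zero; callers summarizing over
    populations exclude these with a logged count (see ``summarize_pairs``).
    """
    if left_um < 0 or right_um < 0:
        raise ValueError("arm lengths must be >= 0")
    longer, shorter = max(left_um, right_um), min(left_um, right_um)
    if shorter == 0:
        return math.inf
    return longer / shorter


def fraction_fold_asymmetric(
    pairs: pd.DataFrame | Iterable[tuple[float, float]], fold: float = 2.0
) -> float:
    """Fraction of sister-fork pairs whose arm ratio exceeds ``fold``.

    Pairs with a zero-length shorter arm have infinite ratio and count as
    asymmetric; pairs with both arms zero are excluded.
    """
    arms = _pair_arms(pairs)
    if len(arms) == 0:
        raise ValueError("fraction_fold_asymmetric requires at least one pair")
    ratios = np.array([asymmetry_ratio(l, r) for l, r in arms if max(l, r) > 0])
    if len(ratios) == 0:
        raise ValueError("all pairs have both arms of length 0")
    return float(np.mean(ratios > fold))


def _pair_arms(pairs: pd.DataFrame | Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    if isinstance(pairs, pd.DataFrame):
        return list(zip(pairs["left_um"].to_numpy(), pairs["right_um"].to_numpy()))
    return [(float(l), float(r)) for l, r in pairs]


def summarize_speeds(values: Sequence[float]) -> TukeySummary:
    """Tukey boxplot summary: type-7 quartiles, whiskers within 1.5*IQR.

    Whiskers are the most extreme observed values inside
    [q1 - 1.5*IQR, q3 + 1.5*IQR].
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("summarize_speeds requires at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear (type-7) interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return TukeySummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n=int(arr.size),
    )


def summarize_pairs(
    pairs: pd.DataFrame, threshold: float = 0.25, fold: float = 2.0
) -> dict:
    """Population summary of sister-fork symmetry.

    Pairs with both arms zero are excluded from everything; pairs with one
    zero arm are asymmetric but excluded from the median ratio.  Exclusion
    counts are logged and reported.
    """
    arms = _pair_arms(pairs)
    n_zero_pairs = sum(1 for l, r in arms if max(l, r) == 0)
    valid = [(l, r) for l, r in arms if max(l, r) > 0]
    if n_zero_pairs:
        logger.warning("excluded %d pairs with both arms of length 0", n_zero_pairs)
    if not valid:
        raise ValueError("no valid sister-fork pairs")
    ratios = np.array([asymmetry_ratio(l, r) for l, r in valid])
    n_infinite = int(np.isinf(ratios).sum())
    if n_infinite:
        logger.warning("excluded %d infinite ratios (zero-length arm) from medians", n_infinite)
    finite = ratios[np.isfinite(ratios)]
    classes = [classify_symmetry(l, r, threshold) for l, r in valid]
    n_sym = sum(c == "symmetric" for c in classes)
    return {
        "n_pairs": len(valid),
        "n_excluded_zero_pairs": n_zero_pairs,
        "n_infinite_ratio": n_infinite,
        "n_symmetric": n_sym,
        "frac_symmetric": n_sym / len(valid),
        "median_ratio": float(np.median(finite)) if finite.size else float("nan"),
        "frac_fold_asymmetric": float(np.mean(ratios > fold)),
        "fold": fold,
        "threshold": threshold,
    }


_TESTS = {"t_unpaired_twotailed", "kruskal_wallis", "mann_whitney"}


def compare_groups(*groups: Sequence[float], test: str = "t_unpaired_twotailed") -> GroupComparison:
    """Two-group (t, Mann-Whitney) or multi-group (Kruskal-Wallis) comparison."""
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {sorted(_TESTS)}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    flags: list[str] = []
    if test == "kruskal_wallis":
        if len(arrays) < 2:
            raise ValueError("Kruskal-Wallis needs >= 2 groups")
        stat, p = stats.kruskal(*arrays)
    elif test == "mann_whitney":
        if len(arrays) != 2:
            raise ValueError("Mann-Whitney needs exactly 2 groups")
        stat, p = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
    else:
        if len(arrays) != 2:
            raise ValueError("t-test needs exactly 2 groups")
        if np.ptp(arrays[0]) == 0 and np.ptp(arrays[1]) == 0:
            flags.append("degenerate_variance")
            if np.array_equal(arrays[0], arrays[1]) or arrays[0].mean() == arrays[1].mean():
                return GroupComparison(test, 0.0, 1.0, tuple(flags))
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        stat, p = res.statistic, res.pvalue
    return GroupComparison(test, float(stat), float(p), tuple(flags))
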