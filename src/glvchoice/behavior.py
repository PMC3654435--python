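"""Paired oviposition-choice analysis.

Each plant carries two scented sides (treatment A and B); the response
variable is the per-plant difference in freshly laid egg counts.  Plants
on which no eggs were laid at all are uninformative and are excluded
before the signed-rank test, with the exclusion count reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .npstats import TestResult, wilcoxon_signed_rank

__all__ = [
    "paired_egg_differences",
    "summarize_counts",
    "fold_change",
    "oviposition_test",
]


def _validate_counts(values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if np.any(arr < 0):
        raise ValueError(f"{name} contains negative counts")
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError(f"{name} contains non-integer counts")
    return arr.astype(int)


def paired_egg_differences(pairs: pd.DataFrame,
                           exclude_zero_pairs: bool = True
                           ) -> tuple[np.ndarray, int]:
    """Per-plant egg-count differences with zero-pair exclusion.

    ``pairs`` needs columns ``eggs_a`` and ``eggs_b``.  d = eggs_a -
    eggs_b; plants with eggs_a = eggs_b = 0 are removed when
    ``exclude_zero_pairs`` (the default, matching the field protocol) and
    the removed count is returned alongside.
    """
    a = _validate_counts(pairs["eggs_a"].to_numpy(), "eggs_a")
    b = _validate_counts(pairs["eggs_b"].to_numpy(), "eggs_b")
    if exclude_zero_pairs:
        keep = ~((a == 0) & (b == 0))
        excluded = int((~keep).sum())
        a, b = a[keep], b[keep]
    else:
        excluded = 0
    return (a - b).astype(float), excluded


def summarize_counts(values) -> tuple[float, float]:
    """(mean, SEM) of egg counts; SEM uses the n-1 sample SD."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, float("nan")
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    return mean, sem


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of group means (e.g. treated vs control emission)."""
    if mean_b <= 0:
        raise ValueError("denominator mean must be > 0")
    return mean_a / mean_b


@dataclass
class OvipositionReport:
    """Full summary of one paired-choice comparison."""

    test: TestResult
    n_pairs_used: int
    n_zero_pairs_excluded: int
    mean_sem_a: tuple[float, float]
    mean_sem_b: tuple[float, float]
    mean_difference: float


def oviposition_test(pairs: pd.DataFrame,
                     exclude_zero_pairs: bool = True) -> OvipositionReport:
    """Signed-rank test on the per-plant differences plus side summaries."""
    diffs, excluded = paired_egg_differences(pairs, exclude_zero_pairs)
    if len(diffs) == 0:
        raise ValueError("no informative pairs remain after exclusion")
    a = pairs["eggs_a"].to_numpy(dtype=float)
    b = pairs["eggs_b"].to_numpy(dtype=float)
    if np.all(diffs == 0):
        # symmetric, uninformative: report p = 1 without ranking zeros
        test = TestResult(method="wilcoxon_signed_rank", statistic=0.0,
                          p_two_sided=1.0, mode="exact",
                          sample_sizes=(len(diffs),))
    else:
        test = wilcoxon_signed_rank(diffs)
    return OvipositionReport(
        test=test,
        n_pairs_used=len(diffs),
        n_zero_pairs_excluded=excluded,
        mean_sem_a=summarize_counts(a),
        mean_sem_b=summarize_counts(b),
        mean_difference=float(diffs.mean()),
    )
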