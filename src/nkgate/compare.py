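"""Nonparametric cohort comparisons.

Within-donor strategy contrasts use the two-sided Wilcoxon signed-rank test
(exact null for n <= 25 without tied ranks, continuity-corrected normal
approximation otherwise; zero differences are dropped and reported).
Cross-condition contrasts use the two-sided Mann-Whitney U test (exact for
small untied samples, tie-corrected approximation otherwise).  alpha = 0.05,
no multiple-testing correction — each figure-analog panel is annotated on
its own, as is conventional for this kind of cohort immunophenotyping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

WILCOXON_EXACT_MAX_N = 25


@dataclass
class ComparisonResult:
    label: str
    test: str
    n: int  # usable pairs (paired) or total sample size (unpaired)
    statistic: float
    p_value: float  # NaN when undefined (no non-zero pairs)
    direction: str  # "A", "B" or "tie"
    effect_size: float  # median paired difference (A - B) / difference of medians
    n_zero_dropped: int = 0
    note: str = ""

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < 0.05)


def _direction(effect: float) -> str:
    if effect > 0:
        return "A"
    if effect < 0:
        return "B"
    return "tie"


def paired_compare(values_a, values_b, label: str = "") -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-donor values.

    Pairs with a missing value are dropped; at least 3 usable pairs are
    required.  Zero differences are dropped (count reported); when no
    non-zero difference remains the p-value is NaN with an explanatory note.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise InsufficientDataError(f"only {a.size} usable pairs; need >= 3")

    diff = a - b
    effect = float(np.median(diff))
    nonzero = diff[diff != 0]
    n_zero = int(diff.size - nonzero.size)
    if nonzero.size == 0:
        return ComparisonResult(label, "wilcoxon_signed_rank", int(a.size),
                                float("nan"), float("nan"), "tie", 0.0,
                                n_zero_dropped=n_zero,
                                note="all paired differences are zero; p undefined")

    has_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    if nonzero.size <= WILCOXON_EXACT_MAX_N and not has_ties:
        method, test = "exact", "wilcoxon_signed_rank_exact"
    else:
        method, test = "approx", "wilcoxon_signed_rank_normal"
    res = stats.wilcoxon(nonzero, alternative="two-sided", method=method,
                         correction=(method == "approx"), zero_method="wilcox")
    return ComparisonResult(label, test, int(a.size), float(res.statistic),
                            float(res.pvalue), _direction(effect), effect,
                            n_zero_dropped=n_zero)


def group_compare(values_a, values_b, label: str = "") -> ComparisonResult:
    """Two-sided Mann-Whitney U test between two independent groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each group needs >= 3 finite values")

    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if has_ties or max(a.size, b.size) > 20:
        method, test = "asymptotic", "mann_whitney_u_normal"
    else:
        method, test = "exact", "mann_whitney_u_exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    effect = float(np.median(a) - np.median(b))
    return ComparisonResult(label, test, int(a.size + b.size), float(res.statistic),
                            float(res.pvalue), _direction(effect), effect)
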