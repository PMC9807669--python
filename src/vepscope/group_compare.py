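"""Genotype-level comparisons: amplitude ratios and unpaired t-tests.

The headline group comparisons for this kind of dataset are simple
unpaired two-sample t-tests (maximal P1N1 amplitude, saturation
amplitude ratio, fitted I50 and slope) at alpha = 0.05.  The default is
the Student pooled-variance test; a Welch variant is available.
Repeated-measures ANOVA across intensities is deliberately not
implemented here -- the pipeline exports tidy long-format tables shaped
for any off-the-shelf stats package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

__all__ = ["ComparisonResult", "amplitude_ratio", "unpaired_t_test"]


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group comparison summary (means +- SEM, t, df, p)."""

    metric: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t: float
    df: float
    p: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.df <= 0:
            raise ValueError("df must be > 0")

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def amplitude_ratio(laser_plus_led_uv: float, laser_alone_uv: float) -> float:
    """Ratio of the response during a saturating step to the response alone.

    Zero is allowed (no measurable response during saturation); a zero
    or negative denominator means there was no measurable unconditioned
    response and is an error.
    """
    if laser_alone_uv <= 0:
        raise ValueError("laser_alone_uv must be > 0 (no measurable unconditioned response)")
    if laser_plus_led_uv < 0:
        raise ValueError("laser_plus_led_uv must be >= 0")
    return laser_plus_led_uv / laser_alone_uv


def unpaired_t_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    equal_variance: bool = True,
    metric: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided unpaired two-sample t-test.

    Student's pooled-variance test by default (``equal_variance=True``);
    set False for the Welch variant.  Each group needs n >= 2.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must contain finite values only")
    res = _stats.ttest_ind(a, b, equal_var=equal_variance)
    return ComparisonResult(
        metric=metric,
        mean_a=float(np.mean(a)),
        sem_a=float(_stats.sem(a)),
        n_a=int(a.size),
        mean_b=float(np.mean(b)),
        sem_b=float(_stats.sem(b)),
        n_b=int(b.size),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        alpha=alpha,
    )
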