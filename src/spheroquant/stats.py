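"""Two-group statistics shared by all analysis stages.

The assays report mean ± SEM and compare two groups with the
equal-variance (Student's) two-sample t-test, two-sided.  Welch's form is
available behind a flag.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "two_group_ttest", "summarize"]


@dataclasses.dataclass
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float
    alpha: float
    significant: bool


def summarize(values) -> tuple[float, float]:
    """Mean and SEM (sample sd / sqrt(n)); SEM is NaN for n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")
    return mean, sem


def two_group_ttest(
    sample_a,
    sample_b,
    alpha: float = 0.05,
    label_a: str = "a",
    label_b: str = "b",
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided two-sample t-test with group means and SEMs.

    Degenerate input (zero variance in both groups with equal means) is
    reported as t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    mean_a, sem_a = summarize(a)
    mean_b, sem_b = summarize(b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, mean_a - mean_b), 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return GroupComparison(
        label_a=label_a, label_b=label_b,
        n_a=int(a.size), n_b=int(b.size),
        mean_a=mean_a, mean_b=mean_b, sem_a=sem_a, sem_b=sem_b,
        t_statistic=t, p_value=p, alpha=alpha, significant=bool(p < alpha),
    )
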