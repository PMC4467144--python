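"""In vitro assay quantification: growth index, relative-to-control ratios
and Student's t significance with the study's star convention."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .datamodel import ValidationError


def growth_index(avg_tn: float, avg_t0: float) -> float:
    """Relative growth (Tn - T0) / T0 from averaged absorbances."""
    if avg_t0 <= 0:
        raise ValidationError(f"T0 absorbance must be > 0, got {avg_t0}")
    return (avg_tn - avg_t0) / avg_t0


def relative_to_control(value: float, control_value: float) -> float:
    """Normalize a population's assay summary to its control; a 70% decrease
    in colony counts corresponds to a ratio of 0.30."""
    if control_value == 0:
        raise ValidationError("control value must be nonzero")
    return value / control_value


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float

    @property
    def stars(self) -> str:
        """Figure-legend convention: * p < 0.05, ** p < 0.01."""
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float],
                 equal_var: bool = True) -> TTestResult:
    """Two-sided two-sample t-test on per-experiment ratios.

    Equal-variance (Student's) by default; Welch via ``equal_var=False``.
    Degenerate zero-variance inputs follow the convention p = 1 for equal
    means, p = 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 replicates")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("non-finite assay values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0)
        return TTestResult(t=np.inf if a.mean() > b.mean() else -np.inf, p=0.0)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue))
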