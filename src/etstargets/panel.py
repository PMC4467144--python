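"""Percentile-cut k-of-n low-expression panel classifier for local invasion.

A tumor is predicted locally invasive (pT3) when at least ``k`` of the panel
genes fall strictly below their per-gene expression percentile threshold
across the evaluable (staged PCa) tumors. Performance is summarized by a 2x2
table against pathological stage with Pearson's chi-square (1 df, no
continuity correction) and PPV/NPV/sensitivity/specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import PANEL_GENES, TumorCohort, ValidationError


@dataclass(frozen=True)
class PanelRule:
    genes: tuple[str, ...] = PANEL_GENES
    percentile: float = 25.0
    k: int = 2

    def __post_init__(self):
        if not self.genes:
            raise ValidationError("panel must be non-empty")
        if not (0 < self.percentile < 100):
            raise ValidationError(
                f"percentile must be in (0, 100), got {self.percentile}"
            )
        if not (1 <= self.k <= len(self.genes)):
            raise ValidationError(
                f"k must be in [1, {len(self.genes)}], got {self.k}"
            )


@dataclass(frozen=True)
class PanelEvaluation:
    rule: PanelRule
    tp: int
    fp: int
    fn: int
    tn: int
    chi2: float
    p: float
    ppv: Optional[float]
    npv: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def percentile_threshold(values: Sequence[float], q: float) -> float:
    """Linear-interpolation percentile: position (n-1)*q/100 on the sorted
    values, interpolated between neighbors. Nearest-rank via
    ``percentile_threshold_nearest_rank``."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValidationError("percentile needs >= 2 values")
    if not (0 < q < 100):
        raise ValidationError(f"percentile must be in (0, 100), got {q}")
    return float(np.percentile(values, q, method="linear"))


def percentile_threshold_nearest_rank(values: Sequence[float],
                                      q: float) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValidationError("percentile needs >= 2 values")
    return float(np.percentile(values, q, method="inverted_cdf"))


def flag_matrix(cohort: TumorCohort, rule: PanelRule,
                method: str = "linear",
                thresholds: Optional[dict] = None) -> pd.DataFrame:
    """Tumor x gene grid: True where expression is strictly below the gene's
    percentile threshold over the evaluable tumors.

    Evaluable tumors are the staged PCa samples; thresholds are computed on
    that cohort itself unless a frozen ``thresholds`` mapping is supplied
    (prospective mode). Strict ``<`` keeps "bottom q%" at most q% under ties.
    """
    samples = cohort.staged_pca_samples()
    if not samples:
        raise ValidationError("no staged PCa samples to evaluate")
    missing = [g for g in rule.genes if g not in cohort.expression.data.index]
    if missing:
        raise ValidationError(f"panel gene(s) missing from cohort: {missing}")
    expr = cohort.expression.data.loc[list(rule.genes), samples]
    threshold_fn = (percentile_threshold if method == "linear"
                    else percentile_threshold_nearest_rank)
    flags = {}
    for gene in rule.genes:
        if thresholds is not None:
            cut = thresholds[gene]
        else:
            cut = threshold_fn(expr.loc[gene].to_numpy(), rule.percentile)
        flags[gene] = expr.loc[gene] < cut
    return pd.DataFrame(flags, index=samples)


def classify(flags: pd.DataFrame, k: int) -> frozenset:
    """Tumors with >= k flagged panel genes are predicted invasive."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    counts = flags.sum(axis=1)
    return frozenset(flags.index[counts >= k])


def chi2_2x2(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float]:
    """Pearson chi-square on [[tp, fn], [fp, tn]] without continuity
    correction: N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), 1 df, two-sided."""
    a, b, c, d = tp, fn, fp, tn
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan"), float("nan")
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def fisher_2x2(tp: int, fp: int, fn: int, tn: int) -> float:
    """Fisher's exact two-sided p, for small cells (optional alternative)."""
    return float(stats.fisher_exact([[tp, fn], [fp, tn]])[1])


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def evaluate(predicted: frozenset, truth: pd.Series,
             rule: PanelRule, exact: bool = False) -> PanelEvaluation:
    """Score predictions against stage labels (pT3 = positive).

    ``truth`` maps evaluable tumor ids to "pT2"/"pT3". Undefined metrics
    (zero denominator) are None and exported as NA.
    """
    if len(truth) == 0:
        raise ValidationError("empty truth labels")
    bad = set(truth.unique()) - {"pT2", "pT3"}
    if bad:
        raise ValidationError(f"truth labels must be pT2/pT3, got {sorted(bad)}")
    positive = set(truth.index[truth == "pT3"])
    negative = set(truth.index[truth == "pT2"])
    predicted = set(predicted) & (positive | negative)
    tp = len(predicted & positive)
    fp = len(predicted & negative)
    fn = len(positive - predicted)
    tn = len(negative - predicted)
    chi2, p = chi2_2x2(tp, fp, fn, tn)
    if exact:
        p = fisher_2x2(tp, fp, fn, tn)
    return PanelEvaluation(
        rule=rule, tp=tp, fp=fp, fn=fn, tn=tn, chi2=chi2, p=p,
        ppv=_ratio(tp, tp + fp), npv=_ratio(tn, tn + fn),
        sensitivity=_ratio(tp, tp + fn), specificity=_ratio(tn, tn + fp),
    )


def evaluate_rule(cohort: TumorCohort, rule: PanelRule,
                  **kwargs) -> PanelEvaluation:
    """Flag, classify and score one (percentile, k) rule on a cohort."""
    flags = flag_matrix(cohort, rule)
    predicted = classify(flags, rule.k)
    samples = cohort.staged_pca_samples()
    truth = cohort.annotations.loc[samples, "stage"]
    return evaluate(predicted, truth, rule, **kwargs)


def cutoff_scan(cohort: TumorCohort,
                panel: tuple[str, ...] = PANEL_GENES,
                grid: Sequence[tuple[float, int]] = ((10.0, 1), (25.0, 2),
                                                    (50.0, 4)),
                ) -> list[PanelEvaluation]:
    """Evaluate a grid of (percentile, k) rules, ranked by ascending p.

    Duplicate grid entries are deduplicated with a warning.
    """
    if not grid:
        raise ValidationError("empty cutoff grid")
    seen = []
    for pair in grid:
        pair = (float(pair[0]), int(pair[1]))
        if pair in seen:
            warnings.warn(f"duplicate cutoff rule {pair} dropped")
            continue
        seen.append(pair)
    evaluations = [
        evaluate_rule(cohort, PanelRule(genes=tuple(panel), percentile=q, k=k))
        for q, k in seen
    ]
    return sorted(evaluations,
                  key=lambda ev: (np.nan_to_num(ev.p, nan=np.inf),
                                  ev.rule.percentile, ev.rule.k))
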