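"""Tumor-cohort association testing.

Gene expression is compared between ETS subtypes, Gleason groups and
pathological stage with the Mann-Whitney U test: exact enumeration for small
tie-free groups, tie-corrected normal approximation otherwise. Raw p-values
are reported against alpha = 0.05 without multiple-testing correction (a
Benjamini-Hochberg option exists but is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import TumorCohort, ValidationError

EXACT_MAX_MIN_N = 8  # exact enumeration when min(nA, nB) <= this and no ties


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first group
    p: float
    method: str  # "exact" | "normal-approx"


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``mode``: "exact" (full null enumeration; tie-free inputs only),
    "normal-approx" (tie-corrected), or "auto" (exact when
    min(nA, nB) <= 8 and there are no ties).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("mann_whitney: empty group")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if mode == "auto":
        mode = ("exact" if min(len(a), len(b)) <= EXACT_MAX_MIN_N
                and not has_ties else "normal-approx")
    if mode == "exact":
        if has_ties:
            raise ValidationError("exact Mann-Whitney requires tie-free data")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif mode == "normal-approx":
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return MannWhitneyResult(u=float(res.statistic),
                             p=float(min(res.pvalue, 1.0)),
                             method=mode)


def _stars(p: float) -> str:
    """Figure-legend tiers: * p < 0.05, ** p < 0.01, *** p < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class AssociationRecord:
    gene: str
    contrast: str
    n_a: int
    n_b: int
    direction: str  # "up" | "down" | "none": group A median vs group B
    u: float
    p: float
    significant: bool

    @property
    def stars(self) -> str:
        return _stars(self.p)


CONTRASTS = ("PEA3_vs_ETSneg", "PEA3_vs_ERG", "PCa_vs_NPT")
GROUPINGS = ("gleason_low_vs_high", "pT2_vs_pT3")


def _contrast_samples(cohort: TumorCohort, contrast: str):
    anno = cohort.annotations
    if contrast == "PEA3_vs_ETSneg":
        a = anno.index[anno["subtype"] == "PEA3"]
        b = anno.index[anno["subtype"] == "ETS_negative"]
    elif contrast == "PEA3_vs_ERG":
        a = anno.index[anno["subtype"] == "PEA3"]
        b = anno.index[anno["subtype"] == "ERG"]
    elif contrast == "PCa_vs_NPT":
        a = anno.index[anno["tissue"] == "PCa"]
        b = anno.index[anno["tissue"] == "NPT"]
    else:
        raise ValidationError(
            f"unknown contrast {contrast!r}; choose one of {CONTRASTS}"
        )
    return list(a), list(b)


def _grouping_samples(cohort: TumorCohort, grouping: str):
    """Two sample lists (lower-risk group first); NPT and NA rows excluded."""
    anno = cohort.annotations
    pca = anno["tissue"] == "PCa"
    if grouping == "gleason_low_vs_high":
        column, low, high = "gleason_group", "low", "high"
    elif grouping == "pT2_vs_pT3":
        column, low, high = "stage", "pT2", "pT3"
    else:
        raise ValidationError(
            f"unknown grouping {grouping!r}; choose one of {GROUPINGS}"
        )
    if anno.loc[pca, column].isna().all():
        raise ValidationError(f"grouping {grouping!r}: all values are NA")
    a = list(anno.index[pca & (anno[column] == low)])
    b = list(anno.index[pca & (anno[column] == high)])
    return a, b, high


def _test_gene(cohort: TumorCohort, gene: str, samples_a, samples_b,
               label: str, alpha: float) -> AssociationRecord:
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError(
            f"{label}: each group needs >= 2 samples "
            f"(got {len(samples_a)} and {len(samples_b)})"
        )
    if gene not in cohort.expression.data.index:
        raise KeyError(f"gene {gene!r} not in cohort expression")
    expr = cohort.expression.data.loc[gene]
    a = expr[samples_a].to_numpy()
    b = expr[samples_b].to_numpy()
    res = mann_whitney(a, b)
    diff = float(np.median(a) - np.median(b))
    direction = "up" if diff > 0 else ("down" if diff < 0 else "none")
    return AssociationRecord(
        gene=gene, contrast=label, n_a=len(a), n_b=len(b),
        direction=direction, u=res.u, p=res.p, significant=res.p < alpha,
    )


def subtype_association(cohort: TumorCohort, gene: str, contrast: str,
                        alpha: float = 0.05) -> AssociationRecord:
    """Mann-Whitney comparison of one gene between two annotated groups."""
    a, b = _contrast_samples(cohort, contrast)
    return _test_gene(cohort, gene, a, b, contrast, alpha)


@dataclass(frozen=True)
class ClinicoPathRecord:
    record: AssociationRecord
    flag: str  # e.g. "decreased in pT3" or "" when not significant


def clinico_path_association(cohort: TumorCohort, gene: str, grouping: str,
                             alpha: float = 0.05) -> ClinicoPathRecord:
    """Gleason- or stage-group comparison, flagging the direction of change
    in the higher-risk group when significant."""
    a, b, high_label = _grouping_samples(cohort, grouping)
    rec = _test_gene(cohort, gene, a, b, grouping, alpha)
    flag = ""
    if rec.significant and rec.direction != "none":
        # rec.direction is group A (lower-risk) vs group B (higher-risk)
        change = "decreased" if rec.direction == "up" else "increased"
        flag = f"{change} in {high_label}"
    return ClinicoPathRecord(record=rec, flag=flag)


@dataclass(frozen=True)
class CovariateIndependence:
    grouping: str
    age_p: float | None
    psa_p: float | None
    independent: bool | None
    notes: str


def covariate_independence(cohort: TumorCohort, grouping: str,
                           alpha: float = 0.05) -> CovariateIndependence:
    """Check that age and PSA do not differ between the grouping's classes.

    "Independent" is declared when both covariate p-values are >= alpha;
    this accompanies gene associations and never gates them. A covariate
    missing for all samples is marked not assessable.
    """
    a, b, _ = _grouping_samples(cohort, grouping)
    anno = cohort.annotations
    pvals: dict[str, float | None] = {}
    notes = []
    for col, label in (("age_years", "age"), ("psa_ng_ml", "PSA")):
        va = anno.loc[a, col].dropna().to_numpy(dtype=float)
        vb = anno.loc[b, col].dropna().to_numpy(dtype=float)
        if len(va) == 0 or len(vb) == 0:
            pvals[label] = None
            notes.append(f"{label} not assessable")
            continue
        pvals[label] = mann_whitney(va, vb).p
    assessable = [p for p in pvals.values() if p is not None]
    independent = (all(p >= alpha for p in assessable)
                   if assessable else None)
    return CovariateIndependence(
        grouping=grouping, age_p=pvals.get("age"), psa_p=pvals.get("PSA"),
        independent=independent, notes="; ".join(notes),
    )


def association_table(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Flat export: gene, contrast, n_A, n_B, direction, U, p, significant."""
    return pd.DataFrame([
        {"gene": r.gene, "contrast": r.contrast, "n_A": r.n_a, "n_B": r.n_b,
         "direction": r.direction, "U": r.u, "p": r.p,
         "significant": r.significant}
        for r in records
    ])


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Optional BH-adjusted p-values (off by default in all pipelines)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out
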