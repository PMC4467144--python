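"""Comparative-Ct qPCR quantification and tumor-series median centering.

Relative expression is 2**-(Ct_target - mean(reference Cts)); multiple
reference genes (the study used 18S and GUSB) are combined by the arithmetic
mean of their Cts, equivalent to a geometric mean of linear quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import ValidationError


@dataclass(frozen=True)
class CtRecord:
    """One sample/target measurement with >= 1 reference-gene Cts."""

    sample_id: str
    target: str
    target_ct: float
    reference_cts: tuple[float, ...]

    def __post_init__(self):
        if not self.reference_cts:
            raise ValidationError(
                f"{self.sample_id}/{self.target}: no reference Cts"
            )
        cts = (self.target_ct,) + tuple(self.reference_cts)
        if not all(np.isfinite(cts)):
            raise ValidationError(
                f"{self.sample_id}/{self.target}: non-finite Ct value"
            )


def comparative_ct(record: CtRecord) -> float:
    """Linear relative expression 2**-(dCt) against the averaged references."""
    dct = record.target_ct - float(np.mean(record.reference_cts))
    return float(2.0 ** -dct)


def records_from_table(table: pd.DataFrame) -> list[CtRecord]:
    """Group a long-format Ct table (sample_id, target, ct, ref_gene, ref_ct)
    into one record per (sample, target)."""
    records = []
    for (sample, target), group in table.groupby(["sample_id", "target"],
                                                 sort=True):
        target_cts = group["ct"].unique()
        if len(target_cts) != 1:
            raise ValidationError(
                f"{sample}/{target}: inconsistent target Ct values {target_cts}"
            )
        records.append(CtRecord(
            sample_id=str(sample), target=str(target),
            target_ct=float(target_cts[0]),
            reference_cts=tuple(float(x) for x in group["ref_ct"]),
        ))
    return records


def median_center(series: Mapping[str, float]) -> dict[str, float]:
    """Divide each linear expression value by the series median.

    The median of an even count is the mean of the two central values, so
    centering is idempotent after the first pass.
    """
    if not series:
        raise ValidationError("median_center: empty series")
    values = np.array(list(series.values()), dtype=float)
    if np.any(values <= 0):
        bad = [k for k, v in series.items() if v <= 0][0]
        raise ValidationError(f"median_center: nonpositive value for {bad!r}")
    med = float(np.median(values))
    return {k: v / med for k, v in series.items()}


def relative_expression_vs_control(expr: float, control_expr: float) -> float:
    """Expression of a manipulated population calibrated to its control;
    a 70-80% knockdown corresponds to ratios 0.2-0.3."""
    if control_expr <= 0:
        raise ValidationError(
            f"control expression must be > 0, got {control_expr}"
        )
    return expr / control_expr


def outlier_report(centered: Mapping[str, float],
                   flag_threshold: float = 10.0) -> pd.DataFrame:
    """Rank samples by tumor-series-centered expression, descending, and
    flag values >= flag_threshold as outlier overexpression.

    The threshold is a configurable analysis choice; no canonical cut-off is
    claimed.
    """
    rows = [{"sample_id": k, "centered_expression": float(v),
             "outlier": float(v) >= flag_threshold}
            for k, v in centered.items()]
    out = pd.DataFrame(rows, columns=["sample_id", "centered_expression",
                                      "outlier"])
    return out.sort_values(["centered_expression", "sample_id"],
                           ascending=[False, True]).reset_index(drop=True)
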