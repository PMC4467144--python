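"""Signed fold-change algebra and per-model clone consensus.

Conventions
-----------
* A signed linear fold-change has magnitude >= 1: +r means r-fold higher in
  the numerator condition, -r means r-fold lower; +1 means no change.
* The clone-consensus rule: a gene contributes a per-model value only when
  both manipulated populations change in the same direction versus control,
  in which case the signed fold-changes are averaged (arithmetic by default,
  geometric available). Disagreement leaves the entry undefined (NaN).
* The *association* axis re-expresses change relative to ETS level: a
  silencing model has its sign flipped so knockdown-down genes read as
  positively associated with the ETS, making silencing and overexpression
  models directly comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import CellLineModel, ExpressionMatrix, ValidationError


def signed_fold_change(log2_a, log2_b):
    """Signed linear FC of a vs b from log2 expression values.

    d = log2_a - log2_b; returns +2**d when d >= 0, else -2**(-d).
    Accepts scalars or numpy arrays.
    """
    d = np.asarray(log2_a, dtype=float) - np.asarray(log2_b, dtype=float)
    out = np.where(d >= 0, np.power(2.0, d), -np.power(2.0, -d))
    if out.ndim == 0:
        return float(out)
    return out


def signed_to_log2(fc):
    """Inverse map: signed linear FC back to a log2 difference."""
    fc = np.asarray(fc, dtype=float)
    out = np.where(fc >= 0, np.log2(np.abs(fc)), -np.log2(np.abs(fc)))
    if out.ndim == 0:
        return float(out)
    return out


def _population_log2(matrix: ExpressionMatrix, sample_ids) -> pd.Series:
    # replicate columns of one population are averaged in log2 space
    return matrix.data.loc[:, list(sample_ids)].mean(axis=1)


def clone_fold_changes(model: CellLineModel,
                       matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene signed FC of each manipulated population versus control."""
    model.check_against(matrix)
    control = _population_log2(matrix, model.control.sample_ids)
    cols = {}
    for pop in model.manipulated:
        log2 = _population_log2(matrix, pop.sample_ids)
        cols[pop.label] = signed_fold_change(log2.to_numpy(), control.to_numpy())
    return pd.DataFrame(cols, index=matrix.data.index)


def consensus_from_clones(clone_fcs: pd.DataFrame,
                          average: str = "arithmetic") -> pd.Series:
    """Collapse per-clone signed FCs to a per-model consensus.

    All clones must share the same sign; a no-change clone (+1.0) agrees only
    with other +1.0 clones. Sign-agreeing clones are averaged; otherwise the
    result is NaN (undefined). Single-clone models pass through.
    """
    values = clone_fcs.to_numpy(dtype=float)
    if values.shape[1] == 1:
        return pd.Series(values[:, 0], index=clone_fcs.index)
    signs = np.sign(values)  # +1.0 maps to sign +1; exact no-change is +1.0
    # treat FC == +1.0 (no change) as its own category: agreement requires
    # every clone strictly same-signed, and a +1.0 clone only matches +1.0
    is_nochange = values == 1.0
    same_sign = np.all(signs == signs[:, :1], axis=1)
    nochange_consistent = np.all(is_nochange, axis=1) | ~np.any(is_nochange, axis=1)
    agree = same_sign & nochange_consistent
    if average == "arithmetic":
        consensus = values.mean(axis=1)
    elif average == "geometric":
        consensus = signs[:, 0] * np.exp(np.log(np.abs(values)).mean(axis=1))
    else:
        raise ValueError(f"unknown averaging mode {average!r}")
    return pd.Series(np.where(agree, consensus, np.nan), index=clone_fcs.index)


def consensus_model_fc(gene: str, model: CellLineModel,
                       matrix: ExpressionMatrix,
                       average: str = "arithmetic") -> float:
    """Consensus signed FC (manipulated vs control) for one gene; NaN if the
    manipulated populations disagree in direction."""
    if gene not in matrix.data.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    clones = clone_fold_changes(model, matrix)
    return float(consensus_from_clones(clones.loc[[gene]], average=average).iloc[0])


def association_fc(model_kind: str, fc):
    """Orient a consensus FC on the ETS-association axis.

    Overexpression models keep their sign; silencing models are flipped
    (knockdown-decreased genes become positively associated). Magnitude is
    preserved, and the no-change value +1.0 maps to +1.0.
    """
    if model_kind not in ("silencing", "overexpression"):
        raise ValidationError(f"unknown model kind {model_kind!r}")
    arr = np.asarray(fc, dtype=float)
    if model_kind == "overexpression":
        out = arr
    else:
        out = np.where(arr == 1.0, arr, -arr)
    if out.ndim == 0:
        return float(out)
    return out


def build_association_profile(models, matrix: ExpressionMatrix,
                              average: str = "arithmetic") -> pd.DataFrame:
    """Gene x model table of consensus association FCs (NaN = undefined)."""
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate model names")
    cols = {}
    for model in models:
        clones = clone_fold_changes(model, matrix)
        consensus = consensus_from_clones(clones, average=average)
        cols[model.name] = association_fc(model.kind, consensus.to_numpy())
    return pd.DataFrame(cols, index=matrix.data.index)


def write_association_profile(profile: pd.DataFrame, path) -> None:
    out = profile.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.8g")
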