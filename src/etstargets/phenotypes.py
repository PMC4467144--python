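"""Invasion- and AIG-associated gene sets via include/exclude FC cascades.

Each rule asks for a consistent association-axis direction with |FC| strictly
above an inclusion threshold in a set of include models ("fold-change higher
than ..."), and vetoes genes moving the *same* direction above an exclusion
threshold in the exclude model(s). The overexpression model participates on
the association axis, the only orientation under which the three
invasion-or-AIG include models can agree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    GeneSetReport,
    PNT2_ETV1,
    SHETV1_LNCAP,
    SHETV1_MDA,
    SHETV4_MDA,
    SHETV4_PC3,
    ValidationError,
)

INV_AIG_INCLUDE = (SHETV4_PC3, SHETV1_LNCAP, PNT2_ETV1)
INV_AIG_EXCLUDE = (SHETV1_MDA,)
AIG_INCLUDE = (SHETV4_MDA, SHETV4_PC3)
AIG_EXCLUDE = (SHETV1_MDA,)
INVASION_INCLUDE = (SHETV1_LNCAP, PNT2_ETV1)
INVASION_EXCLUDE = (SHETV4_MDA, SHETV1_MDA)


def _require_models(profile: pd.DataFrame, models) -> None:
    missing = [m for m in models if m not in profile.columns]
    if missing:
        raise ValidationError(f"profile missing models: {missing}")


def _cascade(profile: pd.DataFrame, include_models, exclude_models,
             include_fc: float, exclude_fc: float,
             exclude_requires_all: bool) -> tuple[frozenset, frozenset]:
    """Shared include/exclude predicate.

    Include: same sign with |FC| > include_fc in every include model.
    Exclude: same-direction |FC| > exclude_fc in every exclude model
    (``exclude_requires_all``) or in the single exclude model.
    """
    include_models = tuple(include_models)
    exclude_models = tuple(exclude_models)
    _require_models(profile, include_models + exclude_models)
    inc = profile.loc[:, list(include_models)].to_numpy(dtype=float)
    exc = profile.loc[:, list(exclude_models)].to_numpy(dtype=float)

    def qualifies(sign: int) -> np.ndarray:
        inc_ok = np.all(sign * inc > include_fc, axis=1)
        exc_hits = sign * exc > exclude_fc
        if exclude_requires_all:
            vetoed = np.all(exc_hits, axis=1)
        else:
            vetoed = np.any(exc_hits, axis=1)
        return inc_ok & ~vetoed

    genes = profile.index
    return frozenset(genes[qualifies(+1)]), frozenset(genes[qualifies(-1)])


def invasion_or_aig_genes(profile: pd.DataFrame,
                          include_models=INV_AIG_INCLUDE,
                          exclude_model=SHETV1_MDA,
                          include_fc: float = 1.2,
                          exclude_fc: float = 1.2) -> tuple[frozenset, frozenset]:
    """Genes tied to invasion and/or AIG: consistent in the three models
    with impact in both phenotypes, absent from the model with none."""
    if len(tuple(include_models)) != 3:
        raise ValidationError("invasion_or_aig rule needs three include models")
    return _cascade(profile, include_models, (exclude_model,),
                    include_fc, exclude_fc, exclude_requires_all=False)


def aig_genes(profile: pd.DataFrame,
              include_models=AIG_INCLUDE,
              exclude_model=SHETV1_MDA,
              include_fc: float = 1.5,
              exclude_fc: float = 1.2) -> tuple[frozenset, frozenset]:
    """Genes more associated with anchorage-independent growth: changed in
    both shETV4 models, not same-direction in shETV1-MDA-PCa-2b."""
    if len(tuple(include_models)) != 2:
        raise ValidationError("aig rule needs two include models")
    return _cascade(profile, include_models, (exclude_model,),
                    include_fc, exclude_fc, exclude_requires_all=False)


def invasion_genes(profile: pd.DataFrame,
                   include_models=INVASION_INCLUDE,
                   exclude_models=INVASION_EXCLUDE,
                   include_fc: float = 1.5,
                   exclude_fc: float = 1.2) -> tuple[frozenset, frozenset]:
    """Genes more associated with invasion: changed in shETV1-LNCaP and
    PNT2-ETV1, vetoed only when BOTH MDA-PCa-2b models echo the change."""
    if len(tuple(include_models)) != 2 or len(tuple(exclude_models)) != 2:
        raise ValidationError("invasion rule needs two include and two "
                              "exclude models")
    return _cascade(profile, include_models, exclude_models,
                    include_fc, exclude_fc, exclude_requires_all=True)


def build_phenotype_report(profile: pd.DataFrame,
                           inv_aig_include_fc: float = 1.2,
                           inv_aig_exclude_fc: float = 1.2,
                           aig_include_fc: float = 1.5,
                           aig_exclude_fc: float = 1.2,
                           invasion_include_fc: float = 1.5,
                           invasion_exclude_fc: float = 1.2,
                           exclude_genes=("ETV1", "ETV4")) -> GeneSetReport:
    """Three labeled sets (invasion_or_aig, aig, invasion), computed
    independently; overlaps reported, not enforced."""
    profile = profile.drop(index=[g for g in exclude_genes
                                  if g in profile.index])
    sets = {
        "invasion_or_aig": invasion_or_aig_genes(
            profile, include_fc=inv_aig_include_fc,
            exclude_fc=inv_aig_exclude_fc),
        "aig": aig_genes(profile, include_fc=aig_include_fc,
                         exclude_fc=aig_exclude_fc),
        "invasion": invasion_genes(profile, include_fc=invasion_include_fc,
                                   exclude_fc=invasion_exclude_fc),
    }
    rows = []
    for provenance, (up, down) in sets.items():
        for direction, genes in (("up", up), ("down", down)):
            for g in sorted(genes):
                row = {"gene": g, "provenance": provenance,
                       "direction": direction, "inverse": False}
                for model in profile.columns:
                    row[f"fc_{model}"] = profile.at[g, model]
                rows.append(row)
    columns = (["gene", "provenance", "direction", "inverse"]
               + [f"fc_{m}" for m in profile.columns])
    return GeneSetReport(members=pd.DataFrame(rows, columns=columns))
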