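"""ETS-specific and ETS-shared candidate target-gene sets.

Filters operate on the association profile (gene x model signed FCs on the
ETS-association axis) built over the four silencing models only; the
overexpression model is excluded from target filtering because the parental
line is non-tumorigenic. Comparators are inclusive (>= threshold), matching
"no less than 1.5-fold" / "at least 1.5-fold".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    ALL_MODELS,
    GeneSetReport,
    SHETV1_LNCAP,
    SHETV1_MDA,
    SHETV4_MDA,
    SHETV4_PC3,
    SILENCING_MODELS,
    ValidationError,
)

ETV1_MODELS = (SHETV1_LNCAP, SHETV1_MDA)
ETV4_MODELS = (SHETV4_PC3, SHETV4_MDA)


def _require_models(profile: pd.DataFrame, models) -> None:
    missing = [m for m in models if m not in profile.columns]
    if missing:
        raise ValidationError(f"profile missing models: {missing}")


def specific_targets(profile: pd.DataFrame, ets: str,
                     models_for_ets=None,
                     threshold: float = 1.5) -> tuple[frozenset, frozenset]:
    """Genes up/down-regulated >= threshold-fold in both models of one ETS.

    Returns (up, down) sets on the association axis: ``up`` genes rise with
    the ETS (decreased upon its knockdown). Undefined (NaN) entries
    disqualify a gene.
    """
    if models_for_ets is None:
        models_for_ets = {"ETV1": ETV1_MODELS, "ETV4": ETV4_MODELS}[ets]
    models_for_ets = tuple(models_for_ets)
    if len(models_for_ets) != 2:
        raise ValidationError(
            f"specific-target rule needs exactly two models, got {models_for_ets}"
        )
    _require_models(profile, models_for_ets)
    sub = profile.loc[:, list(models_for_ets)].to_numpy(dtype=float)
    up = np.all(sub >= threshold, axis=1)
    down = np.all(sub <= -threshold, axis=1)
    genes = profile.index
    return frozenset(genes[up]), frozenset(genes[down])


def shared_targets(profile: pd.DataFrame,
                   silencing_models=SILENCING_MODELS,
                   threshold: float = 1.5,
                   min_models: int = 3) -> tuple[frozenset, frozenset]:
    """Genes changed >= threshold-fold, same direction, in >= min_models of
    the four silenced cell lines.

    A gene pathologically qualifying in both directions is reported in
    neither set.
    """
    silencing_models = tuple(silencing_models)
    if len(silencing_models) != 4:
        raise ValidationError(
            f"shared-target rule needs the four silencing models, "
            f"got {len(silencing_models)}"
        )
    if min_models > len(silencing_models):
        raise ValidationError(
            f"min_models = {min_models} exceeds model count {len(silencing_models)}"
        )
    _require_models(profile, silencing_models)
    sub = profile.loc[:, list(silencing_models)].to_numpy(dtype=float)
    n_up = np.sum(sub >= threshold, axis=1)
    n_down = np.sum(sub <= -threshold, axis=1)
    up = n_up >= min_models
    down = n_down >= min_models
    both = up & down
    genes = profile.index
    return frozenset(genes[up & ~both]), frozenset(genes[down & ~both])


def build_target_report(profile: pd.DataFrame,
                        specific_fc: float = 1.5,
                        shared_fc: float = 1.5,
                        shared_min_models: int = 3,
                        exclude_genes=("ETV1", "ETV4")) -> GeneSetReport:
    """Assemble ETV1-specific, ETV4-specific and shared sets.

    Specific and shared sets are computed independently; overlaps are
    reported, not suppressed. Genes appearing in both specific lists with
    opposite directions are flagged ``inverse``. The manipulated ETS genes
    themselves are excluded from candidate sets.
    """
    profile = profile.drop(index=[g for g in exclude_genes
                                  if g in profile.index])
    e1_up, e1_down = specific_targets(profile, "ETV1", threshold=specific_fc)
    e4_up, e4_down = specific_targets(profile, "ETV4", threshold=specific_fc)
    sh_up, sh_down = shared_targets(profile, threshold=shared_fc,
                                    min_models=shared_min_models)
    inverse = (e1_up & e4_down) | (e1_down & e4_up)

    rows = []
    def add(genes, provenance, direction):
        for g in sorted(genes):
            row = {"gene": g, "provenance": provenance, "direction": direction,
                   "inverse": g in inverse}
            for model in profile.columns:
                row[f"fc_{model}"] = profile.at[g, model]
            rows.append(row)

    add(e1_up, "ETV1_specific", "up")
    add(e1_down, "ETV1_specific", "down")
    add(e4_up, "ETV4_specific", "up")
    add(e4_down, "ETV4_specific", "down")
    add(sh_up, "shared", "up")
    add(sh_down, "shared", "down")

    columns = (["gene", "provenance", "direction", "inverse"]
               + [f"fc_{m}" for m in profile.columns])
    members = pd.DataFrame(rows, columns=columns)
    return GeneSetReport(members=members)


def venn_summary(report: GeneSetReport) -> dict:
    """Set cardinalities and pairwise overlaps (inclusion-exclusion audit)."""
    sets = {p: report.gene_set(p)
            for p in ("ETV1_specific", "ETV4_specific", "shared")}
    labels = list(sets)
    summary = {f"n_{p}": len(s) for p, s in sets.items()}
    pair_total = 0
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            n = len(sets[a] & sets[b])
            summary[f"overlap_{a}__{b}"] = n
            pair_total += n
    triple = len(sets[labels[0]] & sets[labels[1]] & sets[labels[2]])
    summary["overlap_triple"] = triple
    summary["n_union"] = len(sets[labels[0]] | sets[labels[1]] | sets[labels[2]])
    # Venn-diagram view: specific genes not also captured by the shared rule
    summary["n_ETV1_specific_only"] = len(sets["ETV1_specific"] - sets["shared"])
    summary["n_ETV4_specific_only"] = len(sets["ETV4_specific"] - sets["shared"])
    summary["n_inverse"] = int(
        report.members.loc[report.members["inverse"], "gene"].nunique())
    # inclusion-exclusion identity holds exactly by construction; recorded
    # so exported summaries are self-auditing
    summary["inclusion_exclusion_check"] = (
        sum(len(s) for s in sets.values()) - pair_total + triple
        == summary["n_union"]
    )
    return summary
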