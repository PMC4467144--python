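"""Synthetic expression data with planted ground truth.

The generator emulates the study design at the already-normalized level:
five cell-line perturbation models (four shRNA silencing models, one
overexpression model, each with one control and two independently
manipulated populations) and a tumor cohort of 9 noncancerous prostate
tissues plus 50 carcinomas subtyped for ETS rearrangements (14 PEA3 — 12
ETV1, 2 ETV4 — 22 ERG, 14 ETS-negative).

Noise is i.i.d. Gaussian in log2 space per gene per sample; planted effects
are additive log2 shifts applied in exactly the models/samples where the
gene's role says its ETS or phenotype association applies (sign inverted in
silencing models, since the association axis is ETS level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ALL_MODELS,
    CellLineModel,
    ExpressionMatrix,
    PANEL_GENES,
    PNT2_ETV1,
    Population,
    SHETV1_LNCAP,
    SHETV1_MDA,
    SHETV4_MDA,
    SHETV4_PC3,
    TumorCohort,
    ValidationError,
)

ROLES = (
    "null",
    "ETV1_target_up", "ETV1_target_down",
    "ETV4_target_up", "ETV4_target_down",
    "shared_up", "shared_down",
    "inverse_etv1_up_etv4_down",
    "invasion_assoc", "aig_assoc", "invasion_or_aig_assoc",
    "stage_low_in_pT3", "stage_high_in_pT3", "gleason_assoc",
)

_ETV1_MODELS = (SHETV1_LNCAP, SHETV1_MDA, PNT2_ETV1)
_ETV4_MODELS = (SHETV4_MDA, SHETV4_PC3)

# per-role association sign (+ = rises with ETS level) per cell-line model
_CELLLINE_ASSOC: dict[str, dict[str, int]] = {
    "ETV1_target_up": {m: +1 for m in _ETV1_MODELS},
    "ETV1_target_down": {m: -1 for m in _ETV1_MODELS},
    "ETV4_target_up": {m: +1 for m in _ETV4_MODELS},
    "ETV4_target_down": {m: -1 for m in _ETV4_MODELS},
    "shared_up": {m: +1 for m in ALL_MODELS},
    "shared_down": {m: -1 for m in ALL_MODELS},
    "inverse_etv1_up_etv4_down": {
        **{m: +1 for m in _ETV1_MODELS}, **{m: -1 for m in _ETV4_MODELS}
    },
    "invasion_or_aig_assoc": {SHETV4_PC3: +1, SHETV1_LNCAP: +1, PNT2_ETV1: +1},
    "aig_assoc": {SHETV4_MDA: +1, SHETV4_PC3: +1},
    "invasion_assoc": {SHETV1_LNCAP: +1, PNT2_ETV1: +1},
}

# the invasion-or-AIG rule window is (1.2, 1.5); plant its genes at the
# log2 midpoint of that window so they pass 1.2 but stay clear of 1.5
_INV_AIG_L2FC = (np.log2(1.2) + np.log2(1.5)) / 2  # ~0.424, FC ~1.34

DEFAULT_ROLE_L2FC = {role: 1.0 for role in ROLES if role != "null"}
DEFAULT_ROLE_L2FC["invasion_or_aig_assoc"] = float(_INV_AIG_L2FC)


@dataclass
class PlantedTruth:
    """Gene roles plus effect-size and noise parameters.

    ``roles`` maps gene id -> role (genes absent from the map are null);
    ``role_l2fc`` maps role -> planted |log2 FC| (default 1.0 = 2-fold);
    ``noise_sd`` is the per-gene per-sample Gaussian sd in log2 units.
    """

    roles: dict[str, str] = field(default_factory=dict)
    role_l2fc: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ROLE_L2FC))
    noise_sd: float = 0.1

    def __post_init__(self):
        for gene, role in self.roles.items():
            if role not in ROLES:
                raise ValidationError(f"gene {gene!r}: unknown role {role!r}")
        for role, l2fc in self.role_l2fc.items():
            if l2fc < 0:
                raise ValidationError(
                    f"role {role!r}: planted |log2FC| must be >= 0, got {l2fc}"
                )
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, r in self.roles.items() if r == role]

    def effect_l2fc(self, gene: str) -> float:
        role = self.roles.get(gene, "null")
        if role == "null":
            return 0.0
        return self.role_l2fc.get(role, 1.0)


def _enumerate(prefix: str, n: int, start: int = 1) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(start, start + n)]


def study_target_truth(noise_sd: float = 0.1,
                       planted_l2fc: float = 1.0) -> PlantedTruth:
    """Roles mirroring the study's target-set arithmetic: ETV1-specific
    7 up + 6 down, ETV4-specific 9 up + 17 down (each including one of the
    two inversely regulated genes), shared 8 up + 16 down — 61 distinct.
    """
    roles: dict[str, str] = {}
    layout = (
        ("ETV1_target_up", 5), ("ETV1_target_down", 6),
        ("ETV4_target_up", 9), ("ETV4_target_down", 15),
        ("inverse_etv1_up_etv4_down", 2),
        ("shared_up", 8), ("shared_down", 16),
    )
    idx = 1
    for role, n in layout:
        for gene in _enumerate("TGT", n, start=idx):
            roles[gene] = role
        idx += n
    truth = PlantedTruth(roles=roles, noise_sd=noise_sd)
    for role, _ in layout:
        truth.role_l2fc[role] = planted_l2fc
    return truth


def study_phenotype_truth(noise_sd: float = 0.05) -> PlantedTruth:
    """Roles mirroring the study's phenotype sets: 81 invasion-or-AIG,
    17 AIG, 27 invasion genes (disjoint; containment unconstrained)."""
    roles: dict[str, str] = {}
    for gene in _enumerate("PIA", 81):
        roles[gene] = "invasion_or_aig_assoc"
    for gene in _enumerate("PAG", 17):
        roles[gene] = "aig_assoc"
    for gene in _enumerate("PIN", 27):
        roles[gene] = "invasion_assoc"
    return PlantedTruth(roles=roles, noise_sd=noise_sd)


def study_cohort_truth(noise_sd: float = 0.4,
                       panel_l2fc: float = 1.5,
                       panel_genes: Sequence[str] = PANEL_GENES) -> PlantedTruth:
    """The seven-gene invasion panel planted low in pT3 tumors."""
    roles = {gene: "stage_low_in_pT3" for gene in panel_genes}
    truth = PlantedTruth(roles=roles, noise_sd=noise_sd)
    truth.role_l2fc["stage_low_in_pT3"] = panel_l2fc
    return truth


# --- cell-line experiment ----------------------------------------------------

_MODEL_SPECS = (
    # name, ets, kind, control label
    (SHETV1_LNCAP, "ETV1", "silencing", "shNeg"),
    (SHETV1_MDA, "ETV1", "silencing", "shNeg"),
    (SHETV4_MDA, "ETV4", "silencing", "shNeg"),
    (SHETV4_PC3, "ETV4", "silencing", "shNeg"),
    (PNT2_ETV1, "ETV1", "overexpression", "PNT2-Neo"),
)

# log2 shift of the manipulated ETS gene itself: ~75% knockdown when
# silenced, strong ectopic expression when overexpressed
_SELF_KNOCKDOWN_L2FC = -2.0
_SELF_OVEREXPRESSION_L2FC = 4.0


def _build_models(n_replicates: int) -> list[CellLineModel]:
    models = []
    for name, ets, kind, control_label in _MODEL_SPECS:
        def cols(tag):
            if n_replicates == 1:
                return (f"{name}.{tag}",)
            return tuple(f"{name}.{tag}.r{i}" for i in range(1, n_replicates + 1))
        control = Population(label=f"{control_label}-{name}",
                             sample_ids=cols("ctrl"), role="control")
        manipulated = tuple(
            Population(label=f"{name}-P{i}", sample_ids=cols(f"pop{i}"),
                       role="manipulated")
            for i in (1, 2)
        )
        models.append(CellLineModel(name=name, ets=ets, kind=kind,
                                    control=control, manipulated=manipulated))
    return models


def _gene_list(n_genes: int, truth: PlantedTruth,
               include_ets_genes: bool) -> list[str]:
    planted = list(truth.roles)
    ets = ["ETV1", "ETV4"] if include_ets_genes else []
    n_null = n_genes - len(planted) - len(ets)
    if n_null < 0:
        raise ValidationError(
            f"n_genes = {n_genes} is smaller than the {len(planted) + len(ets)} "
            f"planted/ETS genes"
        )
    return ets + planted + _enumerate("NULL", n_null)


def gen_cellline_experiment(
    n_genes: int,
    truth: PlantedTruth,
    seed: Optional[int],
    n_replicates: int = 1,
    noise_sd: Optional[float] = None,
    include_ets_genes: bool = True,
) -> tuple[ExpressionMatrix, list[CellLineModel], PlantedTruth]:
    """Simulate the five-model perturbation experiment.

    Planted genes shift in their associated models' manipulated populations
    (direction inverted in silencing models); null genes are pure noise.
    Deterministic given ``seed``; a missing seed is an error.
    """
    if seed is None:
        raise ValidationError("seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    sd = truth.noise_sd if noise_sd is None else noise_sd
    genes = _gene_list(n_genes, truth, include_ets_genes)
    models = _build_models(n_replicates)

    sample_ids = []
    for model in models:
        sample_ids.extend(model.all_sample_ids)

    baseline = rng.uniform(6.0, 10.0, size=len(genes))
    values = (baseline[:, None]
              + rng.normal(0.0, sd, size=(len(genes), len(sample_ids))))
    data = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=sample_ids)

    for model in models:
        manipulated_cols = [s for pop in model.manipulated
                            for s in pop.sample_ids]
        # knockdown/overexpression of the manipulated ETS gene itself
        if include_ets_genes and model.ets in data.index:
            shift = (_SELF_KNOCKDOWN_L2FC if model.kind == "silencing"
                     else _SELF_OVEREXPRESSION_L2FC)
            data.loc[model.ets, manipulated_cols] += shift
        for gene, role in truth.roles.items():
            assoc = _CELLLINE_ASSOC.get(role, {})
            sign = assoc.get(model.name)
            if sign is None:
                continue
            delta = sign * truth.effect_l2fc(gene)
            if model.kind == "silencing":
                delta = -delta
            data.loc[gene, manipulated_cols] += delta

    return ExpressionMatrix(data), models, truth


# --- tumor cohort ------------------------------------------------------------


def gen_tumor_cohort(
    truth: PlantedTruth,
    seed: Optional[int],
    n_genes: Optional[int] = None,
    n_npt: int = 9,
    subtype_counts: tuple[int, int, int] = (14, 22, 14),
    n_etv1_rearranged: int = 12,
    n_pt3: int = 24,
    n_gleason_high: int = 25,
    noise_sd: Optional[float] = None,
    include_ets_genes: bool = False,
) -> TumorCohort:
    """Simulate the 9 NPT + 50 PCa cohort with planted associations.

    ``subtype_counts`` is (PEA3, ERG, ETS-negative) among the carcinomas and
    must sum to 50 when overridden. Stage and Gleason labels are assigned by
    seeded permutation with the configured prevalences, independent of age
    and PSA by construction. Roles act as follows: stage roles shift pT3
    samples, ``gleason_assoc`` shifts high-Gleason samples down, and ETS
    target roles shift the PEA3 tumors carrying the matching ETS.
    """
    if seed is None:
        raise ValidationError("seed is required for reproducibility")
    n_pea3, n_erg, n_neg = subtype_counts
    n_pca = n_pea3 + n_erg + n_neg
    if n_pca != 50:
        raise ValidationError(
            f"subtype counts must sum to 50 PCa, got {subtype_counts}"
        )
    if n_etv1_rearranged > n_pea3:
        raise ValidationError("ETV1-rearranged count exceeds PEA3 count")
    if not (0 <= n_pt3 <= n_pca and 0 <= n_gleason_high <= n_pca):
        raise ValidationError("stage/Gleason prevalence out of range")

    rng = np.random.default_rng(seed)
    sd = truth.noise_sd if noise_sd is None else noise_sd
    if n_genes is None:
        n_genes = len(truth.roles) + (2 if include_ets_genes else 0)
    genes = _gene_list(n_genes, truth, include_ets_genes)

    npt_ids = [f"NPT{i:02d}" for i in range(1, n_npt + 1)]
    pca_ids = [f"PCA{i:02d}" for i in range(1, n_pca + 1)]
    sample_ids = npt_ids + pca_ids

    subtype = (["PEA3"] * n_pea3 + ["ERG"] * n_erg + ["ETS_negative"] * n_neg)
    pea3_gene = (["ETV1"] * n_etv1_rearranged
                 + ["ETV4"] * (n_pea3 - n_etv1_rearranged)
                 + [None] * (n_erg + n_neg))
    order = rng.permutation(n_pca)
    subtype = [subtype[i] for i in order]
    pea3_gene = [pea3_gene[i] for i in order]

    stage = ["pT3"] * n_pt3 + ["pT2"] * (n_pca - n_pt3)
    stage = [stage[i] for i in rng.permutation(n_pca)]
    gleason = ["high"] * n_gleason_high + ["low"] * (n_pca - n_gleason_high)
    gleason = [gleason[i] for i in rng.permutation(n_pca)]

    age = np.round(rng.normal(64.0, 7.0, size=len(sample_ids))).clip(40, 90)
    psa = np.round(np.exp(rng.normal(np.log(8.0), 0.6,
                                     size=len(sample_ids))), 1)

    anno = pd.DataFrame({
        "tissue": ["NPT"] * n_npt + ["PCa"] * n_pca,
        "subtype": [None] * n_npt + subtype,
        "pea3_gene": [None] * n_npt + pea3_gene,
        "gleason_group": [None] * n_npt + gleason,
        "stage": [None] * n_npt + stage,
        "age_years": age,
        "psa_ng_ml": psa,
    }, index=pd.Index(sample_ids, name="sample_id"))

    baseline = rng.uniform(6.0, 10.0, size=len(genes))
    values = (baseline[:, None]
              + rng.normal(0.0, sd, size=(len(genes), len(sample_ids))))
    data = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=sample_ids)

    is_pt3 = anno["stage"] == "pT3"
    is_high = anno["gleason_group"] == "high"
    pea3_all = anno["subtype"] == "PEA3"
    pea3_etv1 = pea3_all & (anno["pea3_gene"] == "ETV1")
    pea3_etv4 = pea3_all & (anno["pea3_gene"] == "ETV4")

    cohort_shift = {
        "stage_low_in_pT3": (is_pt3, -1),
        "stage_high_in_pT3": (is_pt3, +1),
        "gleason_assoc": (is_high, -1),
        "ETV1_target_up": (pea3_etv1, +1),
        "ETV1_target_down": (pea3_etv1, -1),
        "ETV4_target_up": (pea3_etv4, +1),
        "ETV4_target_down": (pea3_etv4, -1),
        "shared_up": (pea3_all, +1),
        "shared_down": (pea3_all, -1),
    }
    for gene, role in truth.roles.items():
        if role == "inverse_etv1_up_etv4_down":
            data.loc[gene, pea3_etv1[pea3_etv1].index] += truth.effect_l2fc(gene)
            data.loc[gene, pea3_etv4[pea3_etv4].index] -= truth.effect_l2fc(gene)
            continue
        shift_spec = cohort_shift.get(role)
        if shift_spec is None:
            continue
        mask, sign = shift_spec
        data.loc[gene, mask[mask].index] += sign * truth.effect_l2fc(gene)

    return TumorCohort(expression=ExpressionMatrix(data), annotations=anno)


def permute_labels(cohort: TumorCohort, column: str,
                   seed: Optional[int]) -> TumorCohort:
    """Return a cohort with one annotation column permuted among the PCa
    samples — the permutation null for association and panel tests."""
    if seed is None:
        raise ValidationError("seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    anno = cohort.annotations.copy()
    pca = anno.index[anno["tissue"] == "PCa"]
    anno.loc[pca, column] = rng.permutation(anno.loc[pca, column].to_numpy())
    return TumorCohort(expression=cohort.expression, annotations=anno)
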