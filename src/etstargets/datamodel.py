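"""Core domain types for ETS perturbation-model expression analysis.

Expression is carried everywhere in log2 space (exon-array convention);
fold-changes are derived from log2 differences by the signed-FC algebra in
:mod:`etstargets.foldchange`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# --- controlled vocabularies -------------------------------------------------

ETS_CHOICES = ("ETV1", "ETV4")
KIND_CHOICES = ("silencing", "overexpression")
ROLE_CHOICES = ("control", "manipulated")
TISSUE_CHOICES = ("NPT", "PCa")
SUBTYPE_CHOICES = ("PEA3", "ERG", "ETS_negative")
PEA3_GENE_CHOICES = ("ETV1", "ETV4", "ETV5")
GLEASON_CHOICES = ("low", "high")  # low = GS <= 7(3+4), high = GS >= 7(4+3)
STAGE_CHOICES = ("pT2", "pT3")

# canonical names of the five study cell-line models
SHETV1_LNCAP = "shETV1-LNCaP"
SHETV1_MDA = "shETV1-MDA-PCa-2b"
SHETV4_MDA = "shETV4-MDA-PCa-2b"
SHETV4_PC3 = "shETV4-PC3"
PNT2_ETV1 = "PNT2-ETV1"
SILENCING_MODELS = (SHETV1_LNCAP, SHETV1_MDA, SHETV4_MDA, SHETV4_PC3)
ALL_MODELS = SILENCING_MODELS + (PNT2_ETV1,)

# the seven-gene local-invasion panel (GLIS3 excluded for its overlapping
# distribution between pT2 and pT3 tumors)
PANEL_GENES = (
    "CCPG1", "CDK11A", "CHRNB4", "PMCH", "SERF1A", "SLC22A3", "TMPRSS11E",
)


class ValidationError(ValueError):
    """A domain object violated one of its invariants."""


# --- expression matrix -------------------------------------------------------


class ExpressionMatrix:
    """A genes x samples grid of log2 normalized expression values.

    Thin wrapper over a :class:`pandas.DataFrame` (index = gene ids,
    columns = sample ids) enforcing uniqueness and finiteness.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        values = data.to_numpy()
        if values.size and not np.isfinite(values.astype(float, copy=False)).all():
            i, j = np.argwhere(~np.isfinite(values.astype(float)))[0]
            raise ValidationError(
                f"non-finite expression at gene {data.index[i]!r}, "
                f"sample {data.columns[j]!r}"
            )
        self._data = data.astype(float)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self._data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(self._data.loc[:, list(sample_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self._data.equals(other._data)

    def __repr__(self) -> str:
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


# --- cell-line models --------------------------------------------------------


@dataclass(frozen=True)
class Population:
    """One stable cell population (>= 1 replicate array columns)."""

    label: str
    sample_ids: tuple[str, ...]
    role: str  # "control" | "manipulated"

    def __post_init__(self):
        if not self.sample_ids:
            raise ValidationError(f"population {self.label!r} has no samples")
        if self.role not in ROLE_CHOICES:
            raise ValidationError(
                f"population role must be one of {ROLE_CHOICES}, got {self.role!r}"
            )


@dataclass(frozen=True)
class CellLineModel:
    """A perturbation model: one control plus >= 1 manipulated populations."""

    name: str
    ets: str  # "ETV1" | "ETV4"
    kind: str  # "silencing" | "overexpression"
    control: Population
    manipulated: tuple[Population, ...]

    def __post_init__(self):
        if self.ets not in ETS_CHOICES:
            raise ValidationError(f"ets must be one of {ETS_CHOICES}, got {self.ets!r}")
        if self.kind not in KIND_CHOICES:
            raise ValidationError(
                f"kind must be one of {KIND_CHOICES}, got {self.kind!r}"
            )
        if self.control.role != "control":
            raise ValidationError(f"model {self.name!r}: control population role "
                                  f"is {self.control.role!r}")
        if not self.manipulated:
            raise ValidationError(f"model {self.name!r} has no manipulated population")
        for pop in self.manipulated:
            if pop.role != "manipulated":
                raise ValidationError(
                    f"model {self.name!r}: population {pop.label!r} role is "
                    f"{pop.role!r}, expected 'manipulated'"
                )

    @property
    def all_sample_ids(self) -> list[str]:
        ids = list(self.control.sample_ids)
        for pop in self.manipulated:
            ids.extend(pop.sample_ids)
        return ids

    def check_against(self, matrix: ExpressionMatrix) -> None:
        known = set(matrix.sample_ids)
        missing = [s for s in self.all_sample_ids if s not in known]
        if missing:
            raise ValidationError(
                f"model {self.name!r}: samples missing from matrix: {missing}"
            )
        control = set(self.control.sample_ids)
        for pop in self.manipulated:
            overlap = control & set(pop.sample_ids)
            if overlap:
                raise ValidationError(
                    f"model {self.name!r}: samples {sorted(overlap)} appear in both "
                    f"control and manipulated populations"
                )


# --- tumor cohort ------------------------------------------------------------

ANNOTATION_COLUMNS = (
    "tissue", "subtype", "pea3_gene", "gleason_group", "stage",
    "age_years", "psa_ng_ml",
)

_CATEGORICAL_ALLOWED = {
    "tissue": TISSUE_CHOICES,
    "subtype": SUBTYPE_CHOICES,
    "pea3_gene": PEA3_GENE_CHOICES,
    "gleason_group": GLEASON_CHOICES,
    "stage": STAGE_CHOICES,
}


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Check categorical values and NPT invariants; returns the frame."""
    for col in ANNOTATION_COLUMNS:
        if col not in annotations.columns:
            raise ValidationError(f"annotation table missing column {col!r}")
    for col, allowed in _CATEGORICAL_ALLOWED.items():
        values = annotations[col].dropna()
        bad = values[~values.isin(allowed)]
        if len(bad):
            raise ValidationError(
                f"column {col!r}: unknown value {bad.iloc[0]!r} "
                f"(allowed: {', '.join(allowed)} or NA)"
            )
    npt = annotations[annotations["tissue"] == "NPT"]
    for col in ("subtype", "stage", "gleason_group"):
        if npt[col].notna().any():
            bad = npt[npt[col].notna()].index[0]
            raise ValidationError(
                f"NPT sample {bad!r} must have {col} = NA"
            )
    return annotations


@dataclass
class TumorCohort:
    """Expression plus per-sample class/subtype/clinical annotations."""

    expression: ExpressionMatrix
    annotations: pd.DataFrame  # index = sample_id, ANNOTATION_COLUMNS

    def __post_init__(self):
        if list(self.annotations.index) != self.expression.sample_ids:
            raise ValidationError(
                "annotation rows do not match expression sample ids"
            )
        validate_annotations(self.annotations)

    @property
    def pca_samples(self) -> list[str]:
        return list(self.annotations.index[self.annotations["tissue"] == "PCa"])

    @property
    def npt_samples(self) -> list[str]:
        return list(self.annotations.index[self.annotations["tissue"] == "NPT"])

    def staged_pca_samples(self) -> list[str]:
        mask = (self.annotations["tissue"] == "PCa") & self.annotations["stage"].notna()
        return list(self.annotations.index[mask])

    def samples_where(self, column: str, value) -> list[str]:
        return list(self.annotations.index[self.annotations[column] == value])


# --- gene-set report ---------------------------------------------------------

PROVENANCE_CHOICES = (
    "ETV1_specific", "ETV4_specific", "shared",
    "invasion_or_aig", "aig", "invasion",
)
DIRECTION_CHOICES = ("up", "down")


@dataclass
class GeneSetReport:
    """Labeled up/down gene sets with per-model consensus fold-changes.

    ``members`` has one row per (gene, provenance) pair with columns
    ``gene``, ``provenance``, ``direction``, ``inverse`` (bool flag for
    genes present in both specific lists with opposite directions) plus one
    ``fc_<model>`` column per model.
    """

    members: pd.DataFrame

    REQUIRED = ("gene", "provenance", "direction", "inverse")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.members.columns:
                raise ValidationError(f"report missing column {col!r}")
        bad_prov = set(self.members["provenance"]) - set(PROVENANCE_CHOICES)
        if bad_prov:
            raise ValidationError(f"unknown provenance labels: {sorted(bad_prov)}")
        bad_dir = set(self.members["direction"]) - set(DIRECTION_CHOICES)
        if bad_dir:
            raise ValidationError(f"unknown directions: {sorted(bad_dir)}")
        dup = self.members.duplicated(subset=["gene", "provenance"])
        if dup.any():
            row = self.members[dup].iloc[0]
            raise ValidationError(
                f"gene {row['gene']!r} appears twice under provenance "
                f"{row['provenance']!r}"
            )

    def gene_set(self, provenance: str, direction: str | None = None) -> frozenset:
        rows = self.members[self.members["provenance"] == provenance]
        if direction is not None:
            rows = rows[rows["direction"] == direction]
        return frozenset(rows["gene"])

    def union_genes(self) -> frozenset:
        return frozenset(self.members["gene"])

    def cardinalities(self) -> dict[str, int]:
        counts = self.members.groupby("provenance")["gene"].nunique().to_dict()
        counts["union"] = len(self.union_genes())
        return counts

    def sorted_members(self) -> pd.DataFrame:
        return self.members.sort_values(
            ["provenance", "direction", "gene"]
        ).reset_index(drop=True)


# --- run configuration -------------------------------------------------------


@dataclass
class RunConfig:
    """Pipeline thresholds; defaults are the study's printed values."""

    specific_fc: float = 1.5
    shared_fc: float = 1.5
    shared_min_models: int = 3
    inv_aig_include_fc: float = 1.2
    inv_aig_exclude_fc: float = 1.2
    aig_include_fc: float = 1.5
    aig_exclude_fc: float = 1.2
    invasion_include_fc: float = 1.5
    invasion_exclude_fc: float = 1.2
    panel_genes: tuple[str, ...] = PANEL_GENES
    panel_rules: tuple[tuple[float, int], ...] = ((10.0, 1), (25.0, 2), (50.0, 4))
    alpha: float = 0.05
    seed: int | None = None

    _STUDY_DEFAULTS = None  # filled below

    def validate(self) -> list[str]:
        """Return a list of error strings (empty = valid)."""
        errors = []
        for name in ("specific_fc", "shared_fc", "inv_aig_include_fc",
                     "inv_aig_exclude_fc", "aig_include_fc", "aig_exclude_fc",
                     "invasion_include_fc", "invasion_exclude_fc"):
            if getattr(self, name) < 1:
                errors.append(f"{name} must be >= 1 (got {getattr(self, name)})")
        if self.shared_min_models < 1:
            errors.append("shared_min_models must be >= 1")
        if not self.panel_genes:
            errors.append("panel_genes must be non-empty")
        for q, k in self.panel_rules:
            if not (0 < q < 100):
                errors.append(f"panel percentile must be in (0, 100), got {q}")
            if k < 1:
                errors.append(f"panel k must be >= 1, got {k}")
            if k > len(self.panel_genes):
                errors.append(
                    f"panel k = {k} exceeds panel size {len(self.panel_genes)}"
                )
        if not (0 < self.alpha < 1):
            errors.append(f"alpha must be in (0, 1), got {self.alpha}")
        return errors

    def non_study_settings(self) -> list[str]:
        """Names of fields deviating from the study defaults (seed ignored)."""
        default = RunConfig()
        out = []
        for name in ("specific_fc", "shared_fc", "shared_min_models",
                     "inv_aig_include_fc", "inv_aig_exclude_fc",
                     "aig_include_fc", "aig_exclude_fc",
                     "invasion_include_fc", "invasion_exclude_fc",
                     "panel_genes", "panel_rules", "alpha"):
            if getattr(self, name) != getattr(default, name):
                out.append(name)
        return out

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
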