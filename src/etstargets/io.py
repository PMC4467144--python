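"""Tab-delimited readers/writers for matrices, annotations and reports.

All files are UTF-8 TSV with a header row and "." as decimal separator;
missing annotation values are the literal string ``NA``. Output ordering is
deterministic so diffs are stable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    ANNOTATION_COLUMNS,
    ExpressionMatrix,
    GeneSetReport,
    RunConfig,
    TumorCohort,
    ValidationError,
    validate_annotations,
)

_FLOAT_FMT = "%.8g"  # >= 6 significant digits survive a round-trip


def read_expression_matrix(path: Union[str, Path]) -> ExpressionMatrix:
    """Read a ``gene_id<TAB>sample...`` matrix of log2 expression."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise ValidationError(f"{path}: expected gene_id column plus samples")
    gene_col = raw.columns[0]
    genes = raw[gene_col]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    values = raw.iloc[:, 1:]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {values.iat[i, j]!r} at gene "
            f"{genes.iloc[i]!r}, sample {values.columns[j]!r}"
        )
    numeric.index = pd.Index(genes, name="gene_id")
    return ExpressionMatrix(numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path: Union[str, Path]) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


_NUMERIC_ANNOTATIONS = ("age_years", "psa_ng_ml")


def read_annotations(path: Union[str, Path]) -> pd.DataFrame:
    """Read a per-sample annotation table (strict category dialect).

    Literal ``NA`` becomes missing; any other unknown category value is an
    error listing the allowed values.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in raw.columns:
        raise ValidationError(f"{path}: missing sample_id column")
    if raw["sample_id"].duplicated().any():
        dup = raw["sample_id"][raw["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate sample id {dup!r}")
    table = raw.set_index("sample_id")
    table = table.mask(table == "NA")
    for col in _NUMERIC_ANNOTATIONS:
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="raise")
    validate_annotations(table)
    return table


def write_annotations(annotations: pd.DataFrame, path: Union[str, Path]) -> None:
    out = annotations.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)


def read_tumor_cohort(expr_path: Union[str, Path],
                      anno_path: Union[str, Path]) -> TumorCohort:
    matrix = read_expression_matrix(expr_path)
    annotations = read_annotations(anno_path)
    missing = set(matrix.sample_ids) - set(annotations.index)
    if missing:
        raise ValidationError(
            f"samples without annotation: {sorted(missing)}"
        )
    annotations = annotations.loc[matrix.sample_ids]
    return TumorCohort(expression=matrix, annotations=annotations)


def read_cellline_models(path: Union[str, Path]):
    """Read cell-line model layout from a sample annotation table.

    Columns: sample_id, model, ets, kind, population, role. Replicate
    columns of one population share a ``population`` label; each model needs
    exactly one control population.
    """
    from .datamodel import CellLineModel, Population

    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "model", "ets", "kind", "population", "role"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    models = []
    for model_name, group in table.groupby("model", sort=True):
        ets = group["ets"].unique()
        kind = group["kind"].unique()
        if len(ets) != 1 or len(kind) != 1:
            raise ValidationError(
                f"{path}: model {model_name!r} has inconsistent ets/kind"
            )
        controls, manipulated = [], []
        for pop_label, pop in group.groupby("population", sort=True):
            roles = pop["role"].unique()
            if len(roles) != 1:
                raise ValidationError(
                    f"{path}: population {pop_label!r} mixes roles"
                )
            population = Population(label=str(pop_label),
                                    sample_ids=tuple(pop["sample_id"]),
                                    role=str(roles[0]))
            (controls if roles[0] == "control" else manipulated).append(population)
        if len(controls) != 1:
            raise ValidationError(
                f"{path}: model {model_name!r} needs exactly one control "
                f"population, found {len(controls)}"
            )
        models.append(CellLineModel(name=str(model_name), ets=str(ets[0]),
                                    kind=str(kind[0]), control=controls[0],
                                    manipulated=tuple(manipulated)))
    return models


def write_cellline_models(models, path: Union[str, Path]) -> None:
    rows = []
    for model in models:
        for pop in (model.control,) + model.manipulated:
            for sample in pop.sample_ids:
                rows.append({
                    "sample_id": sample, "model": model.name,
                    "ets": model.ets, "kind": model.kind,
                    "population": pop.label, "role": pop.role,
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- gene-set reports --------------------------------------------------------


def write_gene_set_report(report: GeneSetReport, path: Union[str, Path]) -> None:
    """Tab-delimited gene list: gene, direction, provenance, per-model FCs.

    Rows ordered by provenance, then direction, then gene id.
    """
    out = report.sorted_members()
    ordered = ["gene", "direction", "provenance", "inverse"]
    fc_cols = [c for c in out.columns if c.startswith("fc_")]
    out = out[ordered + sorted(fc_cols)]
    out.to_csv(path, sep="\t", index=False, na_rep="NA",
               float_format=_FLOAT_FMT)


def read_gene_set_report(path: Union[str, Path]) -> GeneSetReport:
    raw = pd.read_csv(path, sep="\t", dtype={"gene": str}, na_values=["NA"])
    raw["inverse"] = raw["inverse"].astype(bool)
    return GeneSetReport(members=raw)


def write_panel_evaluations(evaluations, path: Union[str, Path]) -> None:
    """Structured metrics file, one row per (percentile, k) rule."""
    rows = []
    for ev in evaluations:
        rows.append({
            "percentile": ev.rule.percentile,
            "k": ev.rule.k,
            "tp": ev.tp, "fp": ev.fp, "fn": ev.fn, "tn": ev.tn,
            "chi2": ev.chi2, "p": ev.p,
            "ppv": ev.ppv, "npv": ev.npv,
            "sensitivity": ev.sensitivity, "specificity": ev.specificity,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA",
                              float_format="%.10g")


# --- Ct tables ---------------------------------------------------------------


def read_ct_table(path: Union[str, Path]) -> pd.DataFrame:
    """Long-format Ct input: sample_id, target, ct, ref_gene, ref_ct."""
    required = {"sample_id", "target", "ct", "ref_gene", "ref_ct"}
    table = pd.read_csv(path, sep="\t")
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: Ct table missing columns {sorted(missing)}")
    table["ct"] = pd.to_numeric(table["ct"], errors="raise")
    table["ref_ct"] = pd.to_numeric(table["ref_ct"], errors="raise")
    return table


# --- configuration -----------------------------------------------------------


def load_config(path: Union[str, Path, None] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML / flat key=value file.

    File keys must match RunConfig field names; unknown keys are an error.
    """
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        values.update(loaded)
    values.update(overrides)
    field_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(values) - field_names
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "panel_genes" in values:
        values["panel_genes"] = tuple(values["panel_genes"])
    if "panel_rules" in values:
        values["panel_rules"] = tuple(
            (float(q), int(k)) for q, k in values["panel_rules"]
        )
    return RunConfig(**values)
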