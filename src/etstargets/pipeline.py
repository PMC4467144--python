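"""End-to-end orchestration with a reproducibility manifest.

Stages run in study order: synthesize/load -> association profile ->
target sets -> phenotype sets -> cohort associations -> panel scan. Each
stage writes its report; a JSON manifest records the config hash, seed and
a checksum per written file, so a rerun with identical config and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import cohort as cohort_stats
from . import io as dio
from . import panel as panel_mod
from . import phenotypes, synthetic, targets
from .datamodel import RunConfig, TumorCohort, ValidationError
from .foldchange import build_association_profile, write_association_profile

log = logging.getLogger("etstargets.pipeline")


class ConfigError(ValidationError):
    """Aggregated configuration problems."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def validate_config(config: RunConfig) -> RunConfig:
    """Validate, and log every deviation from the study defaults."""
    errors = config.validate()
    if errors:
        raise ConfigError(errors)
    for name in config.non_study_settings():
        log.warning("non-study setting: %s = %r", name, getattr(config, name))
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = {k: v for k, v in dataclasses.asdict(config).items()
               if k != "seed"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(
    config: RunConfig,
    out_dir: Union[str, Path],
    expr_path: Optional[Union[str, Path]] = None,
    anno_path: Optional[Union[str, Path]] = None,
    cohort_expr_path: Optional[Union[str, Path]] = None,
    cohort_anno_path: Optional[Union[str, Path]] = None,
    synthetic_inputs: bool = False,
    n_genes: int = 1000,
) -> Path:
    """Run every stage and return the run directory.

    Inputs are either ``synthetic_inputs=True`` (generated from the
    config's seed) or file paths for the cell-line matrix/annotations and
    the tumor cohort. A stage failure aborts with the failing stage named;
    partial outputs stay on disk next to an ``incomplete`` marker.
    """
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "files": {},
    }
    stage = "inputs"
    try:
        if synthetic_inputs:
            if config.seed is None:
                raise ValidationError("synthetic inputs require a seed")
            truth = synthetic.study_target_truth()
            matrix, models, truth = synthetic.gen_cellline_experiment(
                n_genes=n_genes, truth=truth, seed=config.seed)
            cohort_truth = synthetic.study_cohort_truth(
                panel_genes=config.panel_genes)
            cohort = synthetic.gen_tumor_cohort(
                cohort_truth, seed=config.seed + 1,
                n_genes=max(len(cohort_truth.roles) + 20, 50))
            dio.write_expression_matrix(matrix, out / "cellline_expression.tsv")
            dio.write_cellline_models(models, out / "cellline_models.tsv")
            manifest["stages"]["inputs"] = {
                "mode": "synthetic", "n_genes": n_genes,
                "planted": len(truth.roles),
            }
        else:
            if expr_path is None or anno_path is None:
                raise ValidationError(
                    "expression and model-annotation inputs required "
                    "(or use synthetic_inputs=True)"
                )
            for label, path in (("cell-line expression", expr_path),
                                ("cell-line annotations", anno_path),
                                ("cohort expression", cohort_expr_path),
                                ("cohort annotations", cohort_anno_path)):
                if path is not None and not Path(path).exists():
                    raise ValidationError(f"{label} file not found: {path}")
            matrix = dio.read_expression_matrix(expr_path)
            models = dio.read_cellline_models(anno_path)
            cohort = None
            manifest["stages"]["inputs"] = {
                "mode": "files", "n_genes": matrix.shape[0],
                "models": [m.name for m in models],
            }

        stage = "association_profile"
        profile = build_association_profile(models, matrix)
        write_association_profile(profile, out / "association_profile.tsv")
        manifest["stages"][stage] = {"genes": int(profile.shape[0]),
                                     "models": list(profile.columns)}

        stage = "target_sets"
        target_report = targets.build_target_report(
            profile,
            specific_fc=config.specific_fc, shared_fc=config.shared_fc,
            shared_min_models=config.shared_min_models)
        dio.write_gene_set_report(target_report, out / "target_sets.tsv")
        summary = targets.venn_summary(target_report)
        (out / "target_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        manifest["stages"][stage] = summary

        stage = "phenotype_sets"
        pheno_report = phenotypes.build_phenotype_report(
            profile,
            inv_aig_include_fc=config.inv_aig_include_fc,
            inv_aig_exclude_fc=config.inv_aig_exclude_fc,
            aig_include_fc=config.aig_include_fc,
            aig_exclude_fc=config.aig_exclude_fc,
            invasion_include_fc=config.invasion_include_fc,
            invasion_exclude_fc=config.invasion_exclude_fc)
        dio.write_gene_set_report(pheno_report, out / "phenotype_sets.tsv")
        manifest["stages"][stage] = pheno_report.cardinalities()

        stage = "cohort_associations"
        if not synthetic_inputs and (cohort_expr_path is None
                                     or cohort_anno_path is None):
            manifest["stages"][stage] = {"skipped": "no cohort inputs"}
            cohort = None
        if synthetic_inputs is False and cohort_expr_path is not None:
            cohort = dio.read_tumor_cohort(cohort_expr_path, cohort_anno_path)
        if cohort is not None:
            records = []
            candidate_genes = sorted(
                set(cohort.expression.gene_ids)
                & (target_report.union_genes() | set(config.panel_genes))
            )
            for gene in candidate_genes:
                for contrast in ("PEA3_vs_ETSneg", "PEA3_vs_ERG"):
                    records.append(cohort_stats.subtype_association(
                        cohort, gene, contrast, alpha=config.alpha))
                for grouping in ("gleason_low_vs_high", "pT2_vs_pT3"):
                    records.append(cohort_stats.clinico_path_association(
                        cohort, gene, grouping, alpha=config.alpha).record)
            table = cohort_stats.association_table(records)
            table.to_csv(out / "cohort_associations.tsv", sep="\t",
                         index=False, float_format="%.8g")
            independence = [
                dataclasses.asdict(cohort_stats.covariate_independence(
                    cohort, grouping, alpha=config.alpha))
                for grouping in ("gleason_low_vs_high", "pT2_vs_pT3")
            ]
            (out / "covariate_independence.json").write_text(
                json.dumps(independence, indent=2, sort_keys=True) + "\n")
            manifest["stages"][stage] = {
                "tests": len(records),
                "significant": int(table["significant"].sum()),
            }

            stage = "panel_scan"
            evaluations = panel_mod.cutoff_scan(
                cohort, panel=config.panel_genes, grid=config.panel_rules)
            dio.write_panel_evaluations(evaluations, out / "panel_scan.tsv")
            manifest["stages"][stage] = {
                "rules": len(evaluations),
                "best_p": evaluations[0].p,
                "best_rule": [evaluations[0].rule.percentile,
                              evaluations[0].rule.k],
            }
    except Exception:
        marker.write_text(f"failed at stage: {stage}\n")
        log.error("pipeline failed at stage %s", stage)
        raise

    for path in sorted(out.iterdir()):
        if path.name in ("manifest.json", "INCOMPLETE") or path.is_dir():
            continue
        manifest["files"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    marker.unlink()
    return out
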