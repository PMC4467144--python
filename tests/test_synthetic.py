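"""Determinism and planted-effect fidelity of the synthetic generators."""

import hashlib

import numpy as np
import pytest

from etstargets import (
    PlantedTruth,
    ValidationError,
    build_association_profile,
    build_target_report,
    gen_cellline_experiment,
    gen_tumor_cohort,
    study_cohort_truth,
    study_target_truth,
)
from etstargets.cohort import mann_whitney
from etstargets.datamodel import ALL_MODELS, SILENCING_MODELS


def _digest(matrix):
    return hashlib.sha256(matrix.data.to_csv().encode()).hexdigest()


class TestCellLineGenerator:
    def test_study_layout(self):
        matrix, models, _ = gen_cellline_experiment(
            50, PlantedTruth(), seed=0)
        assert sorted(m.name for m in models) == sorted(ALL_MODELS)
        for model in models:
            assert len(model.manipulated) == 2
        # 5 models x (1 control + 2 manipulated) columns
        assert matrix.shape == (50, 15)

    def test_deterministic_and_seed_sensitive(self):
        a, _, _ = gen_cellline_experiment(40, PlantedTruth(), seed=3)
        b, _, _ = gen_cellline_experiment(40, PlantedTruth(), seed=3)
        c, _, _ = gen_cellline_experiment(40, PlantedTruth(), seed=4)
        assert _digest(a) == _digest(b)
        assert _digest(a) != _digest(c)

    def test_seed_required(self):
        with pytest.raises(ValidationError, match="seed"):
            gen_cellline_experiment(10, PlantedTruth(), seed=None)

    def test_null_truth_gives_empty_target_sets(self):
        """False-positive check: with no planted genes and sd 0.05, the
        default filters stay empty in >= 99% of seeds."""
        clean = 0
        n_seeds = 100
        for seed in range(n_seeds):
            matrix, models, _ = gen_cellline_experiment(
                60, PlantedTruth(noise_sd=0.05), seed=seed)
            profile = build_association_profile(
                [m for m in models if m.kind == "silencing"], matrix)
            report = build_target_report(profile)
            clean += len(report.members) == 0
        assert clean >= 0.99 * n_seeds

    def test_planted_shared_gene_passes_all_four_models(self):
        """A shared_up gene at 2-fold clears +1.5 in every silencing model
        (normal tail bound makes failures ~1e-4 per model at sd 0.1)."""
        truth = PlantedTruth(roles={"G": "shared_up"}, noise_sd=0.1)
        hits = np.zeros(4)
        n_seeds = 50
        for seed in range(n_seeds):
            matrix, models, _ = gen_cellline_experiment(5, truth, seed=seed)
            profile = build_association_profile(models, matrix)
            row = profile.loc["G", list(SILENCING_MODELS)].to_numpy()
            hits += row >= 1.5
        assert (hits >= 0.99 * n_seeds).all()

    def test_planted_effect_size_recovered(self):
        """Group-mean log2 shifts land within 3*sd/sqrt(n) of the plant."""
        truth = PlantedTruth(roles={"G": "shared_up"}, noise_sd=0.1)
        matrix, models, _ = gen_cellline_experiment(
            5, truth, seed=9, n_replicates=20)
        model = models[0]  # a silencing model: association +1 -> shift down
        ctrl = matrix.data.loc["G", list(model.control.sample_ids)]
        manip = matrix.data.loc[
            "G", [s for p in model.manipulated for s in p.sample_ids]]
        observed = manip.mean() - ctrl.mean()
        tol = 3 * 0.1 / np.sqrt(20)
        assert observed == pytest.approx(-1.0, abs=2 * tol)

    def test_ets_self_knockdown_planted(self):
        matrix, models, _ = gen_cellline_experiment(10, PlantedTruth(), seed=2)
        model = [m for m in models if m.name == "shETV1-LNCaP"][0]
        ctrl = matrix.data.loc["ETV1", model.control.sample_ids[0]]
        manip = matrix.data.loc["ETV1", model.manipulated[0].sample_ids[0]]
        assert manip < ctrl - 1.0  # strong knockdown of the targeted ETS


class TestCohortGenerator:
    def test_study_composition_exact(self):
        cohort = gen_tumor_cohort(PlantedTruth(), seed=0, n_genes=5)
        anno = cohort.annotations
        assert (anno["tissue"] == "NPT").sum() == 9
        assert (anno["tissue"] == "PCa").sum() == 50
        counts = anno["subtype"].value_counts()
        assert counts["PEA3"] == 14
        assert counts["ERG"] == 22
        assert counts["ETS_negative"] == 14
        assert (anno["pea3_gene"] == "ETV1").sum() == 12
        assert (anno["stage"] == "pT3").sum() == 24
        assert (anno["stage"] == "pT2").sum() == 26

    def test_deterministic(self):
        a = gen_tumor_cohort(PlantedTruth(), seed=6, n_genes=5)
        b = gen_tumor_cohort(PlantedTruth(), seed=6, n_genes=5)
        assert a.expression == b.expression
        assert a.annotations.equals(b.annotations)

    def test_bad_subtype_counts(self):
        with pytest.raises(ValidationError, match="sum to 50"):
            gen_tumor_cohort(PlantedTruth(), seed=0,
                             subtype_counts=(10, 10, 10))

    def test_stage_gene_power(self):
        """A 2-fold stage-planted gene at sd 0.25 reaches p < 0.05 in
        >= 95% of seeds (pT2 vs pT3 Mann-Whitney)."""
        truth = PlantedTruth(roles={"G": "stage_low_in_pT3"}, noise_sd=0.25)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cohort = gen_tumor_cohort(truth, seed=seed, n_genes=3)
            anno = cohort.annotations
            expr = cohort.expression.data.loc["G"]
            p = mann_whitney(
                expr[anno.index[anno["stage"] == "pT2"]],
                expr[anno.index[anno["stage"] == "pT3"]],
            ).p
            hits += p < 0.05
        assert hits >= 0.95 * n_seeds

    def test_panel_truth_shifts_panel_down_in_pt3(self):
        cohort = gen_tumor_cohort(study_cohort_truth(), seed=4, n_genes=10)
        anno = cohort.annotations
        pt2 = anno.index[anno["stage"] == "pT2"]
        pt3 = anno.index[anno["stage"] == "pT3"]
        diff = (cohort.expression.data.loc["CCPG1", pt3].mean()
                - cohort.expression.data.loc["CCPG1", pt2].mean())
        assert diff == pytest.approx(-1.5, abs=0.5)


def test_distinct_truth_layouts_are_disjoint():
    target = study_target_truth()
    counts = {}
    for role in set(target.roles.values()):
        counts[role] = len(target.genes_with_role(role))
    assert counts == {
        "ETV1_target_up": 5, "ETV1_target_down": 6,
        "ETV4_target_up": 9, "ETV4_target_down": 15,
        "inverse_etv1_up_etv4_down": 2,
        "shared_up": 8, "shared_down": 16,
    }
    assert sum(counts.values()) == 61
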