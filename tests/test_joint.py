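"""Lifestyle categorisation, joint-effect grids and the interaction LRT."""

import numpy as np
import pandas as pd
import pytest

from grsjoint.grs import compute_grs
from grsjoint.joint import (
    JointEffectsModel,
    categorize_lifestyle,
    lrt_interaction,
    lrt_interaction_from_codes,
)
from grsjoint.simulate import SimulationConfig, simulate_cohort, simulate_genotypes, simulate_phenotypes


def pheno_row(pid, bmi, whr, exercise, status="control"):
    return {"id": pid, "status": status, "age": 55.0, "sex": "female",
            "bmi": bmi, "whr": whr, "exercise": exercise}


class TestCategorizeLifestyle:
    def test_all_three_risk_factors(self):
        phenos = pd.DataFrame([pheno_row("a", 26.0, 0.90, False)])
        cats = categorize_lifestyle(phenos, whr_tertile_basis="fixed", whr_cuts=(0.81, 0.85))
        assert cats.loc[0, "composite"] == 3
        assert cats.loc[0, "bmi_class"] == 1
        assert bool(cats.loc[0, "high_whr"])

    def test_no_risk_factors(self):
        phenos = pd.DataFrame([pheno_row("a", 23.0, 0.80, True)])
        cats = categorize_lifestyle(phenos, whr_tertile_basis="fixed", whr_cuts=(0.81, 0.85))
        assert cats.loc[0, "composite"] == 0

    def test_bmi_boundary_values(self):
        phenos = pd.DataFrame(
            [pheno_row("a", 25.0, 0.8, True), pheno_row("b", 30.0, 0.8, True)]
        )
        cats = categorize_lifestyle(phenos, whr_tertile_basis="fixed", whr_cuts=(0.81, 0.85))
        # exactly 25 -> lowest class and no composite BMI point; exactly 30 -> highest
        assert cats.loc[0, "bmi_class"] == 0
        assert cats.loc[0, "composite"] == 0
        assert cats.loc[1, "bmi_class"] == 2

    def test_composite_equals_sum_of_components(self, analytic_sample):
        _, phenos, _ = analytic_sample
        cats = categorize_lifestyle(phenos)
        expected = (
            (phenos["bmi"].to_numpy() > 25).astype(int)
            + (phenos["whr"].to_numpy() > 0.85).astype(int)
            + (~phenos["exercise"].to_numpy()).astype(int)
        )
        np.testing.assert_array_equal(cats["composite"].to_numpy(), expected)
        assert set(cats["composite"]) <= {0, 1, 2, 3}

    def test_whr_tertiles_from_sample(self, analytic_sample):
        _, phenos, _ = analytic_sample
        cats = categorize_lifestyle(phenos)
        counts = cats["whr_tertile"].value_counts()
        assert sorted(counts.index) == [1, 2, 3]


class TestJointEffectTable:
    def test_reference_cell_is_one(self, analytic_sample, panel):
        matrix, phenos, _ = analytic_sample
        table = compute_grs(matrix, panel, score="GRS1")
        cats = categorize_lifestyle(phenos)
        res = JointEffectsModel(table, cats, phenos, env="bmi").fit()
        ref = [c for c in res.cells if c.is_reference]
        assert len(ref) == 1
        assert ref[0].or_value == 1.0
        assert ref[0].grs_category == 1 and ref[0].env_category == "<=25"
        assert np.isnan(ref[0].ci95[0])

    def test_multiplicative_null_recovered(self, panel):
        # no interaction wired in: each cell OR should match row OR x column OR
        config = SimulationConfig(n_cases=20_000, n_controls=20_000, seed=61)
        matrix, phenos = simulate_cohort(config, panel)
        table = compute_grs(matrix, panel, score="GRS1")
        cats = categorize_lifestyle(phenos)
        res = JointEffectsModel(table, cats, phenos, env="exercise").fit()
        grid = {(c.grs_category, c.env_category): c for c in res.cells}
        for g in (2, 3):
            for e in ("no_exercise",):
                joint_or = grid[(g, e)].or_value
                margin = grid[(g, "exercise")].or_value * grid[(1, e)].or_value
                # multiplicative prediction within a loose factor at this n
                assert joint_or == pytest.approx(margin, rel=0.25)

    def test_monotone_margins_in_expectation(self, analytic_sample, panel):
        matrix, phenos, _ = analytic_sample
        table = compute_grs(matrix, panel, score="GRS1")
        cats = categorize_lifestyle(phenos)
        res = JointEffectsModel(table, cats, phenos, env="bmi").fit()
        grid = {(c.grs_category, c.env_category): c.or_value for c in res.cells}
        # risk rises along the GRS margin within the low-BMI row, and along
        # the BMI margin within the low-GRS column
        assert grid[(3, "<=25")] > grid[(1, "<=25")]
        assert grid[(1, ">=30")] > grid[(1, "<=25")]

    def test_empty_cell_reported_not_raised(self, small_cohort, panel):
        _, matrix, phenos = small_cohort
        table = compute_grs(matrix, panel, score="GRS1")
        cats = categorize_lifestyle(phenos)
        # rig an empty cell: nobody in tertile 3 with BMI >= 30
        sel = (table["tertile"].reindex(phenos["id"]).to_numpy() == 3) & (
            phenos["bmi"].to_numpy() >= 30
        )
        phenos2 = phenos.copy()
        phenos2.loc[sel, "bmi"] = 27.0
        cats2 = categorize_lifestyle(phenos2)
        res = JointEffectsModel(table, cats2, phenos2, env="bmi").fit()
        cell = next(c for c in res.cells if c.grs_category == 3 and c.env_category == ">=30")
        assert cell.or_value is None
        assert cell.n_cases == 0 and cell.n_controls == 0

    def test_adjustment_sets_follow_panel_defaults(self, analytic_sample, panel):
        matrix, phenos, _ = analytic_sample
        table = compute_grs(matrix, panel, score="GRS1")
        cats = categorize_lifestyle(phenos)
        assert JointEffectsModel(table, cats, phenos, env="bmi").adjust == ("age", "sex")
        assert JointEffectsModel(table, cats, phenos, env="whr").adjust == ("age", "sex", "bmi")
        custom = JointEffectsModel(table, cats, phenos, env="whr", adjust=("age", "sex"))
        assert custom.adjust == ("age", "sex")

    def test_reference_relabelling_invariance(self, analytic_sample, panel):
        matrix, phenos, _ = analytic_sample
        table = compute_grs(matrix, panel, score="GRS1")
        cats = categorize_lifestyle(phenos)
        res1 = JointEffectsModel(table, cats, phenos, env="exercise").fit()
        # refit after shuffling row order: ORs must be unchanged
        perm = phenos.sample(frac=1.0, random_state=5).reset_index(drop=True)
        cats_perm = categorize_lifestyle(perm)
        res2 = JointEffectsModel(table, cats_perm, perm, env="exercise").fit()
        for c1, c2 in zip(res1.cells, res2.cells):
            if c1.or_value is None:
                assert c2.or_value is None
            else:
                assert c2.or_value == pytest.approx(c1.or_value, abs=1e-6)


class TestLrtInteraction:
    def test_zero_statistic_gives_p_one(self):
        from scipy import stats

        assert stats.chi2.sf(0.0, 1) == 1.0  # contract for chi2 = 0

    def test_detects_wired_interaction(self, panel):
        # power smoke test: a wired-in product effect is detected in most seeds
        p_values = []
        for seed in range(10):
            config = SimulationConfig(n_cases=3000, n_controls=3000, seed=seed,
                                      grs_env_interaction_beta=0.15)
            matrix, phenos = simulate_cohort(config, panel)
            table = compute_grs(matrix, panel, score="GRS1")
            cats = categorize_lifestyle(phenos)
            chi2, df, p = lrt_interaction(table, cats, phenos, env="exercise")
            assert df == 1
            p_values.append(p)
        assert np.median(p_values) < 0.05

    def test_null_no_rejection_excess(self, panel):
        # quick null calibration at module scale (the full 500-replicate
        # calibration runs in the acceptance suite)
        rejections = 0
        n_sims = 40
        for seed in range(n_sims):
            config = SimulationConfig(n_cases=1500, n_controls=1500, seed=100 + seed)
            matrix, phenos = simulate_cohort(config, panel)
            table = compute_grs(matrix, panel, score="GRS1")
            cats = categorize_lifestyle(phenos)
            _, _, p = lrt_interaction(table, cats, phenos, env="exercise")
            rejections += p < 0.05
        assert rejections <= 8  # binomial(40, 0.05) upper tail allowance

    def test_full_model_cannot_undercut_nested(self):
        rng = np.random.default_rng(17)
        n = 2000
        g = rng.integers(0, 3, n).astype(float)
        e = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.2 + 0.3 * g + 0.2 * e)))).astype(float)
        X = pd.DataFrame({"const": np.ones(n)})
        chi2, df, p = lrt_interaction_from_codes(y, g, e, X)
        assert chi2 >= 0.0
        assert 0.0 <= p <= 1.0
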