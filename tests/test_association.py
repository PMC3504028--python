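"""Logistic fitting, single-SNP and GRS association, HWE QC, descriptives."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from grsjoint.association import (
    direction_consistency,
    fit_logistic,
    genotype_counts,
    grs_assoc,
    hwe_chi2,
    single_snp_assoc,
    table1_descriptives,
)
from grsjoint.exceptions import FitError, SeparationError
from grsjoint.grs import compute_grs
from grsjoint.panel import GenotypeMatrix
from grsjoint.simulate import SimulationConfig, simulate_genotypes, simulate_phenotypes


def design_from(df):
    X = df.copy()
    X.insert(0, "const", 1.0)
    return X


class TestFitLogistic:
    def test_two_by_two_matches_cross_product_ratio(self):
        # exposed cases 100, unexposed cases 100, exposed controls 50, unexposed controls 100
        y = np.concatenate([np.ones(200), np.zeros(150)])
        x = np.concatenate([np.ones(100), np.zeros(100), np.ones(50), np.zeros(100)])
        fit = fit_logistic(y, design_from(pd.DataFrame({"exposed": x})))
        assert fit.term("exposed").or_value == pytest.approx(2.0, abs=1e-6)

    def test_null_covariate_beta_near_zero(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=10_000).astype(float)
        x = np.tile([0.0, 1.0], 5_000)
        r = fit_logistic(y, design_from(pd.DataFrame({"x": x}))).term("x")
        assert abs(r.beta) < 3 * r.se

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(FitError, match="one status"):
            fit_logistic(np.ones(20), design_from(pd.DataFrame({"x": np.arange(20.0)})))

    def test_separation_detected_and_named(self):
        y = np.concatenate([np.ones(50), np.zeros(50)])
        x = y.copy()  # perfect predictor
        with pytest.raises((SeparationError, FitError)):
            fit_logistic(y, design_from(pd.DataFrame({"sep_term": x})))

    def test_constant_non_intercept_column_rejected(self):
        y = np.concatenate([np.ones(10), np.zeros(10)])
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(y, design_from(pd.DataFrame({"flat": np.ones(20)})))

    def test_ci_and_or_consistent_with_beta(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        y = (rng.random(2000) < 1 / (1 + np.exp(-0.5 * x))).astype(float)
        r = fit_logistic(y, design_from(pd.DataFrame({"x": x}))).term("x")
        assert r.or_value == pytest.approx(np.exp(r.beta))
        lo, hi = r.ci95
        assert lo < r.or_value < hi
        assert lo == pytest.approx(np.exp(r.beta - 1.959963984540054 * r.se))

    def test_nested_model_never_has_higher_likelihood(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=3000)
        x2 = rng.normal(size=3000)
        y = (rng.random(3000) < 1 / (1 + np.exp(-(0.3 * x1)))).astype(float)
        small = fit_logistic(y, design_from(pd.DataFrame({"x1": x1})))
        big = fit_logistic(y, design_from(pd.DataFrame({"x1": x1, "x2": x2})))
        assert big.llf >= small.llf - 1e-9


class TestSingleSnpAssoc:
    def test_simulated_or_recovered(self, panel):
        rsid = "rs4402960"
        config = SimulationConfig(n_cases=8000, n_controls=8000, seed=21,
                                  per_snp_or={rsid: 1.2}, control_eaf={rsid: 0.26})
        matrix = simulate_genotypes(config, panel)
        phenos = simulate_phenotypes(config)
        r = single_snp_assoc(matrix, phenos, rsid)
        assert abs(r.beta - np.log(1.2)) < 3 * r.se

    def test_flipped_coding_negates_beta(self, analytic_sample):
        matrix, phenos, _ = analytic_sample
        r = single_snp_assoc(matrix, phenos, "rs1111875")
        flipped = GenotypeMatrix(
            list(matrix.participant_ids), list(matrix.snp_ids), 2.0 - matrix.dosage
        )
        r_flip = single_snp_assoc(flipped, phenos, "rs1111875")
        assert r_flip.beta == pytest.approx(-r.beta, abs=1e-6)
        assert r_flip.or_value == pytest.approx(1.0 / r.or_value, rel=1e-6)

    def test_monomorphic_snp_rejected(self, small_cohort):
        _, matrix, phenos = small_cohort
        d = matrix.dosage.copy()
        d[:, 0] = 1.0
        mono = GenotypeMatrix(list(matrix.participant_ids), list(matrix.snp_ids), d)
        with pytest.raises(ValueError, match="monomorphic"):
            single_snp_assoc(mono, phenos, matrix.snp_ids[0])

    def test_missing_genotypes_dropped_per_snp(self, small_cohort):
        _, matrix, phenos = small_cohort
        d = matrix.dosage.copy()
        d[:10, 0] = np.nan
        m = GenotypeMatrix(list(matrix.participant_ids), list(matrix.snp_ids), d)
        r = single_snp_assoc(m, phenos, matrix.snp_ids[0])
        assert r.n_used == matrix.n_participants - 10


class TestGrsAssoc:
    def test_common_or_recovered_per_point(self, panel):
        # every SNP simulated at the same per-allele OR: the continuous score
        # term must recover that common OR
        r_common = 1.05
        config = SimulationConfig(
            n_cases=10_000, n_controls=10_000, seed=31,
            per_snp_or={s.rsid: r_common for s in panel},
        )
        matrix = simulate_genotypes(config, panel)
        phenos = simulate_phenotypes(config)
        table = compute_grs(matrix, panel, score="GRS1")
        fit = grs_assoc(table, phenos, form="continuous")
        r = fit.results[0]
        assert abs(r.beta - np.log(r_common)) < 3 * r.se

    def test_reference_category_or_is_one(self, analytic_sample, panel):
        matrix, phenos, _ = analytic_sample
        table = compute_grs(matrix, panel, score="GRS1")
        fit = grs_assoc(table, phenos, form="quintile")
        assert fit.results[0].or_value == 1.0
        assert np.isnan(fit.results[0].ci95[0])
        assert len(fit.results) == 5

    def test_quintile_ors_increase_under_study_ors(self, analytic_sample, panel):
        matrix, phenos, _ = analytic_sample
        table = compute_grs(matrix, panel, score="GRS1")
        fit = grs_assoc(table, phenos, form="quintile")
        ors = [r.or_value for r in fit.results]
        assert ors[4] > ors[0]
        assert fit.trend_p < 1e-4
        assert fit.heterogeneity_p < 1e-3

    def test_tertile_form_and_trend(self, analytic_sample, panel):
        matrix, phenos, _ = analytic_sample
        table = compute_grs(matrix, panel, score="GRS2")
        fit = grs_assoc(table, phenos, form="tertile")
        assert len(fit.results) == 3
        assert fit.results[0].or_value == 1.0


class TestHwe:
    def test_exact_proportions_zero_statistic(self):
        r = hwe_chi2((25, 50, 25))
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)
        assert not r.excluded

    def test_hand_computed_example(self):
        # f = 0.5 -> expected 25/50/25; chi2 = 1 + 2 + 1 = 4
        r = hwe_chi2((30, 40, 30))
        assert r.chi2 == pytest.approx(4.0)
        assert r.p_value == pytest.approx(0.0455, abs=5e-4)
        assert not r.excluded

    def test_extreme_het_deficit_excluded(self):
        r = hwe_chi2((50, 0, 50))
        assert r.chi2 == pytest.approx(100.0)
        assert r.excluded

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_chi2((0, 0, 0))

    def test_genotype_counts_ignore_missing(self):
        counts = genotype_counts(np.array([0, 1, 2, np.nan, 1]))
        assert counts == (1, 2, 1)

    def test_chi2_flag_matches_exact_oracle_on_clear_cut_triples(self):
        """Levene-Haldane exact oracle: the chi-square 1e-4 flag agrees wherever
        the chi-square approximation is defensible (all expected genotype counts
        >= 5) and the p-value is not within a decade of the threshold."""

        def exact_hwe_p(n2, n1, n0):
            n = n2 + n1 + n0
            na = 2 * n2 + n1
            probs, tot = {}, 0.0
            for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
                a2 = (na - h) // 2
                a0 = n - a2 - h
                if a0 < 0:
                    continue
                w = comb(n, a2) * comb(n - a2, h) * 2**h
                probs[h] = w
                tot += w
            p_obs = probs[n1] / tot
            return sum(v / tot for v in probs.values() if v / tot <= p_obs + 1e-12)

        checked = 0
        for total in range(10, 51):
            for n2 in range(total + 1):
                for n1 in range(total - n2 + 1):
                    n0 = total - n2 - n1
                    p = (2 * n2 + n1) / (2 * total)
                    expected = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2]) * total
                    if expected.min() < 5:
                        continue
                    chi_p = hwe_chi2((n2, n1, n0)).p_value
                    ex_p = exact_hwe_p(n2, n1, n0)
                    if 1e-5 <= chi_p <= 1e-3 or 1e-5 <= ex_p <= 1e-3:
                        continue
                    checked += 1
                    assert (chi_p < 1e-4) == (ex_p < 1e-4), (n2, n1, n0)
        assert checked > 5000


class TestDescriptives:
    def test_identical_samples_give_maximal_p(self):
        half = pd.DataFrame(
            {
                "id": [f"p{i}" for i in range(40)],
                "age": np.linspace(42, 70, 40),
                "sex": ["male", "female"] * 20,
                "bmi": np.linspace(19, 33, 40),
                "whr": np.linspace(0.7, 1.0, 40),
                "exercise": [True, False] * 20,
            }
        )
        phenos = pd.concat(
            [half.assign(status="control"),
             half.assign(status="case", id=[f"q{i}" for i in range(40)])],
            ignore_index=True,
        )
        out = table1_descriptives(phenos)
        assert (out["p_value"].dropna() > 0.99).all()

    def test_fixture_control_bmi_fraction(self, analytic_sample):
        _, phenos, _ = analytic_sample
        out = table1_descriptives(phenos)
        row = out[(out["variable"] == "BMI categories (%)") & (out["category"] == "<=25")]
        assert row["control"].iloc[0] == pytest.approx(68.4, abs=2.5)

    def test_exercise_chi2_from_study_margins(self):
        # 2x2 table reconstructed from exercise fractions 0.364/0.387 at the
        # study group sizes; independent textbook chi-square oracle
        from scipy import stats

        n_ctrl, n_case = 3322, 2679
        table = np.array(
            [
                [round(0.364 * n_ctrl), n_ctrl - round(0.364 * n_ctrl)],
                [round(0.387 * n_case), n_case - round(0.387 * n_case)],
            ]
        )
        p = stats.chi2_contingency(table, correction=False)[1]
        assert 0.05 < p < 0.10

    def test_single_status_rejected(self):
        phenos = pd.DataFrame(
            {
                "id": ["a", "b"], "status": ["case", "case"], "age": [50.0, 60.0],
                "sex": ["male", "female"], "bmi": [22.0, 28.0], "whr": [0.8, 0.9],
                "exercise": [True, False],
            }
        )
        with pytest.raises(ValueError):
            table1_descriptives(phenos)


class TestDirectionConsistency:
    def make_results(self, panel, ors):
        from grsjoint.association import AssocResult

        return [
            AssocResult(term=s.rsid, beta=np.log(o), se=0.1, or_value=o,
                        ci95=(o * 0.9, o * 1.1), p_value=0.5, n_used=100, model="m")
            for s, o in zip(panel, ors)
        ]

    def test_all_above_one(self, panel):
        res = self.make_results(panel, [1.5] * 36)
        assert direction_consistency(res, panel) == (36, 36)

    def test_all_below_one(self, panel):
        res = self.make_results(panel, [0.8] * 36)
        assert direction_consistency(res, panel) == (0, 36)

    def test_or_exactly_one_counts_inconsistent(self, panel):
        res = self.make_results(panel, [1.0] * 36)
        assert direction_consistency(res, panel) == (0, 36)

    def test_published_panel_ors_give_24(self, panel):
        # at printed two-decimal precision 24 ORs strictly exceed 1 (one is 1.00)
        res = self.make_results(panel, [s.published_or for s in panel])
        assert direction_consistency(res, panel) == (24, 36)
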