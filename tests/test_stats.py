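import numpy as np
import pandas as pd
import pytest

from megslow.stats import (
    BONFERRONI_ALPHA,
    ModelResult,
    fit_baseline_group_model,
    fit_clinical_association,
    fit_interaction_model,
    fit_progression_model,
    permutation_connection_test,
)

VISITS = ("BL", "FU1", "FU2")


# ---------------------------------------------------------------------------
# table builders (direct construction: the statistical layer is exercised
# without signal simulation, against known generating coefficients)


def make_longitudinal_table(
    rng,
    n_de_novo=20,
    n_treated=40,
    n_hc=0,
    visit_effects=(0.0, -0.02, -0.04),
    subject_sd=0.01,
    noise_sd=0.005,
    baseline_mean=0.3,
    dropout=0.0,
    measure="rel_power_alpha2_cortical",
    age_slope=0.0,
):
    rows = []
    counter = 0
    for group, n in (("HC", n_hc), ("de_novo", n_de_novo), ("treated", n_treated)):
        for _ in range(n):
            counter += 1
            subj = f"S{counter:03d}"
            age = rng.normal(62, 7)
            sex = "M" if rng.random() < 0.55 else "F"
            isced = int(rng.random() < 0.6)
            dur = max(rng.normal(4, 3), 0.0) if group != "HC" else 0.0
            b = rng.normal(0, subject_sd)
            ledd = max(rng.normal(400, 300), 0.0) if group == "treated" else 0.0
            n_visits = 1 if group == "HC" else len(VISITS)
            for v in range(n_visits):
                if v > 0 and rng.random() < dropout:
                    break
                rows.append(
                    {
                        "subject": subj, "group": group, "visit": VISITS[v],
                        "age": age, "sex": sex, "ISCED": isced,
                        "disease_duration": dur,
                        "LEDD": max(ledd + 350 * v + rng.normal(0, 80), 0.0)
                        if group != "HC" else 0.0,
                        "UPDRS_III": np.nan, "CAMCOG": np.nan,
                        measure: baseline_mean
                        + visit_effects[v]
                        + age_slope * age
                        + b
                        + rng.normal(0, noise_sd),
                    }
                )
                ledd = ledd  # LEDD increments handled in expression above
    return pd.DataFrame(rows)


def make_null_matrices(rng, n, n_regions=20, base=0.5, sd=0.03):
    mats = []
    for _ in range(n):
        a = rng.standard_normal((n_regions, n_regions)) * sd
        m = base + (a + a.T) / 2
        np.fill_diagonal(m, np.nan)
        mats.append(np.clip(m, 0.0, 1.0))
    return mats


# ---------------------------------------------------------------------------
# permutation tests


class TestPermutationTest:
    def test_identical_matrices_give_p_one(self, rng):
        mats = make_null_matrices(rng, 1) * 10  # ten copies of one matrix
        res = permutation_connection_test(
            mats[:5], mats[5:], n_permutations=200, seed=1
        )
        assert np.all(res.p == 1.0)
        assert not res.significant.any()
        res_p = permutation_connection_test(
            mats[:5], mats[5:], n_permutations=200, paired=True, seed=1
        )
        assert np.all(res_p.p == 1.0)

    def test_p_value_bounds_and_q_dominance(self, rng):
        a = make_null_matrices(rng, 10)
        b = make_null_matrices(rng, 12)
        res = permutation_connection_test(a, b, n_permutations=500, seed=3)
        assert np.all(res.p >= 1.0 / 501.0)
        assert np.all(res.p <= 1.0)
        assert np.all(res.q >= res.p - 1e-15)
        np.testing.assert_array_equal(res.significant, res.q <= 0.05)

    def test_deterministic_given_seed(self, rng):
        a = make_null_matrices(rng, 8)
        b = make_null_matrices(rng, 8)
        r1 = permutation_connection_test(a, b, n_permutations=300, seed=7)
        r2 = permutation_connection_test(a, b, n_permutations=300, seed=7)
        np.testing.assert_array_equal(r1.p, r2.p)

    def test_paired_subject_mismatch_rejected(self, rng):
        a = make_null_matrices(rng, 5)
        b = make_null_matrices(rng, 5)
        with pytest.raises(ValueError, match="same subjects"):
            permutation_connection_test(
                a, b, n_permutations=100, paired=True,
                subjects_a=["s1", "s2", "s3", "s4", "s5"],
                subjects_b=["s1", "s2", "s3", "s4", "OTHER"],
            )
        with pytest.raises(ValueError, match="equally many"):
            permutation_connection_test(
                a, b[:4], n_permutations=100, paired=True
            )

    def test_planted_edges_recovered_with_fdr(self, rng):
        # 20 planted connections shifted by +0.3 against noise sd 0.03:
        # all should survive BH across the 190 connections, and false
        # positives should stay rare
        n_reg, shift = 20, 0.3
        a = make_null_matrices(rng, 15, n_regions=n_reg)
        b = make_null_matrices(rng, 15, n_regions=n_reg)
        iu = np.triu_indices(n_reg, k=1)
        planted = [(iu[0][k], iu[1][k]) for k in range(0, 190, 10)]
        for m in a:
            for i, j in planted:
                m[i, j] += shift
                m[j, i] += shift
        res = permutation_connection_test(a, b, n_permutations=2000, seed=9)
        frame = res.to_frame()
        flagged = {
            (i - 1, j - 1)
            for i, j in frame.loc[frame.significant, ["region_i", "region_j"]]
            .itertuples(index=False)
        }
        assert set(planted) <= flagged
        assert len(flagged - set(planted)) <= 5

    def test_edge_list_uses_one_based_regions(self, rng):
        a = make_null_matrices(rng, 4)
        b = make_null_matrices(rng, 4)
        res = permutation_connection_test(a, b, n_permutations=100, seed=2)
        frame = res.to_frame()
        assert frame["region_i"].min() == 1
        assert frame["region_j"].max() == 20


# ---------------------------------------------------------------------------
# mixed models


class TestProgressionModel:
    def test_recovers_planted_visit_effects(self, rng):
        table = make_longitudinal_table(rng, dropout=0.15)
        res = fit_progression_model(table, "rel_power_alpha2_cortical")
        fu1, fu2 = res.term("FU1"), res.term("FU2")
        assert fu1.ci_low <= -0.02 <= fu1.ci_high
        assert fu2.ci_low <= -0.04 <= fu2.ci_high
        assert res.alpha == pytest.approx(BONFERRONI_ALPHA)
        assert res.n_subjects == 60

    def test_healthy_controls_excluded(self, rng):
        table = make_longitudinal_table(rng, n_hc=10)
        res = fit_progression_model(table, "rel_power_alpha2_cortical")
        assert res.n_subjects == 60  # the 10 HC subjects do not contribute

    def test_constant_dependent_rejected(self, rng):
        table = make_longitudinal_table(rng)
        table["rel_power_alpha2_cortical"] = 0.5
        with pytest.raises(ValueError, match="constant"):
            fit_progression_model(table, "rel_power_alpha2_cortical")

    def test_single_visit_rejected(self, rng):
        table = make_longitudinal_table(rng)
        table = table[table.visit == "BL"]
        with pytest.raises(ValueError, match="two visits"):
            fit_progression_model(table, "rel_power_alpha2_cortical")

    def test_reduces_to_ols_without_subject_variance(self, rng):
        import statsmodels.formula.api as smf

        table = make_longitudinal_table(rng, subject_sd=0.0)
        res = fit_progression_model(table, "rel_power_alpha2_cortical")
        formula = res.formula
        ols = smf.ols(formula, data=table).fit()
        for term in res.params.index:
            assert res.params.loc[term, "estimate"] == pytest.approx(
                ols.params[term], rel=0.05, abs=2e-4
            )


class TestBaselineGroupModel:
    def test_recovers_planted_group_shift(self, rng):
        table = make_longitudinal_table(
            rng, n_hc=16, n_de_novo=17, n_treated=44,
            visit_effects=(0.0, 0.0, 0.0), noise_sd=0.01,
        )
        col = "rel_power_alpha2_cortical"
        shift = table["group"].isin(["de_novo", "treated"]).astype(float)
        table[col] = table[col] + 0.05 * shift
        res = fit_baseline_group_model(table, col)
        for g in ("de_novo", "treated"):
            row = res.term(g)
            assert row.p < BONFERRONI_ALPHA
            assert row.ci_low <= 0.05 <= row.ci_high

    def test_pure_age_effect_not_attributed_to_group(self, rng):
        table = make_longitudinal_table(
            rng, n_hc=20, n_de_novo=20, n_treated=20,
            visit_effects=(0.0, 0.0, 0.0),
            subject_sd=0.0, noise_sd=0.01, age_slope=0.002,
        )
        res = fit_baseline_group_model(table, "rel_power_alpha2_cortical")
        age = res.term("age")
        assert age.ci_low <= 0.002 <= age.ci_high
        assert res.term("de_novo").p > BONFERRONI_ALPHA
        assert res.term("treated").p > BONFERRONI_ALPHA

    def test_empty_group_rejected(self, rng):
        table = make_longitudinal_table(rng, n_hc=0)
        with pytest.raises(ValueError, match="HC"):
            fit_baseline_group_model(table, "rel_power_alpha2_cortical")


class TestInteractionModel:
    @staticmethod
    def _bl_table(rng, cortical_shift, subcortical_shift, n=25):
        rows = []
        for g, grp in (("HC", 0.0), ("de_novo", 1.0)):
            for k in range(n):
                b = rng.normal(0, 0.005)
                rows.append(
                    {
                        "subject": f"{g}{k}", "group": g, "visit": "BL",
                        "age": rng.normal(60, 6),
                        "sex": "M" if rng.random() < 0.5 else "F",
                        "ISCED": int(rng.random() < 0.5),
                        "m_cortical": 0.3 + grp * cortical_shift + b
                        + rng.normal(0, 0.005),
                        "m_subcortical": 0.3 + grp * subcortical_shift + b
                        + rng.normal(0, 0.005),
                    }
                )
        return pd.DataFrame(rows)

    def test_cortical_only_effect_detected(self, rng):
        table = self._bl_table(rng, cortical_shift=0.04, subcortical_shift=0.0)
        res = fit_interaction_model(table, "m")
        inter = res.term(":")
        assert inter.p < 0.05
        assert inter.ci_low <= -0.04 <= inter.ci_high  # subcortical deviates less

    def test_equal_effects_center_interaction_at_zero(self, rng):
        table = self._bl_table(rng, cortical_shift=0.04, subcortical_shift=0.04)
        res = fit_interaction_model(table, "m")
        inter = res.term(":")
        assert inter.ci_low <= 0.0 <= inter.ci_high

    def test_missing_location_rows_rejected(self, rng):
        table = self._bl_table(rng, 0.0, 0.0)
        table.loc[table.index[2], "m_subcortical"] = np.nan
        with pytest.raises(ValueError, match="missing location"):
            fit_interaction_model(table, "m")


class TestClinicalAssociation:
    @staticmethod
    def _table(rng, slope, predictor="rel_power_delta", dep="CAMCOG", n=50):
        table = make_longitudinal_table(
            rng, n_de_novo=n // 2, n_treated=n // 2,
            visit_effects=(0.0, 0.01, 0.02),
            measure=f"{predictor}_cortical",
            baseline_mean=0.1, subject_sd=0.02, noise_sd=0.01,
        )
        x = table[f"{predictor}_cortical"]
        noise = rng.normal(0, 1.0, size=len(table))
        table[dep] = 100.0 + slope * x + noise
        return table

    def test_negative_planted_relation_gives_negative_coefficient(self, rng):
        table = self._table(rng, slope=-50.0)
        res = fit_clinical_association(
            table, "CAMCOG", "rel_power_delta", "cortical"
        )
        row = res.term("rel_power_delta_cortical")
        assert row.estimate < 0
        assert row.ci_low <= -50.0 <= row.ci_high

    def test_isced_only_for_camcog(self, rng):
        t1 = self._table(rng, slope=-30.0)
        res1 = fit_clinical_association(
            t1, "CAMCOG", "rel_power_delta", "cortical"
        )
        assert "ISCED" in res1.formula
        t2 = self._table(rng, slope=30.0, dep="UPDRS_III")
        res2 = fit_clinical_association(
            t2, "UPDRS_III", "rel_power_delta", "cortical"
        )
        assert "ISCED" not in res2.formula
        assert "recording_system" in res2.formula

    def test_invalid_arguments_rejected(self, rng):
        table = self._table(rng, slope=0.0)
        with pytest.raises(ValueError, match="CAMCOG"):
            fit_clinical_association(table, "HY", "rel_power_delta", "cortical")
        with pytest.raises(ValueError, match="location"):
            fit_clinical_association(table, "CAMCOG", "rel_power_delta", "lobar")
        with pytest.raises(ValueError, match="missing columns"):
            fit_clinical_association(table, "CAMCOG", "peak_frequency", "cortical")


class TestModelResult:
    def test_ci_must_contain_estimate(self):
        params = pd.DataFrame(
            {"estimate": [1.0], "ci_low": [1.5], "ci_high": [2.0], "p": [0.5]},
            index=["x"],
        )
        with pytest.raises(ValueError, match="interval"):
            ModelResult("y", "y ~ x", params, 10, 5, "OLS", True)

    def test_summary_lists_terms(self, rng):
        table = make_longitudinal_table(rng)
        res = fit_progression_model(table, "rel_power_alpha2_cortical")
        text = res.summary()
        assert "FU1" in text and "FU2" in text
        assert "random intercept" in text
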