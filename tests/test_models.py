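"""Engraftment models: tables, fits, marginal effects, donor swaps."""

import warnings

import numpy as np
import pandas as pd
import pytest

from fmtstrains.models import ModelFit, donor_swap_matrix, fit_case_glmm, \
    fit_strain_glmm, genus_probability, marginal_effect, predict_pairing
from fmtstrains.synthetic import simulate_case_table, simulate_strain_cohort


@pytest.fixture(scope="module")
def strain_fit():
    cohort = simulate_strain_cohort(n_cases=40, n_donors=12, n_species=80,
                                    seed=31)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_strain_glmm(cohort.table)
    return cohort, fit


@pytest.fixture(scope="module")
def case_fit():
    table, truth = simulate_case_table(n_cases=120, n_studies=6, seed=32)
    return table, truth, fit_case_glmm(table)


class TestCaseModel:
    def test_sign_recovery(self, case_fit):
        table, truth, fit = case_fit
        assert fit.converged
        for k, b in truth["beta"].items():
            if k != "intercept" and abs(b) >= 0.5:
                assert np.sign(fit.params[k]) == np.sign(b), k

    def test_single_study_degrades(self, case_fit):
        table, _, _ = case_fit
        sub = table[table["study_id"] == table["study_id"].iloc[0]]
        with pytest.warns(UserWarning, match="study random effect"):
            fit = fit_case_glmm(sub)
        assert "study_id" not in fit.groups

    def test_zero_variance_covariate_dropped(self, case_fit):
        table, _, _ = case_fit
        mod = table.copy()
        mod["abx"] = 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            fit = fit_case_glmm(mod)
        assert "abx" in fit.dropped
        assert "abx" not in fit.params.index


class TestBuildCaseTable:
    def test_from_rendered_cohort(self, small_cohort):
        from fmtstrains import attribution as attr
        from fmtstrains.models import build_case_table
        from fmtstrains.profiles import FilterParams

        summaries = []
        for case in small_cohort.cases:
            donor = attr.pool_donor_samples(
                small_cohort.donor_samples(case), FilterParams())
            tabs, days, pabx = {}, {}, {}
            for post in case.post_samples:
                tabs[post.sample_id] = attr.attribute_origins(
                    case.pre_samples[0], donor, post)
                days[post.sample_id] = post.day
                pabx[post.sample_id] = post.post_abx
            s = attr.engraftment_summary(tabs, days, pabx)
            summaries.append(s)
        table = build_case_table(small_cohort,
                                 pd.concat(summaries, ignore_index=True))
        assert not table.empty
        # scaled covariates have mean 0, sd 1
        for c in ("recipient_shannon", "days_since_fmt"):
            assert table[c].mean() == pytest.approx(0.0, abs=1e-9)
            assert table[c].std() == pytest.approx(1.0, abs=1e-9)
        n_expected = sum(
            1 for case in small_cohort.cases
            for p in case.post_samples if not p.post_abx)
        assert len(table) <= n_expected

    def test_imputation_uses_abx_stratum_means(self, small_cohort):
        from fmtstrains import attribution as attr
        from fmtstrains.models import build_case_table
        from fmtstrains.profiles import FilterParams

        # flag the first case for pre-FMT metric imputation
        small_cohort.cases[0].covariates["impute_pre"] = True
        try:
            summaries = []
            for case in small_cohort.cases:
                donor = attr.pool_donor_samples(
                    small_cohort.donor_samples(case), FilterParams())
                tabs = {p.sample_id: attr.attribute_origins(
                    case.pre_samples[0], donor, p)
                    for p in case.post_samples}
                summaries.append(attr.engraftment_summary(
                    tabs, {p.sample_id: p.day for p in case.post_samples}))
            table = build_case_table(
                small_cohort, pd.concat(summaries, ignore_index=True),
                scale=False, exclude_post_abx=False)
            imputed = table[table["impute_pre"]]
            observed_abx = (table["abx"] > 0) & ~table["impute_pre"]
            expected = table.loc[observed_abx, "recipient_shannon"].mean()
            np.testing.assert_allclose(
                imputed["recipient_shannon"].values, expected)
        finally:
            small_cohort.cases[0].covariates.pop("impute_pre")


class TestMarginalEffect:
    def test_monotone_in_positive_coefficient(self, case_fit):
        table, truth, fit = case_fit
        out = marginal_effect(fit, table, "abx", [0.0, 1.0])
        assert out.loc[1, "probability"] > out.loc[0, "probability"]
        assert (out["ci_upper"] >= out["probability"]).all()

    def test_unknown_variable_rejected(self, case_fit):
        _, _, fit = case_fit
        with pytest.raises(ValueError):
            marginal_effect(fit, pd.DataFrame(), "nope", [0])


class TestGenusProbability:
    def test_max_mode_dominates(self, strain_fit):
        cohort, fit = strain_fit
        genus = cohort.table["genus"].value_counts().index[0]
        obs = genus_probability(fit, cohort.table, genus, "observed")
        mx = genus_probability(fit, cohort.table, genus, "max")
        mn = genus_probability(fit, cohort.table, genus, "min")
        assert mn <= obs <= mx or np.isclose(mn, mx)

    def test_single_row_genus(self, strain_fit):
        cohort, fit = strain_fit
        sizes = cohort.table["genus"].value_counts()
        singles = sizes[sizes == 1]
        if len(singles):
            g = singles.index[0]
            row = cohort.table[cohort.table["genus"] == g]
            assert genus_probability(fit, cohort.table, g) == \
                pytest.approx(float(fit.predict_proba(row)[0]))

    def test_absent_genus_rejected(self, strain_fit):
        cohort, fit = strain_fit
        with pytest.raises(ValueError):
            genus_probability(fit, cohort.table, "not_a_genus")


class TestPredictPairing:
    def test_empty_donor_zero(self, strain_fit):
        _, fit = strain_fit
        assert predict_pairing(fit, pd.DataFrame()) == 0.0

    def test_duplicated_rows_double_expectation(self, strain_fit):
        cohort, fit = strain_fit
        rows = cohort.pairing_rows(cohort.cases.index[0],
                                   cohort.cases["donor_id"].iloc[0])
        one = predict_pairing(fit, rows)
        two = predict_pairing(fit, pd.concat([rows, rows]))
        assert two == pytest.approx(2 * one)


class TestDonorSwap:
    def test_identical_donors_identical_columns(self, strain_fit):
        cohort, fit = strain_fit
        twin = cohort.donor_abund.iloc[0].copy()
        cohort.donor_abund.loc["twin"] = twin.values
        try:
            swap = donor_swap_matrix(fit, cohort)
            first = cohort.donor_abund.index[0]
            np.testing.assert_allclose(swap.matrix["twin"].values,
                                       swap.matrix[first].values,
                                       rtol=1e-9)
            fc = np.log2(swap.matrix["twin"] / swap.matrix[first])
            np.testing.assert_allclose(fc, 0.0, atol=1e-9)
        finally:
            cohort.donor_abund.drop(index="twin", inplace=True)

    def test_actual_pair_fold_change_zero(self, strain_fit):
        cohort, fit = strain_fit
        swap = donor_swap_matrix(fit, cohort)
        for cid in list(cohort.cases.index)[:5]:
            did = cohort.cases.loc[cid, "donor_id"]
            assert swap.log2_fold_change.loc[cid, did] == \
                pytest.approx(0.0, abs=1e-9)
        assert swap.variance_between_pairs >= 0
        assert swap.variance_between_donors >= 0


class TestPersistence:
    def test_save_load_round_trip(self, strain_fit, tmp_path):
        cohort, fit = strain_fit
        path = tmp_path / "model.json"
        fit.save(path)
        loaded = ModelFit.load(path)
        rows = cohort.table.head(50)
        np.testing.assert_allclose(loaded.predict_proba(rows),
                                   fit.predict_proba(rows), rtol=1e-12)
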