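import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adaptscan.groupstats import (
    ModelSpec,
    bh_adjust,
    bic_bayes_factor,
    demographic_matching,
    emmeans_contrasts,
    fit_lmem,
    lrt,
    pairwise_group_permutations,
    permute_group_effect,
    select_model,
    wald_for_term,
    wald_terms,
)
from adaptscan.groupstats.design import FixedEffectsEncoder
from adaptscan.simcortex.cohort import CohortSpec, participant_records, simulate_measures


@pytest.fixture(scope="module")
def measures():
    return simulate_measures(CohortSpec(seed=11))


@pytest.fixture(scope="module")
def rs_spec():
    return ModelSpec(response="rs_magnitude", factors=("group", "category"))


@pytest.fixture(scope="module")
def rs_fit_ml(rs_spec, measures):
    return fit_lmem(rs_spec, measures, method="ml")


@pytest.fixture(scope="module")
def rs_fit_reml(rs_spec, measures):
    return fit_lmem(rs_spec, measures, method="reml")


def _sm_frame(measures):
    df = measures[measures.measure == "rs_magnitude"].copy()
    df["age_c"] = df.age - df.age.mean()
    return df


class TestEncoder:
    def test_reference_levels_and_names(self, measures, rs_spec):
        df = measures[measures.measure == "rs_magnitude"]
        enc = FixedEffectsEncoder(rs_spec, df)
        assert enc.levels["group"][0] == "TD"
        assert enc.levels["category"][0] == "faces"
        assert enc.names[0] == "Intercept"
        assert "group[OTC_patient]" in enc.names
        assert "group[OTC_patient]:category[objects]" in enc.names
        # 1 + 2 + 2 + 4 + 1 columns
        assert enc.n_columns == 10

    def test_reference_row_is_intercept_only(self, measures, rs_spec):
        df = measures[measures.measure == "rs_magnitude"]
        enc = FixedEffectsEncoder(rs_spec, df)
        row = enc.row_for({"group": "TD", "category": "faces"})
        expect = np.zeros(enc.n_columns)
        expect[0] = 1.0
        assert np.allclose(row, expect)  # covariate centred at its mean

    def test_grid_size(self, measures, rs_spec):
        df = measures[measures.measure == "rs_magnitude"]
        enc = FixedEffectsEncoder(rs_spec, df)
        assert len(enc.grid()) == 9


class TestLMEMAgainstStatsmodels:
    def test_ml_loglik_and_params(self, measures, rs_fit_ml):
        smf = pytest.importorskip("statsmodels.formula.api")
        df = _sm_frame(measures)
        mf = smf.mixedlm(
            "value ~ C(group, Treatment('TD')) * C(category, Treatment('faces'))"
            " + age_c",
            df,
            groups=df.participant_id,
        ).fit(reml=False)
        assert rs_fit_ml.loglik == pytest.approx(mf.llf, abs=1e-6)
        ours = dict(zip(rs_fit_ml.encoder.names, rs_fit_ml.params))
        sm_map = {
            "Intercept": "Intercept",
            "group[OTC_patient]": "C(group, Treatment('TD'))[T.OTC_patient]",
            "group[control_patient]": "C(group, Treatment('TD'))[T.control_patient]",
            "category[objects]": "C(category, Treatment('faces'))[T.objects]",
            "age": "age_c",
        }
        for k, smk in sm_map.items():
            assert ours[k] == pytest.approx(mf.fe_params[smk], abs=1e-6)

    def test_reml_params_se_and_variances(self, measures):
        smf = pytest.importorskip("statsmodels.formula.api")
        spec = ModelSpec(
            response="rs_magnitude", factors=("group", "category"), max_order=1
        )
        fit = fit_lmem(spec, measures, method="reml")
        df = _sm_frame(measures)
        mf = smf.mixedlm(
            "value ~ C(group, Treatment('TD')) + C(category, Treatment('faces'))"
            " + age_c",
            df,
            groups=df.participant_id,
        ).fit(reml=True)
        assert fit.sigma2 == pytest.approx(mf.scale, rel=1e-4)
        assert fit.tau2 == pytest.approx(float(mf.cov_re.iloc[0, 0]), rel=1e-4)
        assert np.allclose(np.sort(fit.params), np.sort(mf.fe_params.values), atol=1e-6)
        assert np.allclose(np.sort(fit.se), np.sort(mf.bse_fe.values), atol=1e-5)

    def test_reduces_to_ols_without_grouping_signal(self):
        # one observation per participant: tau2 is confounded with sigma2, so
        # it stays near zero and the GLS solution equals ordinary least
        # squares exactly (V is a multiple of the identity)
        rng = np.random.default_rng(0)
        n = 120
        df = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(n)],
                "group": rng.choice(["TD", "control_patient", "OTC_patient"], n),
                "age": rng.normal(16, 4, n),
                "measure": "rs_magnitude",
                "category": "faces",
                "value": rng.normal(0.3, 0.1, n),
            }
        )
        spec = ModelSpec(response="rs_magnitude", factors=("group",))
        fit = fit_lmem(spec, df, method="ml")
        X, y = fit.X, fit.y
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.tau2 < 0.05 * fit.sigma2
        assert np.allclose(fit.params, beta_ols, atol=1e-8)

    def test_method_validation(self, rs_spec, measures):
        with pytest.raises(ValueError, match="method"):
            fit_lmem(rs_spec, measures, method="gls")


class TestWald:
    def test_single_df_wald_is_squared_z(self, measures):
        spec = ModelSpec(response="rs_magnitude", factors=("group", "category"))
        fit = fit_lmem(spec, measures)
        res = wald_for_term(fit, ("age",))
        i = fit.encoder.names.index("age")
        assert res.chi_sq == pytest.approx((fit.params[i] / fit.se[i]) ** 2)
        assert res.df == 1

    def test_type2_matches_joint_when_no_relatives(self, measures):
        spec = ModelSpec(
            response="rs_magnitude", factors=("group", "category"), max_order=1
        )
        fit = fit_lmem(spec, measures)
        for r2, r3 in zip(wald_terms(fit, "II"), wald_terms(fit, "III")):
            assert r2.chi_sq == pytest.approx(r3.chi_sq, rel=1e-9)

    def test_type2_differs_from_type3_with_interaction(self, rs_fit_reml):
        t2 = wald_for_term(rs_fit_reml, ("group",), "II")
        t3 = wald_for_term(rs_fit_reml, ("group",), "III")
        assert t2.df == t3.df == 2
        assert t2.chi_sq != pytest.approx(t3.chi_sq)

    def test_unknown_kind(self, rs_fit_reml):
        with pytest.raises(ValueError, match="kind"):
            wald_terms(rs_fit_reml, "IV")


class TestSelectionAndBF:
    def test_lrt_nested_direction(self, rs_spec, measures, rs_fit_ml):
        reduced = fit_lmem(rs_spec.drop_term(("group", "category")), measures, "ml")
        chi, df, p = lrt(rs_fit_ml, reduced)
        assert df == 4 and chi >= 0 and 0 <= p <= 1
        with pytest.raises(ValueError, match="nested"):
            lrt(reduced, rs_fit_ml)

    def test_lrt_requires_ml(self, rs_spec, measures, rs_fit_reml, rs_fit_ml):
        with pytest.raises(ValueError, match="ML"):
            lrt(rs_fit_reml, rs_fit_ml)

    def test_select_model_null_drops_interaction(self, measures):
        spec = ModelSpec(response="rs_magnitude", factors=("group", "category"))
        res = select_model(spec, measures, alpha=0.001)
        terms = res.fit.spec.expanded_terms()
        assert ("group", "category") not in terms or res.trail[-1].removed is False
        assert len(res.trail) >= 1
        assert res.fit.method == "reml"

    def test_selection_keeps_injected_effect(self):
        deltas = {"OTC_patient": {"rs_magnitude": -0.25}}
        meas = simulate_measures(CohortSpec(effect_deltas=deltas, seed=21))
        spec = ModelSpec(response="rs_magnitude", factors=("group", "category"))
        res = select_model(spec, meas)
        assert any("group" in t for t in res.fit.spec.expanded_terms())

    def test_bf_reciprocal_identity(self, rs_spec, measures, rs_fit_ml):
        reduced = fit_lmem(rs_spec.drop_term(("group", "category")), measures, "ml")
        a = bic_bayes_factor(rs_fit_ml, reduced).bf01
        b = np.exp((reduced.bic - rs_fit_ml.bic) / 2)
        assert a * b == pytest.approx(1.0, rel=1e-9)

    def test_bf_requires_ml(self, rs_spec, measures, rs_fit_reml, rs_fit_ml):
        with pytest.raises(ValueError, match="ML"):
            bic_bayes_factor(rs_fit_reml, rs_fit_ml)


class TestBH:
    def test_hand_computed_adjustment(self):
        p = [0.01, 0.02, 0.03, 0.04]
        # step-up: p_(i) * m / i with monotonicity from the largest down
        expect = [0.04, 0.04, 0.04, 0.04]
        assert np.allclose(bh_adjust(p), expect)

    def test_known_mixed_example(self):
        p = [0.005, 0.04, 0.2]
        # raw*m/i = [.015, .06, .2]; cumulative-min from the right unchanged
        assert np.allclose(bh_adjust(p), [0.015, 0.06, 0.2])

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=25)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


class TestEMM:
    def test_cells_and_contrast_count(self, rs_fit_reml):
        cells, cons = emmeans_contrasts(rs_fit_reml, ["group"])
        assert len(cells) == 3
        assert len(cons) == 3
        assert "p_bh" in cons.columns

    def test_emm_matches_cell_mean_structure(self, measures):
        # in a balanced design without covariate effect, the group EMM is
        # close to that group's raw mean
        spec = ModelSpec(
            response="rs_magnitude", factors=("group", "category"), covariates=()
        )
        fit = fit_lmem(spec, measures)
        cells, _ = emmeans_contrasts(fit, ["group"])
        df = measures[measures.measure == "rs_magnitude"]
        for _, row in cells.iterrows():
            raw = df[df.group == row.group].value.mean()
            assert row.emm == pytest.approx(raw, abs=0.02)

    def test_unknown_factor(self, rs_fit_reml):
        with pytest.raises(ValueError, match="factor"):
            emmeans_contrasts(rs_fit_reml, ["hemisphere"])


class TestPermutation:
    def test_null_p_not_extreme(self, rs_spec):
        meas = simulate_measures(CohortSpec(seed=303))
        res = permute_group_effect(rs_spec, meas, n_iter=99, seed=4)
        assert 0.0 <= res.p <= 1.0
        assert res.p_smoothed == pytest.approx((res.n_at_or_above + 1) / 100)

    def test_detects_large_effect(self, rs_spec):
        deltas = {"OTC_patient": {"rs_magnitude": -0.4}}
        meas = simulate_measures(CohortSpec(effect_deltas=deltas, seed=17))
        res = permute_group_effect(rs_spec, meas, n_iter=99, seed=4)
        assert res.p <= 0.05

    def test_resample_mode_runs(self, rs_spec):
        meas = simulate_measures(CohortSpec(n_td=6, n_control_patients=4, n_otc_patients=4, seed=5))
        res = permute_group_effect(rs_spec, meas, n_iter=49, seed=1, mode="resample")
        assert res.n_iter == 49

    def test_invalid_args(self, rs_spec, measures):
        with pytest.raises(ValueError, match="factor"):
            permute_group_effect(rs_spec, measures, factor="hemisphere", n_iter=9)
        with pytest.raises(ValueError, match="mode"):
            permute_group_effect(rs_spec, measures, mode="swap", n_iter=9)

    def test_pairwise_table(self, rs_spec):
        meas = simulate_measures(CohortSpec(n_td=6, n_control_patients=4, n_otc_patients=4, seed=9))
        tab = pairwise_group_permutations(rs_spec, meas, n_iter=49, seed=2)
        assert len(tab) == 3
        assert (tab.p_bh >= tab.p_raw - 1e-12).all()


class TestMatching:
    def test_balanced_groups_large_p(self):
        rec = participant_records(CohortSpec(seed=8))
        res = demographic_matching(rec, n_iter=199, seed=3)
        assert res.p > 0.05

    def test_detects_shifted_covariate(self):
        rec = participant_records(CohortSpec(seed=8)).copy()
        rec.loc[rec.group == "OTC_patient", "age"] += 30.0
        res = demographic_matching(rec, n_iter=199, seed=3)
        assert res.p < 0.05
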