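"""Component-wise gradient boosting: design building, the fitting loop,
stopping-iteration tuning, prediction, and score extraction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import brentq

from mia_score import (
    BoostingConfig,
    BoostingFit,
    Cohort,
    GeneratorConfig,
    Location,
    ScoreCoefficients,
    Shape,
    build_design,
    extract_score,
    fit,
    predict_prob,
    rank_patient,
    sample_cohort,
    select_mstop,
)
from mia_score.boosting import ANEURYSM_COVARIATES, DEFAULT_COVARIATES, RANDOM_EFFECT

from conftest import make_patient


def size_only_truth(slope=0.3):
    return ScoreCoefficients(
        size_slope=slope, location_offset={l: 0.0 for l in Location}, irregular_offset=0.0
    )


@pytest.fixture(scope="module")
def size_only_cohort():
    """~200 aneurysms whose rupture depends on size alone."""
    return sample_cohort(
        GeneratorConfig(n_patients=81, seed=3, truth=size_only_truth(), signal_scale=1.0)
    )


class TestBuildDesign:
    def test_same_region_pair_counts_each_other(self):
        cohort = Cohort(
            patients=(
                make_patient("p1", [(4.0, Location.MCA, Shape.REGULAR, True),
                                    (6.0, Location.MCA, Shape.REGULAR, False)]),
            )
        )
        d = build_design(cohort)
        assert d.additional_aneurysms_same_region.tolist() == [1.0, 1.0]
        assert d.aneurysms_per_patient.tolist() == [2.0, 2.0]

    def test_distinct_regions_count_zero(self):
        cohort = Cohort(
            patients=(
                make_patient("p1", [(4.0, Location.MCA, Shape.REGULAR, True),
                                    (6.0, Location.PCOM, Shape.REGULAR, False)]),
            )
        )
        d = build_design(cohort)
        assert d.additional_aneurysms_same_region.tolist() == [0.0, 0.0]

    def test_prospective_cohort_dimensions(self, prospective):
        d = build_design(prospective)
        assert len(d) == 83 and d.ruptured.sum() == 34
        # dummies with the AcomA/AA region as reference
        acom = (d[[c for c in d.columns if c.startswith("loc_")]].sum(axis=1) == 0)
        assert acom.sum() == sum(
            1 for _, a in prospective.aneurysms() if a.location is Location.ACOM_AA
        )

    def test_missing_shape_is_rejected(self):
        cohort = Cohort(
            patients=(make_patient("p1", [(4.0, Location.MCA, Shape.MISSING, True),
                                          (2.0, Location.MCA, Shape.REGULAR, False)]),)
        )
        with pytest.raises(ValueError, match="impute"):
            build_design(cohort)


class TestFit:
    def test_zero_iterations_returns_base_rate(self, size_only_cohort):
        cfg = BoostingConfig()
        f = fit(size_only_cohort, cfg, m_stop=0)
        assert all(v == 0.0 for v in f.coefficients.values())
        pred = predict_prob(f, size_only_cohort)
        d = build_design(size_only_cohort)
        assert np.allclose(pred.probability, d.ruptured.mean())

    def test_first_iteration_matches_brute_force_component_search(self, size_only_cohort):
        """The selected component at iteration 1 is exactly the base learner a
        brute-force least-squares loop finds to have minimal RSS."""
        cfg = BoostingConfig(use_random_effect=True, random_effect_df=4.0)
        f = fit(size_only_cohort, cfg, m_stop=1)

        d = build_design(size_only_cohort)
        y = d.ruptured.to_numpy(float)
        u = y - y.mean()  # negative gradient at the log-odds offset
        rss = {}
        for name in DEFAULT_COVARIATES:
            x = d[name].to_numpy(float)
            x = x - x.mean()
            sxx = x @ x
            b = (x @ u) / sxx if sxx > 0 else 0.0
            rss[name] = float((u - b * x) @ (u - b * x))
        # ridge-penalized patient intercepts at the same effective df
        sizes = d.groupby("patient_id").size().to_numpy(float)
        lam = brentq(lambda l: np.sum(sizes / (sizes + l)) - 4.0, 1e-9, 1e6)
        fitted = (
            d.assign(u=u).groupby("patient_id")["u"].sum().to_numpy() / (sizes + lam)
        )
        per_patient = dict(zip(sorted(d.patient_id.unique()), fitted))
        re_fit = d.patient_id.map(per_patient).to_numpy()
        rss[RANDOM_EFFECT] = float((u - re_fit) @ (u - re_fit))
        assert f.selection_path[0] == min(rss, key=rss.get)

    def test_training_deviance_non_increasing(self, size_only_cohort):
        for nu in (0.05, 0.1, 0.5, 1.0):
            f = fit(size_only_cohort, BoostingConfig(step_length_nu=nu), m_stop=120)
            assert (np.diff(f.deviance_path) <= 1e-9).all()

    def test_coefficients_shrink_with_earlier_stopping(self, small_signal_cohort):
        cfg = BoostingConfig(use_random_effect=False)
        l1 = {
            m: sum(abs(v) for v in fit(small_signal_cohort, cfg, m).coefficients.values())
            for m in (25, 250)
        }
        assert l1[25] < l1[250]

    def test_unselected_covariates_are_exactly_zero(self, size_only_cohort):
        cfg = BoostingConfig(use_random_effect=False)
        f = fit(size_only_cohort, cfg, m_stop=40)
        selected = set(f.selection_path)
        for name, coef in f.coefficients.items():
            if name not in selected:
                assert coef == 0.0
        assert len(f.selection_path) == f.m_stop == 40

    def test_degenerate_outcome_rejected(self):
        cohort = Cohort(
            patients=(make_patient("p1", [(4.0, Location.MCA, Shape.REGULAR, True),
                                          (2.0, Location.MCA, Shape.REGULAR, True)]),)
        )
        with pytest.raises(ValueError, match="degenerate"):
            fit(cohort, BoostingConfig(), m_stop=5)

    def test_nan_candidate_covariates_rejected(self, prospective):
        # the packaged cohort has no patient covariates
        with pytest.raises(ValueError, match="NaN"):
            fit(prospective, BoostingConfig(), m_stop=5)

    def test_fit_json_round_trip(self, size_only_cohort, tmp_path):
        f = fit(size_only_cohort, BoostingConfig(), m_stop=30)
        path = tmp_path / "fit.json"
        f.to_json(path)
        again = BoostingFit.from_json(path)
        assert again == f


class TestOracleEquivalence:
    """Dual-route check: the boosting path against an independently coded
    iteratively-reweighted-least-squares (statsmodels Logit) fit."""

    def test_joint_learner_converges_to_logistic_mle(self, size_only_cohort):
        cfg = BoostingConfig(
            use_random_effect=False, single_learner=True, step_length_nu=1.0,
            max_iterations=3000,
        )
        f = fit(size_only_cohort, cfg, m_stop=3000)
        d = build_design(size_only_cohort)
        X = sm.add_constant(d[list(DEFAULT_COVARIATES)])
        mle = sm.Logit(d.ruptured, X).fit(disp=0).params
        for name in DEFAULT_COVARIATES:
            assert f.coefficients[name] == pytest.approx(mle[name], abs=1e-3)
        assert f.intercept == pytest.approx(mle["const"], abs=1e-3)

    def test_componentwise_size_slope_within_5pct_of_mle(self, size_only_cohort):
        cfg = BoostingConfig(use_random_effect=False, max_iterations=5000)
        f = fit(size_only_cohort, cfg, m_stop=5000)
        d = build_design(size_only_cohort)
        X = sm.add_constant(d[list(DEFAULT_COVARIATES)])
        mle = sm.Logit(d.ruptured, X).fit(disp=0).params
        assert f.coefficients["size_mm"] == pytest.approx(mle["size_mm"], rel=0.05)


class TestSelectMstop:
    def test_deterministic_given_seed(self, size_only_cohort):
        cfg = BoostingConfig(max_iterations=150, seed=5)
        m1, c1 = select_mstop(size_only_cohort, cfg)
        m2, c2 = select_mstop(size_only_cohort, cfg)
        assert m1 == m2 and np.array_equal(c1, c2)

    def test_single_candidate_iteration(self, size_only_cohort):
        m, curve = select_mstop(size_only_cohort, BoostingConfig(max_iterations=1))
        assert m == 1 and len(curve) == 1

    def test_pure_noise_selects_early_stopping(self):
        """With no signal among the candidate covariates (under a zero-signal
        generator only the aneurysm characteristics are pure noise — the
        aneurysm count still carries the marginal 1/k rupture rate) held-out
        deviance favours stopping almost immediately."""
        cohort = sample_cohort(GeneratorConfig(n_patients=120, seed=17, signal_scale=0.0))
        cfg = BoostingConfig(max_iterations=400, seed=17, use_random_effect=False,
                             candidate_covariates=tuple(ANEURYSM_COVARIATES))
        m, _ = select_mstop(cohort, cfg)
        assert m < 100  # small relative to the iteration budget

    def test_fewer_patients_than_folds_rejected(self):
        cohort = sample_cohort(GeneratorConfig(n_patients=5, seed=1))
        with pytest.raises(ValueError, match="folds"):
            select_mstop(cohort, BoostingConfig(inner_cv_folds=10))


class TestPredictAndExtract:
    def test_zero_fit_extracts_zero_score(self, size_only_cohort):
        f = fit(size_only_cohort, BoostingConfig(), m_stop=0)
        sc = extract_score(f)
        assert sc.size_slope == 0.0 and sc.irregular_offset == 0.0
        assert all(v == 0.0 for v in sc.location_offset.values())

    def test_probability_monotone_in_size(self, size_only_cohort):
        f = fit(size_only_cohort, BoostingConfig(use_random_effect=False), m_stop=300)
        assert f.coefficients["size_mm"] > 0
        probe = Cohort(
            patients=(
                make_patient(
                    "q", [(s, Location.MCA, Shape.REGULAR, None) for s in (2.0, 5.0, 9.0, 20.0)]
                ),
            )
        )
        pred = predict_prob(f, probe)
        assert (np.diff(pred.probability) > 0).all()
        assert ((pred.probability > 0) & (pred.probability < 1)).all()

    def test_probabilities_and_score_agree_on_within_patient_ranking(self):
        """With candidates that are constant within patient (plus the aneurysm
        characteristics), predicted probabilities and the extracted score
        induce the same within-patient order."""
        cohort = sample_cohort(GeneratorConfig(n_patients=120, seed=23, signal_scale=2.0))
        covs = tuple(ANEURYSM_COVARIATES) + ("age_years", "smoker", "hypertension",
                                             "aneurysms_per_patient")
        cfg = BoostingConfig(use_random_effect=False, candidate_covariates=covs)
        f = fit(cohort, cfg, m_stop=300)
        sc = extract_score(f)
        pred = predict_prob(f, cohort).set_index("aneurysm_id")
        for p in cohort.patients:
            by_score = rank_patient(p, sc).argmax_set
            probs = {a.aneurysm_id: pred.loc[a.aneurysm_id, "probability"] for a in p.aneurysms}
            best = max(probs.values())
            by_prob = {k for k, v in probs.items() if np.isclose(v, best, rtol=0, atol=1e-12)}
            assert by_prob == set(by_score)

    def test_extracted_score_reproduces_training_argmax(self, small_signal_cohort):
        cfg = BoostingConfig(use_random_effect=False,
                             candidate_covariates=tuple(ANEURYSM_COVARIATES))
        f = fit(small_signal_cohort, cfg, m_stop=300)
        sc = extract_score(f)
        pred = predict_prob(f, small_signal_cohort, use_random_effects=False)
        pred = pred.set_index("aneurysm_id")
        for p in small_signal_cohort.patients:
            probs = {a.aneurysm_id: pred.loc[a.aneurysm_id, "probability"] for a in p.aneurysms}
            assert max(probs, key=probs.get) in rank_patient(p, sc).argmax_set

    def test_selection_avoids_outcome_independent_covariate(self):
        """A covariate unrelated to rupture (hypertension, which carries no
        effect in the generator) is selected in a minority of the first 50
        iterations across seeded replicates."""
        frac = []
        for seed in range(4):
            cohort = sample_cohort(
                GeneratorConfig(n_patients=100, seed=seed, truth=size_only_truth(),
                                signal_scale=1.5)
            )
            f = fit(cohort, BoostingConfig(use_random_effect=False), m_stop=50)
            frac.append(sum(s == "hypertension" for s in f.selection_path) / 50)
        assert np.mean(frac) < 0.5
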