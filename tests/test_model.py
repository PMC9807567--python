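"""Normative model: published coefficients, prediction, screening,
interaction testing, equation fitting and the full building procedure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from enhv import (
    ModelInputError,
    NormativeVolumeModel,
    NormativeVolumeResults,
    RoiId,
    build_model,
    fit_equation,
    published_model,
    screen_variables,
    subjects_to_frame,
)
# aliased so pytest does not try to collect the library function
from enhv import test_sex_icv_interaction as sex_icv_interaction
from enhv.model import InteractionResult, RoiModelEquation, ScreeningResult
from enhv.rois import ANALYSIS_ROIS

from conftest import ols_normal_equations

PUBLISHED_FORMS = {
    RoiId.medulla: 1, RoiId.whole_brainstem: 2, RoiId.pons: 2,
    RoiId.midbrain: 2, RoiId.cerebrum: 3,
}


class TestPublishedModel:
    def test_all_five_rois_with_printed_forms(self, published):
        assert set(published.equations) == set(ANALYSIS_ROIS)
        for roi, form in PUBLISHED_FORMS.items():
            assert published.equations[roi].form == form

    def test_printed_coefficients(self, published):
        med = published.equations[RoiId.medulla].coefficients
        assert med == {"a": 1.35e-3, "b": 2.65e3}
        cer = published.equations[RoiId.cerebrum].coefficients
        assert cer["b_m"] == -2.01e3
        wb = published.equations[RoiId.whole_brainstem].coefficients
        assert wb == {"a_f": 3.92e-3, "b_f": 1.80e4, "a_m": 9.50e-3, "b_m": 1.10e4}

    @pytest.mark.parametrize("roi,kwargs,expected", [
        (RoiId.medulla, dict(icv=1.5e6), 4675.0),
        (RoiId.whole_brainstem, dict(icv=1.5e6, sex=1), 25250.0),
        (RoiId.cerebrum, dict(icv=1.5e6, age=30, sex=0), 991800.0),
    ])
    def test_prediction_matches_hand_arithmetic(self, published, roi, kwargs, expected):
        assert published.predict(roi, **kwargs) == pytest.approx(expected, rel=1e-12)

    def test_age_required_for_cerebrum(self, published):
        with pytest.raises(ModelInputError, match="age"):
            published.predict(RoiId.cerebrum, 1.5e6, sex=0)

    def test_sex_must_be_binary(self, published):
        with pytest.raises(ModelInputError, match="sex"):
            published.predict(RoiId.pons, 1.5e6, sex=2)

    def test_monotone_increasing_in_icv(self, published):
        grid = np.linspace(1.0e6, 2.0e6, 30)
        for roi in ANALYSIS_ROIS:
            for sex in (0, 1):
                vals = published.equations[roi].predict(grid, age=40, sex=sex)
                assert np.all(np.diff(vals) > 0), roi

    def test_cerebrum_decreasing_in_age(self, published):
        ages = np.linspace(20, 65, 20)
        for sex in (0, 1):
            vals = published.equations[RoiId.cerebrum].predict(
                np.full_like(ages, 1.5e6), age=ages, sex=sex)
            assert np.all(np.diff(vals) < 0)

    def test_json_round_trip(self, published, tmp_path):
        path = tmp_path / "model.json"
        published.save(path)
        back = NormativeVolumeResults.load(path)
        assert back.equations == published.equations
        assert back.provenance["source"] == "published"


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    a_f=hst.floats(1e-4, 1e-2), b_f=hst.floats(1e3, 3e4),
    a_m=hst.floats(1e-4, 1e-2), b_m=hst.floats(1e3, 3e4),
    icv=hst.floats(1.0e6, 2.0e6),
)
def test_dummy_variable_identity(a_f, b_f, a_m, b_m, icv):
    """Prediction at sex=0 (sex=1) equals the female (male) sub-equation
    evaluated alone, exactly."""
    eq = RoiModelEquation(
        roi=RoiId.pons, form=2,
        coefficients={"a_f": a_f, "b_f": b_f, "a_m": a_m, "b_m": b_m},
    )
    assert eq.predict(icv, sex=0) == a_f * icv + b_f
    assert eq.predict(icv, sex=1) == a_m * icv + b_m


class TestScreening:
    def test_perfect_linearity_gives_r_one(self, healthy_frame):
        frame = healthy_frame.copy()
        frame["pons"] = 2.0 * frame["icv"]
        scr = screen_variables(frame, RoiId.pons)
        assert scr.r_icv == pytest.approx(1.0)
        assert scr.include_icv

    def test_null_age_excluded_at_nominal_rate(self, config):
        """Volumes independent of age: age screened out in ≈95% of draws."""
        from enhv import generate_healthy_cohort

        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            frame = subjects_to_frame(generate_healthy_cohort(config, n=120, seed=500 + rep))
            scr = screen_variables(frame, RoiId.pons)  # no age term generated
            hits += not scr.include_age
        assert hits / n_rep > 0.88  # binomial 95% band around 0.95 at n=100

    def test_age_significant_only_for_cerebrum(self, healthy_frame):
        """Mirrors the study pattern: negative age effect confined to the
        cerebrum, none in the brainstem."""
        scr = screen_variables(healthy_frame, RoiId.cerebrum)
        assert scr.include_age and scr.r_age < 0

    def test_strict_threshold_excludes_p_exactly_at_alpha(self):
        scr = ScreeningResult(roi=RoiId.pons, r_age=0.145, p_age=0.050,
                              r_icv=0.6, p_icv=1e-9)
        assert not scr.include_age  # p = 0.050 is NOT significant

    def test_zero_variance_predictor_rejected(self, healthy_frame):
        frame = healthy_frame.copy()
        frame["age"] = 40.0
        with pytest.raises(ModelInputError, match="age"):
            screen_variables(frame, RoiId.pons)


def _two_line_cohort(n=120, slope_f=2e-3, slope_m=8e-3, noise=100.0, seed=0):
    rng = np.random.default_rng(seed)
    sex = np.repeat([0, 1], n // 2)
    icv = rng.normal(1.5e6, 1.8e5, n)
    slope = np.where(sex == 1, slope_m, slope_f)
    vol = slope * icv + 5000.0 + rng.normal(0, noise, n)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "age": rng.uniform(20, 60, n), "sex": sex, "icv": icv, "pons": vol,
    })


class TestInteraction:
    def test_distinct_slopes_detected(self):
        inter = sex_icv_interaction(_two_line_cohort(), RoiId.pons)
        assert inter.stratify and inter.p < 1e-6

    def test_denominator_df_is_n_minus_4(self):
        frame = _two_line_cohort(n=182)
        inter = sex_icv_interaction(frame, RoiId.pons)
        assert (inter.df_num, inter.df_den) == (1, 178)

    def test_common_line_rarely_flags(self):
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            frame = _two_line_cohort(slope_f=5e-3, slope_m=5e-3,
                                     noise=500.0, seed=1000 + rep)
            hits += not sex_icv_interaction(frame, RoiId.pons).stratify
        assert hits / n_rep > 0.88

    def test_single_sex_cohort_instructs_pooled_fit(self):
        frame = _two_line_cohort()
        frame = frame[frame["sex"] == 1]
        with pytest.raises(ModelInputError, match="pooled"):
            sex_icv_interaction(frame, RoiId.pons)


def _noise_free_frame(published, n=40, seed=0):
    rng = np.random.default_rng(seed)
    sex = np.repeat([0, 1], n // 2)
    icv = rng.uniform(1.2e6, 1.9e6, n)
    age = rng.uniform(20, 65, n)
    frame = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "age": age, "sex": sex, "icv": icv,
    })
    for roi, eq in published.equations.items():
        frame[str(roi)] = eq.predict(icv, age=age, sex=sex)
    return frame


class TestFitEquation:
    def test_noise_free_recovery_of_published_medulla(self, published):
        frame = _noise_free_frame(published)
        scr = ScreeningResult(roi=RoiId.medulla, r_age=0, p_age=1, r_icv=1, p_icv=0)
        inter = InteractionResult(roi=RoiId.medulla, f_stat=0, df_num=1,
                                  df_den=len(frame) - 4, p=1.0)
        eq = fit_equation(frame, RoiId.medulla, scr, inter)
        assert eq.form == 1
        assert eq.coefficients["a"] == pytest.approx(1.35e-3, rel=1e-9)
        assert eq.coefficients["b"] == pytest.approx(2.65e3, rel=1e-9)

    def test_noise_free_recovery_of_form2_whole_brainstem(self, published):
        frame = _noise_free_frame(published)
        scr = ScreeningResult(roi=RoiId.whole_brainstem, r_age=0, p_age=1, r_icv=1, p_icv=0)
        inter = InteractionResult(roi=RoiId.whole_brainstem, f_stat=100, df_num=1,
                                  df_den=len(frame) - 4, p=1e-12)
        eq = fit_equation(frame, RoiId.whole_brainstem, scr, inter)
        assert eq.form == 2
        for key, truth in published.equations[RoiId.whole_brainstem].coefficients.items():
            assert eq.coefficients[key] == pytest.approx(truth, rel=1e-9)

    def test_identical_slopes_collapse_to_pooled_form1(self):
        frame = _two_line_cohort(slope_f=4e-3, slope_m=4e-3, noise=0.0)
        scr = ScreeningResult(roi=RoiId.pons, r_age=0, p_age=1, r_icv=1, p_icv=0)
        inter = InteractionResult(roi=RoiId.pons, f_stat=0, df_num=1,
                                  df_den=len(frame) - 4, p=1.0)
        eq = fit_equation(frame, RoiId.pons, scr, inter)
        assert eq.form == 1
        assert eq.coefficients["a"] == pytest.approx(4e-3, rel=1e-9)

    def test_nonsignificant_icv_warns_but_is_retained(self, healthy_frame):
        scr = ScreeningResult(roi=RoiId.pons, r_age=0, p_age=1, r_icv=0.01, p_icv=0.9)
        inter = InteractionResult(roi=RoiId.pons, f_stat=0, df_num=1,
                                  df_den=len(healthy_frame) - 4, p=1.0)
        with pytest.warns(UserWarning, match="ICV retained"):
            eq = fit_equation(healthy_frame, RoiId.pons, scr, inter)
        assert "a" in eq.coefficients

    def test_ols_matches_normal_equations_oracle(self):
        """OLS agrees with the closed-form normal-equations solution on
        small instances."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(5, 11))
            icv = rng.uniform(1.2e6, 1.9e6, n)
            vol = rng.uniform(4e3, 3e4, n)
            frame = pd.DataFrame({
                "subject_id": [f"s{i}" for i in range(n)],
                "age": rng.uniform(20, 60, n),
                "sex": np.zeros(n, dtype=int), "icv": icv, "medulla": vol,
            })
            scr = ScreeningResult(roi=RoiId.medulla, r_age=0, p_age=1, r_icv=1, p_icv=0)
            eq = fit_equation(frame, RoiId.medulla, scr, None)
            a_ref, b_ref = ols_normal_equations(vol, icv)
            assert eq.coefficients["a"] == pytest.approx(a_ref, rel=1e-9)
            assert eq.coefficients["b"] == pytest.approx(b_ref, rel=1e-9)


class TestBuildModel:
    def test_noise_free_cohort_recovers_every_coefficient(self, published, config):
        """Generator at zero residual noise -> exact OLS recovery, with the
        published decision path forced by the structure of the data."""
        from enhv import generate_healthy_cohort

        # vanishing (not exactly zero) noise: a perfect fit makes the
        # medulla interaction F-test a degenerate 0/0
        cfg = config.model_copy(update={
            "residual_sd": {str(r): 1e-6 for r in ANALYSIS_ROIS}})
        frame = subjects_to_frame(generate_healthy_cohort(cfg, n=182, seed=21))
        res = build_model(frame)
        for roi, eq in published.equations.items():
            got = res.equations[roi]
            assert got.form == eq.form
            for key, truth in eq.coefficients.items():
                assert got.coefficients[key] == pytest.approx(truth, rel=1e-9)

    def test_provenance_records_every_decision(self, healthy_frame):
        res = build_model(healthy_frame)
        prov = res.provenance
        assert prov["source"] == "fitted"
        assert prov["n"] == len(healthy_frame)
        assert set(prov["screening"]) == {str(r) for r in ANALYSIS_ROIS}
        assert set(prov["interaction"]) == {str(r) for r in ANALYSIS_ROIS}
        for rec in prov["interaction"].values():
            assert rec["df"] == [1, len(healthy_frame) - 4]

    def test_single_sex_cohort_falls_back_to_form1_with_warning(self, healthy_frame):
        frame = healthy_frame[healthy_frame["sex"] == 1]
        with pytest.warns(UserWarning, match="single sex"):
            res = NormativeVolumeModel(frame).fit()
        assert all(eq.form == 1 for eq in res.equations.values())

    def test_deterministic_given_cohort(self, healthy_frame):
        r1 = build_model(healthy_frame)
        r2 = build_model(healthy_frame)
        assert r1.equations == r2.equations

    def test_summary_mentions_fit_size_and_forms(self, healthy_frame):
        text = build_model(healthy_frame).summary()
        assert "n=182" in text
        assert "cerebrum" in text and "sex x ICV" in text
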