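"""Cross-validation hygiene, longitudinal delta-age behaviour, and the
age-adjusted association estimators."""

import numpy as np
import pandas as pd
import pytest

from metaboclock.evaluation import (
    CvScheme,
    associate_biomarker,
    associate_incident,
    associate_risk_factor,
    cross_validate,
    delta_age,
    sensitivity_adjust_bmi,
)
from metaboclock.synthetic import CohortSpec, simulate_study, simulate_survival

from conftest import make_single_cohort


def _oracle_fitter(tr_mets, tr_samples):
    ages = tr_samples["age"]  # noqa: F841 — the oracle ignores training
    def predict_fn(mm):
        return mm.attrs["true_age"].loc[mm.index].to_numpy()
    return predict_fn


@pytest.fixture(scope="module")
def multi_cohort():
    model = make_single_cohort(slope=0.3, p=4)[1]
    specs = [
        CohortSpec("a", 120, (30, 60)),
        CohortSpec("b", 120, (40, 70)),
        CohortSpec("c", 120, (35, 65), visit_gaps=(5.0,)),
        CohortSpec("d", 120, (30, 70)),
        CohortSpec("e", 120, (45, 75)),
    ]
    samples, mets, _ = simulate_study(specs, model, seed=40)
    mets.attrs["true_age"] = samples["age"].astype(float)
    return samples, mets


class TestCrossValidate:
    def test_oracle_predictor_is_perfect(self, multi_cohort):
        samples, mets = multi_cohort
        oof, rep = cross_validate(_oracle_fitter, mets, samples,
                                  CvScheme("kfold", 7), seed=0)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.mae == pytest.approx(0.0, abs=1e-12)
        assert oof["predicted_age"].notna().all()
        assert CvScheme("kfold").k == 7

    def test_every_sample_predicted_once_per_scheme(self, multi_cohort):
        samples, mets = multi_cohort
        oof, _ = cross_validate(_oracle_fitter, mets, samples,
                                CvScheme("kfold", 7), seed=1)
        assert sorted(oof["fold"].unique()) == [f"fold{i}" for i in range(7)]
        # subjects never straddle folds
        per_subject = oof.join(samples["subject_id"]).groupby("subject_id")["fold"].nunique()
        assert (per_subject == 1).all()

    def test_loco_fold_structure(self, multi_cohort):
        samples, mets = multi_cohort
        oof, rep = cross_validate(_oracle_fitter, mets, samples,
                                  CvScheme("loco"), seed=0)
        assert sorted(oof["fold"].unique()) == sorted(samples["cohort"].unique())
        for cohort, grp in oof.groupby("fold"):
            assert (grp["cohort"] == cohort).all()
        assert set(rep.per_cohort) == set(samples["cohort"].unique())

    def test_report_matches_independent_recomputation(self, multi_cohort):
        samples, mets = multi_cohort

        def noisy_fitter(tr_mets, tr_samples):
            rng = np.random.default_rng(5)
            return lambda mm: (mm.attrs["true_age"].loc[mm.index].to_numpy()
                               + rng.normal(0, 5, len(mm)))

        mets2 = mets.copy()
        mets2.attrs["true_age"] = samples["age"].astype(float)
        oof, rep = cross_validate(noisy_fitter, mets2, samples,
                                  CvScheme("kfold", 5), seed=2)
        r = np.corrcoef(oof["age"], oof["predicted_age"])[0, 1]
        mae = (oof["age"] - oof["predicted_age"]).abs().mean()
        assert rep.pearson_r == pytest.approx(r)
        assert rep.mae == pytest.approx(mae)

    def test_loco_needs_two_cohorts(self):
        model = make_single_cohort()[1]
        samples, mets, _ = simulate_study([CohortSpec("only", 50, (30, 60))],
                                          model, seed=0)
        with pytest.raises(ValueError, match="two cohorts"):
            cross_validate(_oracle_fitter, mets, samples, CvScheme("loco"))


class TestDeltaAge:
    def _repeat_study(self, n=1000, gap=6.0, seed=50):
        spec = CohortSpec("rv", n, (30, 60), visit_gaps=(gap,))
        model = make_single_cohort()[1]
        samples, mets, _ = simulate_study([spec], model, seed=seed)
        return samples, mets

    def test_identical_predictions_give_zero_delta(self):
        samples, _ = self._repeat_study(n=50)
        preds = pd.Series(55.0, index=samples.index)
        pairs, _, _ = delta_age(preds, samples)
        assert (pairs["delta_predicted"] == 0).all()

    def test_perfect_clock_tracks_delta_ca(self):
        samples, _ = self._repeat_study(n=50)
        preds = samples["age"].astype(float)
        pairs, summary, r = delta_age(preds, samples)
        np.testing.assert_allclose(pairs["delta_predicted"], pairs["delta_ca"])
        assert summary.loc[summary["interval"] == 6, "median"].iloc[0] == pytest.approx(6.0)

    def test_attenuated_clock_recovers_planted_slope(self):
        """Clock = 0.6*age + noise: the delta-pred on delta-CA slope is 0.6."""
        rng = np.random.default_rng(51)
        # variable gaps so delta CA varies
        frames = []
        for gap, seed in [(4.0, 1), (6.0, 2), (8.0, 3)]:
            spec = CohortSpec(f"g{int(gap)}", 340, (30, 60), visit_gaps=(gap,))
            model = make_single_cohort()[1]
            s, _, _ = simulate_study([spec], model, seed=seed)
            frames.append(s)
        samples = pd.concat(frames)
        preds = pd.Series(
            0.6 * samples["age"].to_numpy() + rng.normal(0, 2.0, len(samples)),
            index=samples.index,
        )
        pairs, _, _ = delta_age(preds, samples)
        slope = np.polyfit(pairs["delta_ca"], pairs["delta_predicted"], 1)[0]
        assert 0.5 <= slope <= 0.7

    def test_no_repeats_warns_and_returns_empty(self, caplog):
        spec = CohortSpec("once", 30, (30, 60))
        model = make_single_cohort()[1]
        samples, _, _ = simulate_study([spec], model, seed=0)
        preds = pd.Series(50.0, index=samples.index)
        with caplog.at_level("WARNING"):
            pairs, summary, r = delta_age(preds, samples)
        assert pairs.empty and np.isnan(r)


@pytest.fixture(scope="module")
def assoc_study():
    """Study with a planted binary exposure effect on the clock driver."""
    rng = np.random.default_rng(60)
    n = 5000
    idx = [f"s{i}" for i in range(n)]
    age = rng.uniform(35, 75, n)
    exposure = rng.integers(0, 2, n)
    driver = 0.5 * age + 0.0 * exposure + rng.normal(0, 5, n)
    samples = pd.DataFrame({
        "subject_id": idx, "cohort": np.where(np.arange(n) % 2 == 0, "c1", "c2"),
        "visit": 0, "age": age, "sex": rng.integers(0, 2, n),
        "bmi": rng.normal(27, 4, n), "ethnicity": rng.integers(0, 2, n),
        "exposed": exposure,
    }, index=idx)
    # clock score in years: driven by the metabolite, hence by age
    clock = pd.Series(driver / 0.5 + rng.normal(0, 4, n), index=idx)
    return samples, clock, exposure


class TestAssociations:
    def test_planted_exposure_effect_detected(self):
        rng = np.random.default_rng(61)
        n = 5000
        idx = [f"s{i}" for i in range(n)]
        age = rng.uniform(35, 75, n)
        exposure = rng.integers(0, 2, n)
        samples = pd.DataFrame({
            "subject_id": idx, "cohort": "c1", "visit": 0, "age": age,
            "sex": rng.integers(0, 2, n), "bmi": rng.normal(27, 4, n),
            "ethnicity": rng.integers(0, 2, n), "exposed": exposure,
        }, index=idx)
        clock = pd.Series(age + 3.0 * exposure + rng.normal(0, 8, n), index=idx)
        a = associate_risk_factor(clock, samples, "exposed")
        assert a.estimate > 0
        assert a.p < 0.001

    def test_null_exposure_calibrated(self, assoc_study):
        samples, clock, _ = assoc_study
        a = associate_risk_factor(clock, samples, "exposed")
        assert abs(a.estimate) < 3 * a.se

    def test_constant_exposure_errors(self, assoc_study):
        samples, clock, _ = assoc_study
        s2 = samples.copy()
        s2["exposed"] = 1
        with pytest.raises(ValueError, match="constant"):
            associate_risk_factor(clock, s2, "exposed")

    def test_biomarker_identity_after_scaling(self, assoc_study):
        samples, clock, _ = assoc_study
        s2 = samples.copy()
        s2["marker"] = clock
        # adjusting only for independent covariates keeps the identity
        a = associate_biomarker(clock, s2, "marker", covariates=("sex", "ethnicity"))
        assert a.estimate == pytest.approx(1.0, abs=0.01)

    def test_biomarker_sign_follows_construction(self, assoc_study):
        samples, clock, _ = assoc_study
        rng = np.random.default_rng(62)
        s2 = samples.copy()
        s2["marker"] = -0.8 * clock + rng.normal(0, clock.std() / 2, len(clock))
        a = associate_biomarker(clock, s2, "marker", covariates=("sex", "ethnicity"))
        assert a.estimate < 0

    def test_independent_biomarker_null(self, assoc_study):
        samples, clock, _ = assoc_study
        rng = np.random.default_rng(63)
        s2 = samples.copy()
        s2["marker"] = rng.normal(size=len(clock))
        a = associate_biomarker(clock, s2, "marker")
        assert abs(a.estimate) < 3 * a.se


class TestAssociateIncident:
    def _survival_frame(self, hr_per_year=0.0, n=3000, seed=70):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        age = rng.uniform(40, 70, n)
        clock = pd.Series(age + rng.normal(0, 8, n), index=idx)
        eta = hr_per_year * (clock.to_numpy() - clock.mean())
        t = 30.0 * (rng.exponential(size=n) / np.exp(eta)) ** (1 / 1.4)
        samples = pd.DataFrame({
            "subject_id": idx, "cohort": np.where(np.arange(n) % 2 == 0, "c1", "c2"),
            "visit": 0, "age": age, "sex": rng.integers(0, 2, n),
            "bmi": rng.normal(27, 4, n), "ethnicity": rng.integers(0, 2, n),
            "time": np.minimum(t, 15.0), "event": (t <= 15.0).astype(int),
        }, index=idx)
        return samples, clock

    def test_planted_hazard_recovered_as_hr_per_year(self):
        samples, clock = self._survival_frame(hr_per_year=0.05)
        a = associate_incident(clock, samples, covariates=("sex",))
        assert a.pooled
        assert np.exp(a.estimate) == pytest.approx(np.exp(0.05), abs=0.02)
        assert a.p < 0.001

    def test_null_clock_covers_hr_one(self):
        hits = 0
        for rep in range(30):
            samples, clock = self._survival_frame(hr_per_year=0.0, n=800,
                                                  seed=100 + rep)
            a = associate_incident(clock, samples, covariates=("sex",))
            lo, hi = a.ci95
            if lo <= 0.0 <= hi:
                hits += 1
        assert hits >= 24  # ~95% nominal with binomial slack at 30 reps

    def test_collinear_clock_rejected(self):
        samples, clock = self._survival_frame()
        with pytest.raises(ValueError, match="collinear"):
            associate_incident(samples["age"].astype(float) * 1.0000001, samples)

    def test_eventless_cohort_skipped(self, caplog):
        samples, clock = self._survival_frame(n=600)
        samples.loc[samples["cohort"] == "c2", "event"] = 0
        with caplog.at_level("WARNING"):
            a = associate_incident(clock, samples, covariates=("sex",))
        assert "no events" in caplog.text
        assert a.n_events == int(samples.loc[samples["cohort"] == "c1", "event"].sum())


class TestSensitivityAdjustBmi:
    def test_irrelevant_bmi_is_stable(self, assoc_study):
        samples, clock, _ = assoc_study
        base = associate_risk_factor(clock, samples, "exposed")
        adj = sensitivity_adjust_bmi(associate_risk_factor, clock, samples,
                                     "exposed")
        assert "bmi" in adj.adjusted_for
        assert abs(base.estimate - adj.estimate) < 2 * base.se

    def test_mediation_attenuates(self):
        rng = np.random.default_rng(64)
        n = 4000
        idx = [f"s{i}" for i in range(n)]
        exposure = rng.integers(0, 2, n)
        bmi = 25 + 4 * exposure + rng.normal(0, 2, n)  # exposure raises BMI
        age = rng.uniform(40, 70, n)
        clock = pd.Series(age + 1.0 * bmi + rng.normal(0, 6, n), index=idx)
        samples = pd.DataFrame({
            "subject_id": idx, "cohort": "c1", "visit": 0, "age": age,
            "sex": rng.integers(0, 2, n), "bmi": bmi,
            "ethnicity": rng.integers(0, 2, n), "exposed": exposure,
        }, index=idx)
        base = associate_risk_factor(clock, samples, "exposed")
        adj = sensitivity_adjust_bmi(associate_risk_factor, clock, samples,
                                     "exposed")
        assert abs(adj.estimate) < abs(base.estimate)

    def test_error_propagates(self, assoc_study):
        samples, clock, _ = assoc_study
        s2 = samples.copy()
        s2["exposed"] = 0
        with pytest.raises(ValueError, match="constant"):
            sensitivity_adjust_bmi(associate_risk_factor, clock, s2, "exposed")


def test_dedupe_keeps_earliest_visit():
    spec = CohortSpec("rv", 40, (30, 60), visit_gaps=(5.0,))
    model = make_single_cohort(slope=0.2)[1]
    samples, mets, _ = simulate_study([spec], model, seed=80)
    rng = np.random.default_rng(80)
    samples["exposed"] = np.repeat(rng.integers(0, 2, 40), 1)[
        samples.groupby("subject_id").ngroup()]
    clock = samples["age"].astype(float) + rng.normal(0, 5, len(samples))
    a = associate_risk_factor(clock, samples, "exposed")
    assert a.n == 40  # one row per subject
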