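"""Association-study contracts: stratified OLS and Cox fits, fixed-effect
pooling closed forms, heterogeneity, BH-FDR, and concordance labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaboclock.mwas import (
    AssocResult,
    DEFAULT_AGE_BANDS,
    bh_fdr,
    classify_concordance,
    fixed_effect_meta,
    mwas_age,
    mwas_age_stratified,
    mwas_mortality,
)
from metaboclock.synthetic import (
    CohortSpec,
    MetaboliteModel,
    simulate_study,
    simulate_survival,
)

from conftest import make_single_cohort


def _frame(n, seed, age_effect=0.0, sex_confounded=False):
    rng = np.random.default_rng(seed)
    age = rng.uniform(30, 70, n)
    sex = rng.integers(0, 2, n)
    if sex_confounded:
        age = age + 6 * sex  # sex shifts both age and the metabolite
    samples = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "cohort": "c1",
            "visit": 0,
            "age": age,
            "sex": sex,
            "bmi": rng.normal(27, 4, n),
            "ethnicity": rng.integers(0, 2, n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    met = age_effect * age + (2.0 * sex if sex_confounded else 0) + rng.normal(0, 1, n)
    mets = pd.DataFrame({"m0": met}, index=samples.index)
    return samples, mets


class TestMwasAge:
    def test_type_one_error_calibration(self):
        """Across 1000 simulated null metabolites the p < 0.05 fraction is
        within binomial noise of 0.05."""
        rng = np.random.default_rng(0)
        n = 60
        samples, _ = _frame(n, 1)
        mets = pd.DataFrame(
            rng.normal(0, 1, size=(n, 1000)),
            index=samples.index,
            columns=[f"null{i}" for i in range(1000)],
        )
        res = mwas_age(mets, samples)
        frac = np.mean([r.p < 0.05 for r in res])
        assert 0.035 <= frac <= 0.065

    def test_adjusted_recovery_under_confounding(self):
        hits = 0
        for rep in range(100):
            samples, mets = _frame(400, 100 + rep, age_effect=0.5,
                                   sex_confounded=True)
            r = mwas_age(mets, samples)[0]
            if abs(r.estimate - 0.5) <= 1.96 * r.se:
                hits += 1
        assert hits >= 93

    def test_constant_age_cohort_skipped(self, caplog):
        spec = CohortSpec("birth", 50, (46, 46))
        model = make_single_cohort()[1]
        samples, mets, _ = simulate_study([spec], model, seed=0)
        with caplog.at_level("WARNING"):
            res = mwas_age(mets, samples)
        assert res == []
        assert "constant age" in caplog.text


class TestMwasAgeStratified:
    def test_planted_curvature_flips_sign_across_centre(self):
        # slope +s below 60, -s above: quadratic with negative curvature
        # centred at 60
        names = ["m0"]
        model = MetaboliteModel(
            names=names, base_mean=[200.0], base_sd=[2.0],
            age_slope=[0.0], age_curvature=[-0.05], curvature_center=60.0,
        )
        spec = CohortSpec("wide", 4000, (30, 86))
        samples, mets, _ = simulate_study([spec], model, seed=3)
        res = mwas_age_stratified(mets, samples, covariates=("sex", "bmi"))
        est = {r.stratum: r.estimate for r in res}
        assert est["40-45"] > 0
        assert est[">70"] < 0

    def test_single_band_reduces_to_pooled_mwas_with_cohort(self):
        model = make_single_cohort(slope=0.3)[1]
        specs = [CohortSpec("a", 300, (30, 70)), CohortSpec("b", 300, (30, 70))]
        samples, mets, _ = simulate_study(specs, model, seed=4)
        band = mwas_age_stratified(mets, samples, age_bands=[(18, None)])
        assert len(band) == len(mets.columns)
        # matches a direct pooled OLS with cohort dummy
        import statsmodels.api as sm

        X = pd.DataFrame({
            "age": samples["age"].astype(float),
            "sex": samples["sex"].astype(float),
            "bmi": samples["bmi"].astype(float),
            "ethnicity": samples["ethnicity"].astype(float),
            "cohort_b": (samples["cohort"] == "b").astype(float),
        })
        fit = sm.OLS(mets["m0"], sm.add_constant(X)).fit()
        r0 = next(r for r in band if r.metabolite == "m0")
        assert r0.estimate == pytest.approx(float(fit.params["age"]), rel=1e-9)

    def test_default_bands(self):
        assert DEFAULT_AGE_BANDS[0] == (20, 35)
        assert DEFAULT_AGE_BANDS[-1] == (70, None)
        assert all(b[1] == DEFAULT_AGE_BANDS[i + 1][0]
                   for i, b in enumerate(DEFAULT_AGE_BANDS[:-1]))


class TestMwasMortality:
    def test_planted_loghr_recovered(self):
        """Single hazardous metabolite: pooled per-SD log-HR covers the
        planted 0.3 over seeded replicates at roughly the nominal rate."""
        hits = 0
        reps = 40
        for rep in range(reps):
            spec, model = make_single_cohort(
                n=800, p=2, log_hazard=np.array([0.3, 0.0]), seed=rep,
            )
            samples, mets, _ = simulate_study([spec], model, seed=300 + rep)
            samples = simulate_survival(samples, mets, model, (1.4, 25.0),
                                        12.0, seed=300 + rep)
            res = [r for r in mwas_mortality(mets, samples) if r.metabolite == "m0"]
            pooled = fixed_effect_meta(res)[0]
            if abs(pooled.pooled_estimate - 0.3) <= 1.96 * pooled.pooled_se:
                hits += 1
        assert hits >= int(0.80 * reps)  # >= 93% nominal, binomial slack at 40 reps

    def test_all_censored_cohort_skipped(self, caplog):
        spec, model = make_single_cohort(n=50, log_hazard=np.zeros(4))
        samples, mets, _ = simulate_study([spec], model, seed=5)
        samples = simulate_survival(samples, mets, model, (1.4, 25.0), 0.001, seed=5)
        with caplog.at_level("WARNING"):
            res = mwas_mortality(mets, samples)
        assert res == []
        assert "skipped" in caplog.text


class TestFixedEffectMeta:
    def test_homogeneous_strata(self):
        rs = [AssocResult("m", f"s{i}", 0.3, 0.1, 0.01, 100) for i in range(4)]
        meta = fixed_effect_meta(rs)[0]
        assert meta.pooled_estimate == pytest.approx(0.3)
        assert meta.pooled_se == pytest.approx(0.05)
        assert meta.Q == pytest.approx(0.0, abs=1e-12)
        assert meta.I2 == 0.0
        assert meta.k == 4

    def test_two_strata_closed_form(self):
        rs = [AssocResult("m", "a", 1.0, 1.0, 0.3, 50),
              AssocResult("m", "b", 3.0, 1.0, 0.3, 50)]
        meta = fixed_effect_meta(rs)[0]
        assert meta.pooled_estimate == pytest.approx(2.0)
        assert meta.pooled_se == pytest.approx(1 / np.sqrt(2))
        assert meta.Q == pytest.approx(2.0)
        assert meta.I2 == pytest.approx((2 - 1) / 2)

    def test_single_stratum_identity(self):
        rs = [AssocResult("m", "a", 0.7, 0.2, 0.0005, 80)]
        meta = fixed_effect_meta(rs)[0]
        assert meta.pooled_estimate == pytest.approx(0.7)
        assert meta.pooled_se == pytest.approx(0.2)
        assert meta.k == 1

    def test_pooled_se_never_exceeds_min_stratum_se(self):
        rng = np.random.default_rng(2)
        rs = [AssocResult("m", f"s{i}", rng.normal(), float(rng.uniform(0.05, 2)),
                          0.5, 30) for i in range(6)]
        meta = fixed_effect_meta(rs)[0]
        assert meta.pooled_se < min(r.se for r in rs)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(3)
        rs = [AssocResult(f"m{j}", "a", rng.normal(), 0.5, 0.5, 30)
              for j in range(20)]
        for meta in fixed_effect_meta(rs):
            assert meta.q >= meta.p


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_singleton_and_ties(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_permutation_invariance_and_monotonicity(self, ps):
        q = bh_fdr(ps)
        perm = np.random.default_rng(0).permutation(len(ps))
        q_perm = bh_fdr(list(np.array(ps)[perm]))
        np.testing.assert_allclose(q_perm, q[perm])
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q > 0) & (q <= 1)).all()

    def test_global_null_fdr_controlled(self):
        rng = np.random.default_rng(4)
        # 1000 null z-test p-values
        from scipy import stats

        p = 2 * stats.norm.sf(np.abs(rng.standard_normal(1000)))
        frac = np.mean(bh_fdr(p) < 0.05)
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        assert bh_fdr([]).size == 0


class TestConcordance:
    def _meta(self, met, est, q):
        from metaboclock.mwas import MetaResult

        return MetaResult(met, est, 0.1, 0.001, q, 0.0, 0.0, 3)

    def test_sign_rules(self):
        age = [self._meta("up_up", 0.5, 0.01), self._meta("up_down", 0.5, 0.01),
               self._meta("ns", 0.5, 0.5)]
        mort = [self._meta("up_up", 0.2, 0.01), self._meta("up_down", -0.2, 0.01),
                self._meta("ns", 0.2, 0.01)]
        labels = {c.metabolite: c for c in classify_concordance(age, mort)}
        assert labels["up_up"].concordant
        assert not labels["up_down"].concordant
        assert "ns" not in labels  # q >= 0.05 in the age analysis
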