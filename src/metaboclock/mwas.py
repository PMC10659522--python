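"""Metabolome-wide association of age and mortality with fixed-effect
meta-analysis, FDR, heterogeneity, and age/mortality concordance labels.

Age associations are ordinary least squares of each metabolite on age within
a stratum (cohort, or age band pooled over cohorts), adjusted for sex, BMI
and ethnicity (plus cohort for age-band strata). Mortality associations are
per-cohort Cox proportional-hazards fits of time-to-death on the
standardized metabolite (log-HR per SD), adjusted for age, sex and BMI.
Stratum estimates are pooled by inverse-variance fixed-effect meta-analysis
with Cochran's Q and I^2; Benjamini-Hochberg FDR across metabolites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_AGE_BANDS = [(20, 35), (35, 40), (40, 45), (45, 50), (50, 55),
                     (55, 60), (60, 65), (65, 70), (70, None)]

__all__ = [
    "AssocResult",
    "MetaResult",
    "ConcordanceLabel",
    "DEFAULT_AGE_BANDS",
    "mwas_age",
    "mwas_age_stratified",
    "mwas_mortality",
    "fixed_effect_meta",
    "bh_fdr",
    "classify_concordance",
    "assoc_to_frame",
    "meta_to_frame",
]


@dataclass
class AssocResult:
    metabolite: str
    stratum: str
    estimate: float
    se: float
    p: float
    n: int
    n_events: int | None = None


@dataclass
class MetaResult:
    metabolite: str
    pooled_estimate: float
    pooled_se: float
    p: float
    q: float
    Q: float
    I2: float
    k: int


@dataclass
class ConcordanceLabel:
    metabolite: str
    age_sign: int
    mortality_sign: int

    @property
    def concordant(self) -> bool:
        return self.age_sign * self.mortality_sign > 0


def _design(meta: pd.DataFrame, covariates: list[str], stratum: str) -> pd.DataFrame:
    """Covariate design with intercept; drops covariates that are constant or
    collinear within the stratum (e.g. sex in a single-sex cohort)."""
    cols = {}
    for c in covariates:
        if c == "cohort":
            d = pd.get_dummies(meta["cohort"], prefix="cohort", drop_first=True, dtype=float)
            for name in d.columns:
                cols[name] = d[name]
        else:
            cols[c] = meta[c].astype(float)
    X = pd.DataFrame(cols, index=meta.index)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        logger.warning("stratum %s: dropping constant covariate(s) %s", stratum, dropped)
        X = X.drop(columns=dropped)
    return sm.add_constant(X, has_constant="add")


def mwas_age(
    mets: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "bmi", "ethnicity"),
    standardize: bool = False,
) -> list[AssocResult]:
    """Cohort-stratified OLS of each metabolite on age plus covariates.

    Strata with constant age (birth cohorts) are skipped with a warning.
    With ``standardize`` the metabolite is z-scored within the stratum so
    coefficients are SD per year rather than concentration units per year.
    """
    meta = samples.loc[mets.index]
    out: list[AssocResult] = []
    for cohort, idx in meta.groupby("cohort").groups.items():
        sub = meta.loc[idx]
        if sub["age"].nunique() <= 1:
            logger.warning("cohort %s has constant age; skipped from age MWAS", cohort)
            continue
        X = _design(sub, list(covariates), str(cohort))
        X.insert(1, "age", sub["age"].astype(float))
        for m in mets.columns:
            y = mets.loc[idx, m].astype(float)
            if standardize:
                y = (y - y.mean()) / y.std(ddof=0)
            fit = sm.OLS(y, X, missing="drop").fit()
            out.append(
                AssocResult(
                    metabolite=m,
                    stratum=str(cohort),
                    estimate=float(fit.params["age"]),
                    se=float(fit.bse["age"]),
                    p=float(fit.pvalues["age"]),
                    n=int(fit.nobs),
                )
            )
    return out


def mwas_age_stratified(
    mets: pd.DataFrame,
    samples: pd.DataFrame,
    age_bands: list[tuple[float, float | None]] | None = None,
    covariates: tuple[str, ...] = ("sex", "bmi", "ethnicity", "cohort"),
    standardize: bool = False,
) -> list[AssocResult]:
    """Age-band-stratified MWAS of age, pooled across cohorts with cohort as
    an additional categorical covariate. The final band is open-ended."""
    bands = age_bands if age_bands is not None else DEFAULT_AGE_BANDS
    meta = samples.loc[mets.index]
    out: list[AssocResult] = []
    for lo, hi in bands:
        label = f"{lo:g}-{hi:g}" if hi is not None else f">{lo:g}"
        mask = (meta["age"] >= lo) & ((meta["age"] < hi) if hi is not None else True)
        sub = meta.loc[mask]
        if len(sub) < len(covariates) + 3 or sub["age"].nunique() <= 1:
            logger.warning("age band %s too small or degenerate; skipped", label)
            continue
        X = _design(sub, list(covariates), label)
        X.insert(1, "age", sub["age"].astype(float))
        for m in mets.columns:
            y = mets.loc[sub.index, m].astype(float)
            if standardize:
                y = (y - y.mean()) / y.std(ddof=0)
            fit = sm.OLS(y, X, missing="drop").fit()
            out.append(
                AssocResult(m, label, float(fit.params["age"]),
                            float(fit.bse["age"]), float(fit.pvalues["age"]),
                            int(fit.nobs))
            )
    return out


def mwas_mortality(
    mets: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "bmi"),
    min_events: int = 10,
) -> list[AssocResult]:
    """Per-cohort Cox MWAS of all-cause mortality.

    Each metabolite is standardized within the analysis sample so the
    estimate is a log hazard ratio per SD. Cohorts with fewer than
    ``min_events`` events are skipped with a warning.
    """
    meta = samples.loc[mets.index]
    if (meta["time"] <= 0).any():
        raise ValueError("all survival times must be > 0")
    out: list[AssocResult] = []
    for cohort, idx in meta.groupby("cohort").groups.items():
        sub = meta.loc[idx]
        n_events = int(sub["event"].sum())
        if n_events < min_events:
            logger.warning(
                "cohort %s has %d events (< %d); skipped from mortality MWAS",
                cohort, n_events, min_events,
            )
            continue
        covs = pd.DataFrame(
            {c: sub[c].astype(float) for c in covariates}, index=sub.index
        )
        covs = covs.loc[:, covs.nunique() > 1]
        for m in mets.columns:
            x = mets.loc[idx, m].astype(float)
            z = (x - x.mean()) / x.std(ddof=0)
            df = covs.copy()
            df["met_z"] = z
            df["time"] = sub["time"].astype(float)
            df["event"] = sub["event"].astype(int)
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            out.append(
                AssocResult(
                    metabolite=m,
                    stratum=str(cohort),
                    estimate=float(cph.params_["met_z"]),
                    se=float(cph.standard_errors_["met_z"]),
                    p=float(cph.summary.loc["met_z", "p"]),
                    n=len(df),
                    n_events=n_events,
                )
            )
    return out


def fixed_effect_meta(results: list[AssocResult]) -> list[MetaResult]:
    """Inverse-variance fixed-effect pooling per metabolite.

    pooled = sum(w_i b_i)/sum(w_i), w_i = 1/se_i^2; pooled se = sum(w_i)^-1/2;
    Q = sum w_i (b_i - pooled)^2; I^2 = max(0, (Q - (k-1))/Q); two-sided
    normal p. FDR q-values are attached across metabolites.
    """
    by_met: dict[str, list[AssocResult]] = {}
    for r in results:
        if r.se <= 0:
            raise ValueError(f"{r.metabolite}/{r.stratum}: se must be > 0")
        by_met.setdefault(r.metabolite, []).append(r)

    out: list[MetaResult] = []
    for m, rs in by_met.items():
        b = np.array([r.estimate for r in rs])
        w = np.array([1.0 / r.se**2 for r in rs])
        pooled = float(w @ b / w.sum())
        se = float(w.sum() ** -0.5)
        q_stat = float(w @ (b - pooled) ** 2)
        k = len(rs)
        i2 = max(0.0, (q_stat - (k - 1)) / q_stat) if q_stat > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(pooled / se)))
        out.append(MetaResult(m, pooled, se, max(p, np.finfo(float).tiny),
                              np.nan, q_stat, i2, k))
    qs = bh_fdr([r.p for r in out])
    for r, q in zip(out, qs):
        r.q = float(q)
    return out


def bh_fdr(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_concordance(
    age_meta: list[MetaResult],
    mort_meta: list[MetaResult],
    q_threshold: float = 0.05,
) -> list[ConcordanceLabel]:
    """Direction-concordance labels for metabolites significant (FDR q below
    threshold) in both the age and the mortality meta-analysis."""
    age = {r.metabolite: r for r in age_meta}
    mort = {r.metabolite: r for r in mort_meta}
    out = []
    for m in sorted(set(age) & set(mort)):
        if age[m].q < q_threshold and mort[m].q < q_threshold:
            out.append(
                ConcordanceLabel(
                    m,
                    int(np.sign(age[m].pooled_estimate)),
                    int(np.sign(mort[m].pooled_estimate)),
                )
            )
    return out


def assoc_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": r.metabolite, "stratum": r.stratum,
                "estimate": r.estimate, "se": r.se, "p": r.p,
                "n": r.n, "n_events": r.n_events,
            }
            for r in results
        ]
    )


def meta_to_frame(results: list[MetaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": r.metabolite, "pooled_estimate": r.pooled_estimate,
                "pooled_se": r.pooled_se, "p": r.p, "q": r.q,
                "Q": r.Q, "I2": r.I2, "k": r.k,
            }
            for r in results
        ]
    )
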