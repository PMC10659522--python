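"""Model evaluation: grouped cross-validation (7-fold and leave-one-cohort-
out), longitudinal delta-age checks, and chronological-age-adjusted
association of clock scores with binary risk factors, scaled biomarkers and
incident events (per-cohort Cox pooled by fixed-effect meta-analysis).

Subjects — not samples — are the cross-validation unit: all samples of a
subject share a fold, so repeat visits can never leak between training and
test. Because association models adjust for chronological age, estimates
read as effects of age acceleration (years of metabolomic age beyond CA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from .mwas import AssocResult, fixed_effect_meta

logger = logging.getLogger(__name__)

__all__ = [
    "CvScheme",
    "PerformanceReport",
    "AssociationEstimate",
    "cross_validate",
    "delta_age",
    "associate_risk_factor",
    "associate_biomarker",
    "associate_incident",
    "sensitivity_adjust_bmi",
]


@dataclass(frozen=True)
class CvScheme:
    kind: str  # 'kfold' | 'loco'
    k: int = 7

    def __post_init__(self):
        if self.kind not in ("kfold", "loco"):
            raise ValueError("scheme kind must be 'kfold' or 'loco'")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class PerformanceReport:
    scheme: str
    pearson_r: float
    mae: float
    per_cohort: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"scheme": self.scheme, "pearson_r": self.pearson_r,
                "mae": self.mae, "per_cohort": self.per_cohort}


@dataclass
class AssociationEstimate:
    label: str
    estimate: float
    se: float
    p: float
    n: int
    n_events: int | None = None
    adjusted_for: tuple[str, ...] = ()
    pooled: bool = False

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)


def _make_folds(samples: pd.DataFrame, scheme: CvScheme, seed: int) -> list[tuple[str, pd.Index]]:
    """Fold label -> test-sample index, grouped by subject (kfold) or cohort."""
    if scheme.kind == "loco":
        cohorts = sorted(samples["cohort"].unique())
        if len(cohorts) < 2:
            raise ValueError("LOCO needs at least two cohorts")
        return [(c, samples.index[samples["cohort"] == c]) for c in cohorts]
    subjects = np.sort(samples["subject_id"].unique())
    if scheme.k > len(subjects):
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(subjects)
    out = []
    for f, chunk in enumerate(np.array_split(perm, scheme.k)):
        mask = samples["subject_id"].isin(chunk)
        out.append((f"fold{f}", samples.index[mask]))
    return out


def cross_validate(
    fit_fn,
    mets: pd.DataFrame,
    samples: pd.DataFrame,
    scheme: CvScheme,
    seed: int = 0,
) -> tuple[pd.DataFrame, PerformanceReport]:
    """Out-of-fold predictions under a grouped CV scheme.

    ``fit_fn(train_mets, train_samples)`` must return a callable
    ``predict_fn(mets) -> array of predicted ages``. Every sample receives
    exactly one out-of-fold prediction; train/test subject sets are audited
    to be disjoint.
    """
    meta = samples.loc[mets.index]
    folds = _make_folds(meta, scheme, seed)
    oof = pd.DataFrame(
        {"cohort": meta["cohort"], "age": meta["age"].astype(float),
         "predicted_age": np.nan, "fold": ""},
        index=meta.index,
    )
    for label, test_idx in folds:
        train_idx = meta.index.difference(test_idx)
        train_subj = set(meta.loc[train_idx, "subject_id"])
        test_subj = set(meta.loc[test_idx, "subject_id"])
        assert not train_subj & test_subj, "fold hygiene violated"
        if meta.loc[train_idx, "age"].nunique() <= 1:
            raise ValueError(f"fold {label}: training ages are constant")
        predict_fn = fit_fn(mets.loc[train_idx], meta.loc[train_idx])
        oof.loc[test_idx, "predicted_age"] = np.asarray(
            predict_fn(mets.loc[test_idx]), dtype=float)
        oof.loc[test_idx, "fold"] = label

    r = float(np.corrcoef(oof["age"], oof["predicted_age"])[0, 1])
    mae = float((oof["age"] - oof["predicted_age"]).abs().mean())
    per_cohort = {}
    for c, grp in oof.groupby("cohort"):
        rc = (float(np.corrcoef(grp["age"], grp["predicted_age"])[0, 1])
              if grp["age"].nunique() > 1 and grp["predicted_age"].nunique() > 1
              else np.nan)
        per_cohort[str(c)] = {
            "pearson_r": rc,
            "mae": float((grp["age"] - grp["predicted_age"]).abs().mean()),
            "n": int(len(grp)),
        }
    report = PerformanceReport(
        scheme=f"{scheme.kind}" + (f"-{scheme.k}" if scheme.kind == "kfold" else ""),
        pearson_r=r, mae=mae, per_cohort=per_cohort,
    )
    return oof, report


def delta_age(
    predictions: pd.Series,
    samples: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Change in predicted age vs change in CA between consecutive visits.

    Returns (per-subject pairs, per-interval summary, Pearson r between
    delta predicted and delta CA). Intervals are integer-rounded year gaps.
    """
    meta = samples.loc[predictions.index]
    rows = []
    for subj, grp in meta.groupby("subject_id"):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("visit")
        pred = predictions.loc[grp.index].to_numpy(float)
        age = grp["age"].to_numpy(float)
        for i in range(1, len(grp)):
            rows.append({
                "subject_id": subj,
                "delta_predicted": pred[i] - pred[i - 1],
                "delta_ca": age[i] - age[i - 1],
            })
    if not rows:
        logger.warning("no subjects with repeat visits; delta-age output empty")
        return pd.DataFrame(columns=["subject_id", "delta_predicted", "delta_ca"]), \
            pd.DataFrame(), np.nan
    pairs = pd.DataFrame(rows)
    pairs["interval"] = pairs["delta_ca"].round().astype(int)
    summary = pairs.groupby("interval")["delta_predicted"].agg(
        median="median",
        iqr_low=lambda s: s.quantile(0.25),
        iqr_high=lambda s: s.quantile(0.75),
        n="count",
    ).reset_index()
    if pairs["delta_ca"].nunique() > 1 and pairs["delta_predicted"].nunique() > 1:
        r = float(np.corrcoef(pairs["delta_predicted"], pairs["delta_ca"])[0, 1])
    else:
        r = np.nan
    return pairs, summary, r


def _dedupe_earliest(meta: pd.DataFrame) -> pd.Index:
    return meta.sort_values(["subject_id", "visit"]).groupby(
        "subject_id", sort=False).head(1).index


def _ols_association(
    y: pd.Series, x: pd.Series, meta: pd.DataFrame,
    covariates: tuple[str, ...], label: str,
) -> AssociationEstimate:
    X = pd.DataFrame({"exposure": x.astype(float)})
    for c in covariates:
        X[c] = meta[c].astype(float)
    X = X.loc[:, X.nunique() > 1]
    if "exposure" not in X.columns:
        raise ValueError(f"{label}: exposure is constant")
    fit = sm.OLS(y.astype(float), sm.add_constant(X), missing="drop").fit()
    return AssociationEstimate(
        label=label,
        estimate=float(fit.params["exposure"]),
        se=float(fit.bse["exposure"]),
        p=float(fit.pvalues["exposure"]),
        n=int(fit.nobs),
        adjusted_for=tuple(c for c in covariates if c in X.columns),
    )


def associate_risk_factor(
    clock_scores: pd.Series,
    samples: pd.DataFrame,
    exposure: str,
    covariates: tuple[str, ...] = ("age", "sex", "ethnicity"),
    dedupe: bool = True,
) -> AssociationEstimate:
    """SD change of (CA-adjusted) clock score per level of a binary exposure,
    using one sample per subject (earliest visit)."""
    meta = samples.loc[clock_scores.index]
    idx = _dedupe_earliest(meta) if dedupe else meta.index
    meta = meta.loc[idx]
    s = clock_scores.loc[idx].astype(float)
    z = (s - s.mean()) / s.std(ddof=0)
    exp = meta[exposure]
    if set(exp.dropna().unique()) - {0, 1, True, False}:
        raise ValueError(f"exposure {exposure!r} must be binary")
    return _ols_association(z, exp, meta, covariates, exposure)


def associate_biomarker(
    clock_scores: pd.Series,
    samples: pd.DataFrame,
    biomarker: str,
    covariates: tuple[str, ...] = ("age", "sex", "ethnicity"),
    dedupe: bool = True,
) -> AssociationEstimate:
    """SD of clock per SD of a continuous biomarker, CA/sex/ethnicity
    adjusted; both sides are univariate scaled for cross-comparison."""
    meta = samples.loc[clock_scores.index]
    idx = _dedupe_earliest(meta) if dedupe else meta.index
    meta = meta.loc[idx]
    s = clock_scores.loc[idx].astype(float)
    b = meta[biomarker].astype(float)
    if b.nunique() <= 1:
        raise ValueError(f"biomarker {biomarker!r} is constant")
    z_s = (s - s.mean()) / s.std(ddof=0)
    z_b = (b - b.mean()) / b.std(ddof=0)
    return _ols_association(z_s, z_b, meta, covariates, biomarker)


def associate_incident(
    clock_scores: pd.Series,
    samples: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "ethnicity"),
    pool_by: str = "cohort",
    dedupe: bool = True,
    label: str = "incident",
) -> AssociationEstimate:
    """Pooled hazard ratio per year of metabolomic age for an incident event.

    Per-cohort Cox fits of time-to-event on the clock score (years) plus
    covariates; cohorts without events are skipped with a warning; log-HRs
    pooled by inverse-variance fixed-effect meta-analysis. The estimate is
    the pooled log-HR per year (exponentiate for the HR).
    """
    meta = samples.loc[clock_scores.index]
    idx = _dedupe_earliest(meta) if dedupe else meta.index
    meta = meta.loc[idx]
    s = clock_scores.loc[idx].astype(float)
    if "age" in covariates:
        r = np.corrcoef(s, meta["age"].astype(float))[0, 1]
        if abs(r) > 0.999:
            raise ValueError(
                "clock score is numerically collinear with CA (|r| > 0.999); "
                "the age-adjusted model is unidentifiable"
            )
    results: list[AssocResult] = []
    for cohort, grp_idx in meta.groupby(pool_by).groups.items():
        grp = meta.loc[grp_idx]
        n_events = int(grp["event"].sum())
        if n_events == 0:
            logger.warning("cohort %s has no events; skipped", cohort)
            continue
        df = pd.DataFrame({"clock": s.loc[grp_idx]})
        for c in covariates:
            df[c] = grp[c].astype(float)
        df = df.loc[:, df.nunique() > 1]
        df["time"] = grp["time"].astype(float)
        df["event"] = grp["event"].astype(int)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        results.append(AssocResult(
            metabolite=label, stratum=str(cohort),
            estimate=float(cph.params_["clock"]),
            se=float(cph.standard_errors_["clock"]),
            p=float(cph.summary.loc["clock", "p"]),
            n=len(grp), n_events=n_events,
        ))
    if not results:
        raise ValueError("no cohort had events")
    pooled = fixed_effect_meta(results)[0]
    return AssociationEstimate(
        label=label, estimate=pooled.pooled_estimate, se=pooled.pooled_se,
        p=pooled.p, n=int(sum(r.n for r in results)),
        n_events=int(sum(r.n_events for r in results)),
        adjusted_for=covariates, pooled=True,
    )


def sensitivity_adjust_bmi(assoc_fn, *args, covariates=("age", "sex", "ethnicity"), **kwargs):
    """Re-run any association with BMI appended to the covariate set."""
    covs = tuple(covariates) + (("bmi",) if "bmi" not in covariates else ())
    return assoc_fn(*args, covariates=covs, **kwargs)
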