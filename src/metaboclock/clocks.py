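"""The four metabolomic-age constructions and published-score application.

Chronological-age (CA) clocks: an elastic net (mixing alpha = 0.5), a
degree-2 MARS model, and a penalty-factor-weighted elastic net
("phenotypic age") whose per-metabolite shrinkage is the metabolite's
mortality-association p-value, set to 1 for metabolites whose age and
mortality associations point in opposite directions. The fourth model is a
penalized-Cox mortality score over the pruned metabolites with unpenalized
demographic covariates; its metabolite-only linear predictor is rescaled to
the training-CA mean and SD so all scores read in years.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .mars import HingeFactor, MarsModel, MarsTerm, fit_mars, mars_predict
from .mwas import MetaResult
from .penalized import cv_lambda, fit_enet_path

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = [
    "LinearClockModel",
    "CoxScoreModel",
    "ScoreScaler",
    "PublishedWeights",
    "fit_elastic_net_age",
    "fit_mars_age",
    "build_penalty_factors",
    "fit_phenotypic_age",
    "fit_mortality_score",
    "scale_to_years",
    "apply_published_score",
    "predict",
    "model_to_json",
    "model_from_json",
    "read_published_weights",
    "write_published_weights",
]


@dataclass
class ScoreScaler:
    """Affine map rendering a raw score in years of chronological age."""

    source_mean: float
    source_sd: float
    target_mean: float
    target_sd: float

    def __post_init__(self):
        if self.source_sd <= 0 or self.target_sd <= 0:
            raise ValueError("scaler SDs must be > 0 (degenerate score)")

    def apply(self, raw: np.ndarray) -> np.ndarray:
        return (np.asarray(raw, float) - self.source_mean) / self.source_sd \
            * self.target_sd + self.target_mean


@dataclass
class LinearClockModel:
    intercept: float
    coefficients: dict[str, float]   # years per concentration unit
    mixing: float
    penalty: float
    penalty_factors: dict[str, float]
    training_summary: dict[str, float] = field(default_factory=dict)

    @property
    def metabolites(self) -> list[str]:
        return list(self.coefficients)


@dataclass
class CoxScoreModel:
    metabolite_coefficients: dict[str, float]  # log-hazard per SD
    covariate_coefficients: dict[str, float]   # audit only; not in the score
    mixing: float
    penalty: float
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def metabolites(self) -> list[str]:
        return list(self.metabolite_coefficients)

    def raw_score(self, mets: pd.DataFrame) -> np.ndarray:
        missing = set(self.metabolites) - set(mets.columns)
        if missing:
            raise KeyError(f"missing model variable(s): {sorted(missing)}")
        s = np.zeros(len(mets))
        for m, b in self.metabolite_coefficients.items():
            mu, sd = self.standardization[m]
            s += b * (mets[m].to_numpy(float) - mu) / sd
        return s


@dataclass
class PublishedWeights:
    """A user-supplied weight table for an externally published score."""

    names: list[str]
    weights: dict[str, float]
    transform: str  # 'log-then-cohort-z' or 'raw'
    provenance: str = ""
    expected_count: int | None = None

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("biomarker names must be unique")
        if self.transform not in ("log-then-cohort-z", "raw"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.expected_count is not None and len(self.names) != self.expected_count:
            raise ValueError(
                f"weight table declares {self.expected_count} biomarkers "
                f"but contains {len(self.names)}"
            )


def fit_elastic_net_age(
    mets: pd.DataFrame,
    ages: pd.Series | np.ndarray,
    alpha: float = 0.5,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    penalty_factors: pd.Series | None = None,
    seed: int = 0,
) -> LinearClockModel:
    """Elastic-net CA clock; lambda picked by internal k-fold CV MSE.

    Predictors are standardized internally; reported coefficients are on the
    original concentration scale.
    """
    y = np.asarray(ages, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("ages must vary")
    x = mets.to_numpy(float)
    f = None if penalty_factors is None \
        else penalty_factors.reindex(mets.columns).to_numpy(float)
    if f is not None and np.any(~np.isfinite(f) | (f <= 0)):
        raise ValueError("penalty factors must be finite and > 0")
    best_lam, grid, _ = cv_lambda(x, y, alpha, f, lambda_grid, cv_folds, seed)
    path = fit_enet_path(x, y, alpha, f, grid)
    b0, b = path.coef_at(best_lam)
    pf = dict(zip(mets.columns, (path.factors).tolist()))
    return LinearClockModel(
        intercept=b0,
        coefficients=dict(zip(mets.columns, b.tolist())),
        mixing=alpha,
        penalty=best_lam,
        penalty_factors=pf,
        training_summary={"n": len(y), "ca_mean": float(y.mean()),
                          "ca_sd": float(y.std(ddof=0))},
    )


def fit_mars_age(
    mets: pd.DataFrame,
    ages: pd.Series | np.ndarray,
    max_degree: int = 2,
    max_terms: int | None = None,
    gcv_penalty: float = 3.0,
    max_knots: int = 16,
) -> MarsModel:
    """Degree-2 MARS CA clock with GCV backward pruning."""
    return fit_mars(mets, np.asarray(ages, float), max_degree=max_degree,
                    max_terms=max_terms, gcv_penalty=gcv_penalty,
                    max_knots=max_knots)


def build_penalty_factors(
    age_meta: list[MetaResult],
    mort_meta: list[MetaResult],
    metabolites: list[str],
) -> pd.Series:
    """Mortality-informed shrinkage weights for the phenotypic-age model.

    f_j = pooled mortality p-value of metabolite j; metabolites whose pooled
    age and mortality estimates disagree in sign get f_j = 1 (maximal
    penalty). All factors lie in (0, 1].
    """
    age = {r.metabolite: r for r in age_meta}
    mort = {r.metabolite: r for r in mort_meta}
    missing = [m for m in metabolites if m not in age or m not in mort]
    if missing:
        raise KeyError(f"metabolite(s) absent from meta table(s): {missing}")
    f = {}
    for m in metabolites:
        if age[m].pooled_estimate * mort[m].pooled_estimate < 0:
            f[m] = 1.0
        else:
            f[m] = float(min(max(mort[m].p, np.finfo(float).tiny), 1.0))
    return pd.Series(f, name="penalty_factor")


def fit_phenotypic_age(
    mets: pd.DataFrame,
    ages: pd.Series | np.ndarray,
    penalty_factors: pd.Series,
    alpha: float = 0.5,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> LinearClockModel:
    """Penalty-factor-weighted elastic net on CA.

    Factors are normalized internally to mean 1, so multiplying all factors
    by a constant (with lambda rescaled) leaves the fit unchanged; with all
    factors equal this reduces exactly to :func:`fit_elastic_net_age`.
    """
    f = penalty_factors.reindex(mets.columns)
    if f.isna().any():
        raise KeyError(
            f"penalty factor missing for: {list(f.index[f.isna()])}"
        )
    if (f <= 0).any():
        raise ValueError("penalty factors must be > 0")
    return fit_elastic_net_age(mets, ages, alpha, lambda_grid, cv_folds,
                               penalty_factors=f, seed=seed)


def _cox_covariate_matrix(samples: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    cols = {}
    for c in covariates:
        if c == "cohort":
            d = pd.get_dummies(samples["cohort"], prefix="cohort",
                               drop_first=True, dtype=float)
            cols.update({k: d[k] for k in d.columns})
        else:
            cols[c] = samples[c].astype(float)
    X = pd.DataFrame(cols, index=samples.index)
    return X.loc[:, X.nunique() > 1]


def _cox_log_partial_likelihood(risk: np.ndarray, time: np.ndarray,
                                event: np.ndarray) -> float:
    """Breslow log partial likelihood of given risk scores (up to constants)."""
    order = np.argsort(-time, kind="stable")  # descending time
    risk, time, event = risk[order], time[order], event[order]
    log_cum = np.logaddexp.accumulate(risk)
    # handle ties in time: risk set includes all with time >= t
    ll = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        denom = log_cum[j]
        for k in range(i, j + 1):
            if event[k]:
                ll += risk[k] - denom
        i = j + 1
    return ll


def fit_mortality_score(
    mets: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.5,
    n_lambda: int = 30,
    cv_folds: int = 5,
    covariates: tuple[str, ...] = ("age", "sex", "bmi", "ethnicity", "cohort"),
    seed: int = 0,
) -> tuple[CoxScoreModel, ScoreScaler]:
    """Elastic-net-penalized Cox model of all-cause mortality.

    Metabolites (standardized, so coefficients are log-HR per SD) are
    penalized; demographic covariates enter unpenalized so metabolite
    shrinkage is not distorted by covariate scale. Lambda is chosen by
    k-fold cross-validated test partial likelihood. The score is the
    metabolite-only linear predictor, and the returned scaler renders it in
    years against the training-CA mean and SD.
    """
    meta = samples.loc[mets.index]
    n_events = int(meta["event"].sum())
    if n_events == 0:
        raise ValueError("no events in training data")
    if n_events < 10 * mets.shape[1]:
        logger.warning(
            "only %d events for %d candidate metabolites (< 10 per term)",
            n_events, mets.shape[1],
        )

    z = (mets - mets.mean()) / mets.std(ddof=0)
    standardization = {
        m: (float(mets[m].mean()), float(mets[m].std(ddof=0))) for m in mets.columns
    }
    covs = _cox_covariate_matrix(meta, covariates)
    X = pd.concat([z, covs], axis=1)
    pf = np.r_[np.ones(z.shape[1]), np.zeros(covs.shape[1])]
    y = Surv.from_arrays(meta["event"].astype(bool).to_numpy(),
                         meta["time"].astype(float).to_numpy())

    base = CoxnetSurvivalAnalysis(
        l1_ratio=alpha, penalty_factor=pf, n_alphas=n_lambda,
        alpha_min_ratio=0.01, normalize=False, fit_baseline_model=False,
    )
    base.fit(X.to_numpy(), y)
    alphas = np.asarray(base.alphas_)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    folds = np.array_split(order, cv_folds)
    scores = np.full((cv_folds, len(alphas)), -np.inf)
    t_arr = meta["time"].astype(float).to_numpy()
    e_arr = meta["event"].astype(int).to_numpy()
    for f, test in enumerate(folds):
        train = np.setdiff1d(order, test)
        if e_arr[train].sum() == 0 or e_arr[test].sum() == 0:
            continue
        cv_fit = CoxnetSurvivalAnalysis(
            l1_ratio=alpha, penalty_factor=pf, alphas=alphas,
            normalize=False, fit_baseline_model=False,
        )
        cv_fit.fit(X.to_numpy()[train], Surv.from_arrays(
            e_arr[train].astype(bool), t_arr[train]))
        fitted = np.asarray(cv_fit.alphas_)
        coefs = cv_fit.coef_  # (p, n_fitted)
        for a_idx, a in enumerate(alphas):
            j = int(np.argmin(np.abs(fitted - a)))
            risk = X.to_numpy()[test] @ coefs[:, j]
            scores[f, a_idx] = _cox_log_partial_likelihood(
                risk, t_arr[test], e_arr[test])
    mean_score = np.nanmean(np.where(np.isfinite(scores), scores, np.nan), axis=0)
    # a null metabolite score is unusable: restrict the choice to lambdas
    # whose full-data path retains at least one metabolite
    support = (np.abs(base.coef_[: z.shape[1], :]) > 0).sum(axis=0)
    candidates = np.flatnonzero(support > 0)
    if candidates.size == 0:
        raise ValueError("no lambda on the path retains any metabolite; "
                         "the mortality score would be degenerate")
    unrestricted = int(np.nanargmax(mean_score))
    best = int(candidates[np.nanargmax(mean_score[candidates])])
    if unrestricted != best and support[unrestricted] == 0:
        logger.warning(
            "CV preferred the metabolite-free model; using the best "
            "supported lambda instead (CV log partial likelihood %.2f vs %.2f)",
            mean_score[best], mean_score[unrestricted],
        )
    coef = base.coef_[:, best]

    met_coef = dict(zip(z.columns, coef[: z.shape[1]].tolist()))
    cov_coef = dict(zip(covs.columns, coef[z.shape[1]:].tolist()))
    model = CoxScoreModel(
        metabolite_coefficients=met_coef,
        covariate_coefficients=cov_coef,
        mixing=alpha,
        penalty=float(alphas[best]),
        standardization=standardization,
    )
    raw = model.raw_score(mets)
    ages = meta["age"].astype(float)
    scaler = ScoreScaler(
        source_mean=float(raw.mean()), source_sd=float(raw.std(ddof=0)),
        target_mean=float(ages.mean()), target_sd=float(ages.std(ddof=0)),
    )
    return model, scaler


def scale_to_years(raw_scores: np.ndarray | pd.Series, scaler: ScoreScaler) -> np.ndarray:
    """Render a raw score in years: match the training-CA mean and SD."""
    return scaler.apply(np.asarray(raw_scores, float))


def apply_published_score(
    mets: pd.DataFrame,
    samples: pd.DataFrame,
    weights: PublishedWeights,
) -> np.ndarray:
    """Evaluate an externally published biomarker score on this dataset.

    ``log-then-cohort-z``: per cohort, z-score the log concentrations,
    take the weighted sum, then rescale against the dataset's CA so the
    result reads in years. ``raw``: direct linear combination (already in
    years).
    """
    missing = [m for m in weights.names if m not in mets.columns]
    if missing:
        raise KeyError(f"missing biomarker(s): {missing}")
    w = np.array([weights.weights[m] for m in weights.names])
    x = mets[weights.names].to_numpy(float)
    if weights.transform == "raw":
        return x @ w
    if np.any(x <= 0):
        raise ValueError(
            "non-positive concentration under log transform; apply a "
            "pseudocount upstream (config: published.pseudocount)"
        )
    logged = np.log(x)
    cohorts = samples.loc[mets.index, "cohort"]
    z = np.empty_like(logged)
    for cohort, idx in cohorts.groupby(cohorts).groups.items():
        loc = mets.index.get_indexer(idx)
        block = logged[loc]
        z[loc] = (block - block.mean(axis=0)) / block.std(axis=0, ddof=0)
    raw = z @ w
    ages = samples.loc[mets.index, "age"].astype(float)
    scaler = ScoreScaler(float(raw.mean()), float(raw.std(ddof=0)),
                         float(ages.mean()), float(ages.std(ddof=0)))
    return scaler.apply(raw)


def predict(model, mets: pd.DataFrame, scaler: ScoreScaler | None = None) -> np.ndarray:
    """Evaluate any fitted clock on a metabolite matrix (years)."""
    if isinstance(model, LinearClockModel):
        missing = set(model.metabolites) - set(mets.columns)
        if missing:
            raise KeyError(f"missing model variable(s): {sorted(missing)}")
        x = mets[model.metabolites].to_numpy(float)
        b = np.array([model.coefficients[m] for m in model.metabolites])
        return model.intercept + x @ b
    if isinstance(model, MarsModel):
        return mars_predict(model, mets)
    if isinstance(model, CoxScoreModel):
        if scaler is None:
            raise ValueError("CoxScoreModel prediction needs its ScoreScaler")
        return scaler.apply(model.raw_score(mets))
    raise TypeError(f"unknown model type {type(model).__name__}")


# ---------------------------------------------------------------------------
# serialization

def model_to_json(model, scaler: ScoreScaler | None = None) -> str:
    if isinstance(model, LinearClockModel):
        payload = {"type": "linear_clock", **asdict(model)}
    elif isinstance(model, MarsModel):
        payload = {
            "type": "mars",
            "gcv": model.gcv,
            "gcv_penalty": model.gcv_penalty,
            "variables": model.variables,
            "coefficients": model.coefficients.tolist(),
            "terms": [
                [{"var": f.var, "knot": f.knot, "direction": f.direction}
                 for f in t.factors]
                for t in model.terms
            ],
        }
    elif isinstance(model, CoxScoreModel):
        payload = {"type": "cox_score", **asdict(model)}
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    if scaler is not None:
        payload["scaler"] = asdict(scaler)
    payload["schema_version"] = SCHEMA_VERSION
    return json.dumps(payload, indent=1, sort_keys=True)


def model_from_json(text: str):
    d = json.loads(text)
    scaler = ScoreScaler(**d["scaler"]) if "scaler" in d else None
    kind = d["type"]
    if kind == "linear_clock":
        model = LinearClockModel(
            intercept=d["intercept"], coefficients=d["coefficients"],
            mixing=d["mixing"], penalty=d["penalty"],
            penalty_factors=d["penalty_factors"],
            training_summary=d.get("training_summary", {}),
        )
    elif kind == "mars":
        terms = [
            MarsTerm(tuple(HingeFactor(f["var"], f["knot"], f["direction"])
                           for f in t))
            for t in d["terms"]
        ]
        model = MarsModel(terms, np.asarray(d["coefficients"]), d["gcv"],
                          d["gcv_penalty"], d["variables"])
    elif kind == "cox_score":
        model = CoxScoreModel(
            metabolite_coefficients=d["metabolite_coefficients"],
            covariate_coefficients=d["covariate_coefficients"],
            mixing=d["mixing"], penalty=d["penalty"],
            standardization={k: tuple(v) for k, v in d["standardization"].items()},
        )
    else:
        raise ValueError(f"unknown model type {kind!r}")
    return (model, scaler) if scaler is not None else model


def write_published_weights(path, weights: PublishedWeights) -> None:
    """Two-column TSV with a YAML-style comment header."""
    with open(path, "w") as fh:
        fh.write(f"# transform: {weights.transform}\n")
        fh.write(f"# expected_count: {weights.expected_count}\n")
        fh.write(f"# provenance: {weights.provenance}\n")
        fh.write("biomarker\tweight\n")
        for m in weights.names:
            fh.write(f"{m}\t{weights.weights[m]!r}\n")


def read_published_weights(path) -> PublishedWeights:
    import yaml

    header_lines = []
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line[1:].strip())
            elif line.strip() and not line.startswith("biomarker\t"):
                name, w = line.rstrip("\n").split("\t")
                rows.append((name, float(w)))
    header = yaml.safe_load("\n".join(header_lines)) or {}
    ec = header.get("expected_count")
    return PublishedWeights(
        names=[r[0] for r in rows],
        weights={r[0]: r[1] for r in rows},
        transform=header.get("transform", "raw"),
        provenance=str(header.get("provenance", "")),
        expected_count=None if ec in (None, "None") else int(ec),
    )
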