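"""Pre-modelling data pipeline: variable QC, multivariate sample-outlier
weights, between-cohort calibration on demographically matched subsets, and
k-nearest-neighbour imputation.

Outlier detection follows a transparent robust-PCA scheme: per cohort,
metabolites are centred and scaled by median/MAD, projected onto principal
components retaining a configured share of variance, and each sample's
robust squared distance in component space is mapped monotonically onto a
weight in [0, 1]; samples with weight at or below a threshold (default 0.1)
are flagged. The contract is the flags, not the exact weight values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MAD_CONSISTENCY = 1.4826  # makes MAD a consistent sigma estimate for Gaussians

__all__ = [
    "QCReport",
    "CalibrationFactors",
    "OutlierWeights",
    "filter_variables",
    "detect_outliers",
    "calibrate",
    "impute_knn",
]


@dataclass
class QCReport:
    removed_variables: dict[str, str]  # variable -> reason code
    removed_samples: dict[str, float]  # sample id -> outlier weight
    n_before: int
    n_after: int

    def to_dict(self) -> dict:
        return {
            "removed_variables": self.removed_variables,
            "removed_samples": self.removed_samples,
            "n_before": self.n_before,
            "n_after": self.n_after,
        }


@dataclass
class CalibrationFactors:
    reference_cohort: str
    factors: dict[str, dict[str, float]]  # cohort -> metabolite -> scale
    matched_subset_sizes: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference_cohort": self.reference_cohort,
            "factors": self.factors,
            "matched_subset_sizes": self.matched_subset_sizes,
        }


@dataclass
class OutlierWeights:
    weights: pd.Series  # per sample, in [0, 1]
    threshold: float = 0.1

    @property
    def flags(self) -> pd.Series:
        return self.weights <= self.threshold

    def flagged_ids(self) -> list[str]:
        return list(self.weights.index[self.flags])


def filter_variables(
    mets: pd.DataFrame,
    samples: pd.DataFrame,
    derived_names: list[str] | None = None,
    dual_measures: pd.DataFrame | None = None,
    r_threshold: float = 0.7,
    missing_rule: float = 0.5,
) -> tuple[pd.DataFrame, QCReport]:
    """Drop derived/ratio variables, variables predominantly missing in any
    cohort, and variables discordant between paired quantification protocols.

    ``missing_rule`` is the within-cohort missingness fraction at or above
    which a variable counts as missing in that cohort. ``dual_measures``,
    when given, holds the same variables re-quantified under a second
    protocol on a (subset of) samples; variables with cross-protocol Pearson
    r below ``r_threshold`` are removed. Each removed variable carries
    exactly one reason code, assessed in the order derived-ratio,
    missing-in-cohort, cross-protocol-r-below-threshold.
    """
    if not 0 < r_threshold <= 1:
        raise ValueError("r_threshold must be in (0, 1]")
    derived_names = derived_names or []
    removed: dict[str, str] = {}

    for name in derived_names:
        if name in mets.columns:
            removed[name] = "derived-ratio"

    cohorts = samples.loc[mets.index, "cohort"]
    for name in mets.columns:
        if name in removed:
            continue
        frac = mets[name].isna().groupby(cohorts).mean()
        if (frac >= missing_rule).any():
            removed[name] = "missing-in-cohort"

    if dual_measures is not None:
        common = dual_measures.index.intersection(mets.index)
        for name in dual_measures.columns:
            if name not in mets.columns or name in removed:
                continue
            a = mets.loc[common, name]
            b = dual_measures.loc[common, name]
            ok = a.notna() & b.notna()
            if ok.sum() < 3:
                continue
            r = np.corrcoef(a[ok], b[ok])[0, 1]
            if r < r_threshold:
                removed[name] = "cross-protocol-r-below-threshold"

    keep = [c for c in mets.columns if c not in removed]
    if not keep:
        raise ValueError("variable QC removed every variable")
    report = QCReport(
        removed_variables=removed,
        removed_samples={},
        n_before=len(mets),
        n_after=len(mets),
    )
    return mets[keep], report


def _cohort_weights(x: np.ndarray, retained_variance: float) -> np.ndarray:
    """Robust-PCA outlier weights for one cohort's (n, p) matrix."""
    med = np.median(x, axis=0)
    mad = MAD_CONSISTENCY * np.median(np.abs(x - med), axis=0)
    keep = mad > 0
    if keep.sum() < 2:
        raise ValueError("fewer than two non-constant metabolites in cohort")
    if not keep.all():
        logger.warning(
            "excluding %d constant (zero-MAD) metabolite(s) from outlier distances",
            (~keep).sum(),
        )
    z = (x[:, keep] - med[keep]) / mad[keep]
    # principal axes of the scaled data; distances re-robustified per component
    cov = np.cov(z, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    cum = np.cumsum(np.clip(evals, 0, None))
    k = int(np.searchsorted(cum / cum[-1], retained_variance) + 1)
    scores = z @ evecs[:, :k]
    s_med = np.median(scores, axis=0)
    s_mad = MAD_CONSISTENCY * np.median(np.abs(scores - s_med), axis=0)
    s_mad[s_mad == 0] = 1.0
    d2 = (((scores - s_med) / s_mad) ** 2).sum(axis=1)
    # typical point -> weight ~ 1; weight decays linearly between the chi^2
    # median and the 99.9% point of the component-space distance
    lo = stats.chi2.ppf(0.5, df=k)
    hi = stats.chi2.ppf(0.999, df=k)
    w = np.clip((hi - d2) / (hi - lo), 0.0, 1.0)
    return w


def detect_outliers(
    mets: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    per_cohort: bool = True,
    weight_threshold: float = 0.1,
    retained_variance: float = 0.99,
) -> OutlierWeights:
    """Multivariate location-outlier weights, computed per study cohort.

    Requires at least 10 samples and 2 metabolites per cohort. Constant
    (zero-MAD) metabolites are excluded from the distance computation with a
    logged warning.
    """
    if not 0 <= weight_threshold <= 1:
        raise ValueError("weight_threshold must be in [0, 1]")
    if mets.shape[1] < 2:
        raise ValueError("need at least two metabolites")
    if per_cohort:
        if samples is None:
            raise ValueError("per-cohort detection needs the sample table")
        groups = samples.loc[mets.index, "cohort"]
    else:
        groups = pd.Series("all", index=mets.index)

    weights = pd.Series(np.nan, index=mets.index, name="outlier_weight")
    for cohort, idx in groups.groupby(groups).groups.items():
        block = mets.loc[idx]
        if len(block) < 10:
            raise ValueError(f"cohort {cohort!r} has fewer than 10 samples")
        weights.loc[idx] = _cohort_weights(block.to_numpy(float), retained_variance)
    return OutlierWeights(weights=weights, threshold=weight_threshold)


# WHO BMI bands: underweight, normal, overweight, obese I, obese II+
_BMI_EDGES = [-np.inf, 18.5, 25.0, 30.0, 35.0, np.inf]


def _matching_cells(
    meta: pd.DataFrame, age_bin_width: float
) -> pd.Series:
    age_bin = (meta["age"] // age_bin_width).astype(int)
    bmi_bin = pd.cut(meta["bmi"], _BMI_EDGES, labels=False)
    return (
        age_bin.astype(str)
        + "|" + meta["sex"].astype(str)
        + "|" + bmi_bin.astype(str)
        + "|" + meta["ethnicity"].astype(str)
    )


def calibrate(
    mets: pd.DataFrame,
    samples: pd.DataFrame,
    reference: str,
    age_bin_width: float = 5.0,
    estimator: str = "median",
    min_cell: int = 1,
) -> tuple[pd.DataFrame, CalibrationFactors]:
    """Rescale each non-reference cohort onto the reference cohort's scale.

    Target and reference samples are matched cell-wise on binned age
    (``age_bin_width``-year bands), sex, WHO BMI band, and ethnicity; cells
    present in both with at least ``min_cell`` samples on each side form the
    matched subsets. The per-metabolite scale factor is the reference-subset
    median over the target-subset median (means via ``estimator='mean'``),
    applied to the whole target cohort. The reference cohort passes through
    unchanged.
    """
    cohorts = samples.loc[mets.index, "cohort"]
    if reference not in set(cohorts):
        raise ValueError(f"reference cohort {reference!r} not present")
    agg = {"median": np.median, "mean": np.mean}[estimator]

    meta = samples.loc[mets.index]
    cells = _matching_cells(meta, age_bin_width)
    ref_idx = mets.index[cohorts == reference]
    ref_cells = cells.loc[ref_idx]

    out = mets.copy()
    factors: dict[str, dict[str, float]] = {
        reference: {m: 1.0 for m in mets.columns}
    }
    sizes: dict[str, int] = {reference: len(ref_idx)}
    for cohort in sorted(set(cohorts) - {reference}):
        tgt_idx = mets.index[cohorts == cohort]
        tgt_cells = cells.loc[tgt_idx]
        common = sorted(
            set(tgt_cells.value_counts()[lambda s: s >= min_cell].index)
            & set(ref_cells.value_counts()[lambda s: s >= min_cell].index)
        )
        if not common:
            raise ValueError(
                f"cohort {cohort!r}: no demographic cell matches the reference "
                f"(age bands of {age_bin_width} y, sex, BMI band, ethnicity)"
            )
        tgt_sub = mets.loc[tgt_idx[tgt_cells.isin(common)]]
        ref_sub = mets.loc[ref_idx[ref_cells.isin(common)]]
        sizes[cohort] = len(tgt_sub)
        f = {}
        for m in mets.columns:
            denom = agg(tgt_sub[m].dropna().to_numpy())
            if denom == 0 or not np.isfinite(denom):
                raise ValueError(
                    f"cohort {cohort!r}, metabolite {m!r}: target-subset "
                    f"{estimator} is zero, scale factor undefined"
                )
            f[m] = float(agg(ref_sub[m].dropna().to_numpy()) / denom)
        factors[cohort] = f
        out.loc[tgt_idx] = out.loc[tgt_idx] * pd.Series(f)
    return out, CalibrationFactors(
        reference_cohort=reference, factors=factors, matched_subset_sizes=sizes
    )


def impute_knn(mets: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """k-nearest-neighbour imputation of missing concentrations.

    Neighbours are ranked by Euclidean distance over the metabolites
    observed in both samples, after per-metabolite standardization; a
    missing cell becomes the mean of that metabolite among the k nearest
    samples in which it is observed. Ties in distance break by sample-id
    order. Observed cells are untouched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = mets.to_numpy(float)
    obs = ~np.isnan(x)
    if (~obs).sum() == 0:
        return mets.copy()
    if (obs.sum(axis=0) == 0).any():
        bad = mets.columns[obs.sum(axis=0) == 0].tolist()
        raise ValueError(f"metabolite(s) missing for all samples: {bad}")
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("every sample must have at least one observed metabolite")

    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    z0 = np.where(obs, z, 0.0)
    # squared distance over mutually observed coords:
    # sum_m obs_im obs_jm (z_im - z_jm)^2
    sq = z0**2
    d2 = sq @ obs.T + obs @ sq.T - 2 * z0 @ z0.T
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")  # stable => id-order tie-break

    out = x.copy()
    rows, cols = np.where(~obs)
    for i, j in zip(rows, cols):
        donors = [t for t in order[i] if obs[t, j]][:k]
        out[i, j] = x[donors, j].mean()
    return pd.DataFrame(out, index=mets.index, columns=mets.columns)
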