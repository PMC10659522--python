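"""Synthetic multi-cohort metabolomic study generator.

Emulates the statistical structure a multi-cohort NMR-metabolomics ageing
analysis assumes: several cohorts with distinct (possibly degenerate) age
ranges, correlated metabolite blocks with linear and curvilinear age effects,
cohort-level multiplicative batch factors, Cox-type mortality with
metabolite-dependent hazards and administrative censoring, planted
multivariate outliers, and repeat visits. Every generating parameter is
recorded in a :class:`GroundTruth` so downstream stages can be tested for
parameter recovery.

Conventions: ``sex`` is coded 0 = male, 1 = female; ``ethnicity`` is a
two-level integer category (0 majority, 1 minority). Sample ids are
``<cohort>-<subject>-v<visit>`` and subject ids ``<cohort>-<subject>``.
All metadata columns are prefixed ``meta_`` when written to CSV (see
:mod:`metaboclock.io`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "MetaboliteModel",
    "GroundTruth",
    "simulate_study",
    "simulate_survival",
    "inject_outliers",
    "analytic_clock_r2",
    "default_cohort_specs",
    "default_metabolite_model",
    "default_study",
]

META_COLUMNS = [
    "subject_id",
    "cohort",
    "visit",
    "age",
    "sex",
    "bmi",
    "ethnicity",
    "smoking",
    "fasting",
    "birth_cohort",
]


def derive_seed(seed: int, label: str) -> int:
    """Stage/cohort-local seed: CRC32 of the label folded into the base seed.

    Keeps every derived seed below 2**31 and makes the splitting scheme
    reproducible and documented.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class CohortSpec:
    """Identity and sampling design of one study cohort.

    ``batch_factors`` is the per-metabolite multiplicative scale applied to
    every concentration in the cohort (a scalar applies to all metabolites).
    ``visit_gaps`` lists years between consecutive repeat visits; an empty
    list means single-visit. A degenerate ``age_range`` (min == max) marks a
    birth cohort, which training stages exclude.
    """

    name: str
    n_subjects: int
    age_range: tuple[float, float]
    sex_ratio: float = 0.5
    batch_factors: float | Mapping[str, float] = 1.0
    visit_gaps: tuple[float, ...] = ()
    fasting: bool = True

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError(f"cohort {self.name!r}: n_subjects must be >= 1")
        lo, hi = self.age_range
        if lo > hi or lo < 18 or hi > 100:
            raise ValueError(
                f"cohort {self.name!r}: age_range must satisfy 18 <= min <= max <= 100"
            )
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError(f"cohort {self.name!r}: sex_ratio must be in [0, 1]")
        object.__setattr__(self, "visit_gaps", tuple(self.visit_gaps))

    @property
    def is_birth_cohort(self) -> bool:
        return self.age_range[0] == self.age_range[1]

    def resolved_batch_factors(self, names: Sequence[str]) -> np.ndarray:
        if np.isscalar(self.batch_factors):
            out = np.full(len(names), float(self.batch_factors))
        else:
            out = np.array([float(self.batch_factors.get(m, 1.0)) for m in names])
        if np.any(out <= 0):
            raise ValueError(f"cohort {self.name!r}: batch factors must be > 0")
        return out


@dataclass
class MetaboliteModel:
    """Generating model for the metabolite panel.

    Concentrations follow, before batch scaling and flooring at zero,

        x_m = base_mean_m + age_slope_m * age
              + age_curvature_m * (age - curvature_center)^2 + eps_m,

    with ``eps`` zero-mean Gaussian, sd ``base_sd_m``, block-equicorrelated
    with correlation ``rho`` inside each block of ``blocks`` and independent
    across blocks. ``log_hazard`` is the per-SD log hazard ratio each
    metabolite contributes to mortality.
    """

    names: list[str]
    base_mean: np.ndarray
    base_sd: np.ndarray
    age_slope: np.ndarray
    age_curvature: np.ndarray | None = None
    curvature_center: float = 60.0
    blocks: list[list[str]] = field(default_factory=list)
    rho: float = 0.0
    log_hazard: np.ndarray | None = None

    def __post_init__(self):
        self.names = list(self.names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("metabolite names must be unique")
        p = len(self.names)
        for attr in ("base_mean", "base_sd", "age_slope"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape != (p,):
                raise ValueError(f"{attr} must have one entry per metabolite")
            setattr(self, attr, v)
        if np.any(self.base_sd <= 0):
            raise ValueError("base_sd must be > 0")
        if self.age_curvature is None:
            self.age_curvature = np.zeros(p)
        else:
            self.age_curvature = np.asarray(self.age_curvature, dtype=float)
        if self.log_hazard is not None:
            self.log_hazard = np.asarray(self.log_hazard, dtype=float)
        if not -1 < self.rho < 1:
            raise ValueError("|rho| must be < 1")
        if not self.blocks:
            self.blocks = [list(self.names)]
        flat = [m for b in self.blocks for m in b]
        if sorted(flat) != sorted(self.names):
            raise ValueError("blocks must partition the metabolite names")

    @property
    def n_metabolites(self) -> int:
        return len(self.names)

    def noise_covariance(self) -> np.ndarray:
        """Covariance of eps implied by the block-equicorrelation structure."""
        p = self.n_metabolites
        idx = {m: j for j, m in enumerate(self.names)}
        corr = np.eye(p)
        for block in self.blocks:
            jj = [idx[m] for m in block]
            for a in jj:
                for b in jj:
                    if a != b:
                        corr[a, b] = self.rho
        d = np.diag(self.base_sd)
        return d @ corr @ d


@dataclass
class GroundTruth:
    """All generating parameters, for recovery tests."""

    batch_factors: dict[str, dict[str, float]]
    age_slope: dict[str, float]
    age_curvature: dict[str, float]
    log_hazard: dict[str, float]
    curvature_center: float
    outlier_ids: list[str] = field(default_factory=list)
    true_survival_time: dict[str, float] = field(default_factory=dict)
    gamma_age: float = 0.0

    def to_dict(self) -> dict:
        return {
            "batch_factors": self.batch_factors,
            "age_slope": self.age_slope,
            "age_curvature": self.age_curvature,
            "log_hazard": self.log_hazard,
            "curvature_center": self.curvature_center,
            "outlier_ids": list(self.outlier_ids),
            "true_survival_time": self.true_survival_time,
            "gamma_age": self.gamma_age,
        }


def _draw_noise(rng: np.random.Generator, model: MetaboliteModel, n: int) -> np.ndarray:
    """Block-equicorrelated Gaussian noise via shared + idiosyncratic factors."""
    p = model.n_metabolites
    idx = {m: j for j, m in enumerate(model.names)}
    eps = np.empty((n, p))
    rho = model.rho
    for block in model.blocks:
        jj = [idx[m] for m in block]
        z = rng.standard_normal((n, len(jj)))
        if rho > 0:
            shared = rng.standard_normal((n, 1))
            z = np.sqrt(1.0 - rho) * z + np.sqrt(rho) * shared
        eps[:, jj] = z
    return eps * model.base_sd


def simulate_study(
    specs: Sequence[CohortSpec],
    model: MetaboliteModel,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a multi-cohort study.

    Returns ``(samples, mets, truth)`` where ``samples`` holds one row per
    sample (subjects x visits) with metadata columns, ``mets`` the aligned
    concentration matrix, and ``truth`` every generating parameter. The same
    ``(specs, model, seed)`` triple yields byte-identical output.
    """
    if len(specs) == 0:
        raise ValueError("at least one cohort spec is required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("cohort names must be unique")

    meta_rows = []
    met_rows = []
    index = []
    truth_batches: dict[str, dict[str, float]] = {}
    for spec in specs:
        rng = np.random.default_rng(derive_seed(seed, f"cohort:{spec.name}"))
        lo, hi = spec.age_range
        base_age = rng.uniform(lo, hi, spec.n_subjects) if hi > lo else np.full(spec.n_subjects, lo)
        sex = (rng.random(spec.n_subjects) < spec.sex_ratio).astype(int)
        bmi = np.clip(rng.normal(27.0, 4.5, spec.n_subjects), 16.0, 50.0)
        ethnicity = (rng.random(spec.n_subjects) < 0.15).astype(int)
        smoking = (rng.random(spec.n_subjects) < 0.25).astype(int)
        batch = spec.resolved_batch_factors(model.names)
        truth_batches[spec.name] = dict(zip(model.names, batch.tolist()))

        visit_ages = [0.0, *np.cumsum(spec.visit_gaps)]
        for visit, offset in enumerate(visit_ages):
            age = base_age + offset
            mu = (
                model.base_mean
                + np.outer(age, model.age_slope)
                + np.outer((age - model.curvature_center) ** 2, model.age_curvature)
            )
            x = (mu + _draw_noise(rng, model, spec.n_subjects)) * batch
            np.maximum(x, 0.0, out=x)  # concentrations are non-negative
            met_rows.append(x)
            for i in range(spec.n_subjects):
                subject = f"{spec.name}-{i:05d}"
                index.append(f"{subject}-v{visit}")
                meta_rows.append(
                    {
                        "subject_id": subject,
                        "cohort": spec.name,
                        "visit": visit,
                        "age": age[i],
                        "sex": int(sex[i]),
                        "bmi": bmi[i],
                        "ethnicity": int(ethnicity[i]),
                        "smoking": int(smoking[i]),
                        "fasting": bool(spec.fasting),
                        "birth_cohort": spec.is_birth_cohort,
                    }
                )

    samples = pd.DataFrame(meta_rows, index=pd.Index(index, name="sample_id"))
    mets = pd.DataFrame(
        np.vstack(met_rows), index=samples.index, columns=model.names
    )
    truth = GroundTruth(
        batch_factors=truth_batches,
        age_slope=dict(zip(model.names, model.age_slope.tolist())),
        age_curvature=dict(zip(model.names, model.age_curvature.tolist())),
        log_hazard=dict(
            zip(model.names, (model.log_hazard if model.log_hazard is not None else np.zeros(model.n_metabolites)).tolist())
        ),
        curvature_center=model.curvature_center,
    )
    return samples, mets, truth


def simulate_survival(
    samples: pd.DataFrame,
    mets: pd.DataFrame,
    model: MetaboliteModel,
    baseline: tuple[float, float] = (1.4, 40.0),
    censor_time: float = 15.0,
    seed: int = 0,
    gamma_age: float = 0.0,
    ground_truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Attach Weibull-baseline proportional-hazards survival to a study.

    The linear predictor is ``sum_m logHR_m * z_m + gamma_age * (age - mean age)``
    with ``z_m`` the within-dataset standardized metabolite, evaluated at each
    subject's first visit; the drawn (time, event) pair is shared across that
    subject's visits so repeat samples stay coherent. ``baseline`` is the
    Weibull (shape k, scale lambda); administrative censoring at
    ``censor_time``. Age is centred so the event rate is governed by the
    baseline, not the age origin.
    """
    shape, scale = baseline
    if shape <= 0 or scale <= 0:
        raise ValueError("Weibull shape and scale must be > 0")
    if censor_time <= 0:
        raise ValueError("censor_time must be > 0")
    if model.log_hazard is None:
        raise ValueError("model.log_hazard must be defined for every metabolite")

    rng = np.random.default_rng(derive_seed(seed, "survival"))
    z = (mets - mets.mean()) / mets.std(ddof=0)
    eta_all = z.to_numpy() @ model.log_hazard + gamma_age * (
        samples["age"].to_numpy() - samples["age"].mean()
    )
    eta = pd.Series(eta_all, index=samples.index)

    first = samples.sort_values("visit").groupby("subject_id", sort=False).head(1)
    out = samples.copy()
    out["time"] = np.nan
    out["event"] = 0
    truth_times: dict[str, float] = {}
    # one draw per subject, in deterministic subject order
    first = first.sort_index()
    e = rng.exponential(size=len(first))
    t_true = scale * (e / np.exp(eta.loc[first.index].to_numpy())) ** (1.0 / shape)
    for sid, subj, t in zip(first.index, first["subject_id"], t_true):
        truth_times[subj] = float(t)
    subj_time = out["subject_id"].map(truth_times)
    out["time"] = np.minimum(subj_time, censor_time)
    out["event"] = (subj_time <= censor_time).astype(int)
    out.loc[out["time"] <= 0, "time"] = 1e-6
    if ground_truth is not None:
        ground_truth.true_survival_time = truth_times
        ground_truth.gamma_age = gamma_age
    return out


def inject_outliers(
    mets: pd.DataFrame,
    fraction: float,
    magnitude: float,
    seed: int,
    ground_truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Shift a random subset of samples along a random direction.

    Each selected row moves ``magnitude`` (in units of each metabolite's SD)
    along an independent random unit direction in metabolite space — the
    contamination pattern the multivariate outlier detector must find.
    Returns the modified matrix and the ids of the altered rows.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    if fraction > 0 and magnitude <= 0:
        raise ValueError("magnitude must be > 0")
    n = len(mets)
    n_out = int(np.floor(fraction * n))
    if n_out == 0:
        return mets.copy(), []
    rng = np.random.default_rng(derive_seed(seed, "outliers"))
    rows = np.sort(rng.choice(n, size=n_out, replace=False))
    sd = mets.std(ddof=0).to_numpy()
    u = rng.standard_normal((n_out, mets.shape[1]))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    out = mets.copy()
    out.iloc[rows] = out.iloc[rows].to_numpy() + magnitude * u * sd
    ids = list(mets.index[rows])
    if ground_truth is not None:
        ground_truth.outlier_ids = ids
    return out, ids


def analytic_clock_r2(model: MetaboliteModel, specs: Sequence[CohortSpec]) -> float:
    """Population R^2 of the best linear age predictor from the metabolites.

    With x = s*age + eps, the optimal linear combination attains
    R^2 = q / (1 + q) with q = var(age) * s' Sigma^-1 s, where Sigma is the
    noise covariance and var(age) the pooled (mixture-over-cohorts) age
    variance. Curvature terms are ignored (they add signal, slightly raising
    the attainable R^2). Batch factors cancel: they scale signal and noise
    alike.
    """
    weights = np.array([s.n_subjects * (1 + len(s.visit_gaps)) for s in specs], dtype=float)
    weights /= weights.sum()
    means = np.array([(s.age_range[0] + s.age_range[1]) / 2 for s in specs])
    variances = np.array([(s.age_range[1] - s.age_range[0]) ** 2 / 12 for s in specs])
    pooled_mean = weights @ means
    var_age = weights @ (variances + (means - pooled_mean) ** 2)
    s = model.age_slope
    sigma = model.noise_covariance()
    q = var_age * s @ np.linalg.solve(sigma, s)
    return float(q / (1.0 + q))


def default_cohort_specs(n_per_cohort: int = 400) -> list[CohortSpec]:
    """Five-cohort default study: staggered age ranges spanning 24-86 y, one
    revisit cohort, one single-sex cohort, cohort-level batch factors."""
    return [
        CohortSpec("alpha", n_per_cohort, (24, 45), sex_ratio=0.5, batch_factors=1.0),
        CohortSpec("bravo", n_per_cohort, (35, 60), sex_ratio=0.55, batch_factors=1.25),
        CohortSpec("whitegate", n_per_cohort, (40, 70), sex_ratio=0.5, batch_factors=1.0),
        CohortSpec(
            "delta", n_per_cohort, (50, 86), sex_ratio=1.0, batch_factors=0.8,
        ),
        CohortSpec(
            "echo", n_per_cohort, (30, 55), sex_ratio=0.5, batch_factors=1.1,
            visit_gaps=(6.0,),
        ),
    ]


def default_metabolite_model(
    n_metabolites: int = 40,
    target_r2: float = 0.5,
    specs: Sequence[CohortSpec] | None = None,
) -> MetaboliteModel:
    """Default correlated metabolite panel with age slopes scaled so the
    population linear-clock R^2 equals ``target_r2``.

    Half the metabolites carry age effects with alternating sign, a handful
    carry curvature (age-stratum heterogeneity), and eight carry mortality
    log hazards; blocks of eight share within-block correlation 0.3.
    """
    if specs is None:
        specs = default_cohort_specs()
    p = n_metabolites
    names = [f"met{j:03d}" for j in range(p)]
    rng = np.random.default_rng(20260101)  # fixed panel, not per-study randomness
    base_mean = rng.uniform(8.0, 40.0, p)
    base_sd = base_mean * rng.uniform(0.08, 0.20, p)
    slope_pattern = np.zeros(p)
    for j in range(0, p, 2):
        slope_pattern[j] = (1 if (j // 2) % 2 == 0 else -1) * rng.uniform(0.5, 1.5)
    slope_pattern *= base_sd  # effects on each metabolite's own scale
    curvature = np.zeros(p)
    for j in (1, 9, 17, 25):
        if j < p:
            curvature[j] = 0.0008 * base_sd[j] * (1 if j % 4 == 1 else -1)
    log_hazard = np.zeros(p)
    hazard_idx = [0, 4, 8, 12, 16, 20, 24, 28]
    for r, j in enumerate(hazard_idx):
        if j < p:
            log_hazard[j] = (0.3 if r % 2 == 0 else -0.2) * (1.0 - 0.05 * r)
    block_size = 8
    blocks = [names[i : i + block_size] for i in range(0, p, block_size)]
    model = MetaboliteModel(
        names=names,
        base_mean=base_mean,
        base_sd=base_sd,
        age_slope=slope_pattern,
        age_curvature=curvature,
        blocks=blocks,
        rho=0.3,
        log_hazard=log_hazard,
    )
    # closed-form scaling: R^2 = q/(1+q), so q_target = r2/(1-r2)
    r2_now = analytic_clock_r2(model, specs)
    q_now = r2_now / (1 - r2_now)
    q_target = target_r2 / (1 - target_r2)
    model.age_slope = model.age_slope * np.sqrt(q_target / q_now)
    return model


def default_study(
    seed: int,
    n_per_cohort: int = 400,
    n_metabolites: int = 40,
    outlier_fraction: float = 0.02,
    outlier_magnitude: float = 10.0,
    censor_time: float = 15.0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """One call producing the bundled default study: five cohorts, correlated
    panel at linear-clock R^2 0.5, mortality, planted outliers."""
    specs = default_cohort_specs(n_per_cohort)
    model = default_metabolite_model(n_metabolites, specs=specs)
    samples, mets, truth = simulate_study(specs, model, seed)
    samples = simulate_survival(
        samples, mets, model, censor_time=censor_time, seed=seed,
        gamma_age=0.05, ground_truth=truth,
    )
    mets, _ = inject_outliers(
        mets, outlier_fraction, outlier_magnitude, seed, ground_truth=truth
    )
    return samples, mets, truth
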