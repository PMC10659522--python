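"""End-to-end orchestration: simulate -> preprocess -> mwas -> prune ->
train -> evaluate, with every intermediate artifact written to disk, a
machine-readable manifest (config echo, seed, stage checksums) and a short
human-readable report. Identical config and seed give identical manifest
checksums.

Stage-local randomness derives from the run seed through
:func:`metaboclock.synthetic.derive_seed` (CRC32 of the stage name folded
into the seed), so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clocks import (
    build_penalty_factors,
    fit_elastic_net_age,
    fit_mars_age,
    fit_mortality_score,
    fit_phenotypic_age,
    model_to_json,
    predict,
)
from .config import PipelineConfig
from .evaluation import (
    CvScheme,
    associate_incident,
    associate_risk_factor,
    cross_validate,
    delta_age,
)
from .io import read_tables, write_tables
from .mwas import (
    assoc_to_frame,
    classify_concordance,
    fixed_effect_meta,
    meta_to_frame,
    mwas_age,
    mwas_age_stratified,
    mwas_mortality,
)
from .preprocess import calibrate, detect_outliers, filter_variables
from .synthetic import default_study, derive_seed
from .vif import backward_prune

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "StageError", "STAGES"]

STAGES = ["simulate", "preprocess", "mwas", "prune", "train", "evaluate"]


class StageError(RuntimeError):
    def __init__(self, stage: str, last_good: str, cause: BaseException):
        super().__init__(
            f"stage {stage!r} failed ({cause}); last good artifact state: {last_good}"
        )
        self.stage = stage
        self.last_good = last_good
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    sim = cfg.simulate
    samples, mets, truth = default_study(
        seed=derive_seed(cfg.seed, "simulate"),
        n_per_cohort=sim.n_per_cohort,
        n_metabolites=sim.n_metabolites,
        outlier_fraction=sim.outlier_fraction,
        outlier_magnitude=sim.outlier_magnitude,
        censor_time=sim.censor_time,
    )
    write_tables(out / "study.csv", samples, mets)
    _write_json(out / "ground_truth.json", truth.to_dict())


def stage_preprocess(cfg: PipelineConfig, out: Path) -> None:
    samples, mets = read_tables(out / "study.csv")
    mets, qc = filter_variables(
        mets, samples, derived_names=[], r_threshold=cfg.qc.r_threshold,
        missing_rule=cfg.qc.missing_rule,
    )
    ow = detect_outliers(
        mets, samples, per_cohort=True,
        weight_threshold=cfg.outliers.weight_threshold,
        retained_variance=cfg.outliers.retained_variance,
    )
    flagged = ow.flagged_ids()
    qc.removed_samples = {s: float(ow.weights[s]) for s in flagged}
    qc.n_after = qc.n_before - len(flagged)
    keep = mets.index.difference(flagged)
    samples, mets = samples.loc[keep], mets.loc[keep]
    mets, factors = calibrate(
        mets, samples, reference=cfg.calibrate.reference,
        age_bin_width=cfg.calibrate.age_bin_width,
        estimator=cfg.calibrate.estimator,
    )
    ow.weights.to_csv(out / "outlier_weights.csv", float_format="%.17g")
    _write_json(out / "qc_report.json", qc.to_dict())
    _write_json(out / "calibration.json", factors.to_dict())
    write_tables(out / "calibrated.csv", samples, mets)


def stage_mwas(cfg: PipelineConfig, out: Path) -> None:
    samples, mets = read_tables(out / "calibrated.csv")
    bands = [tuple(b) for b in cfg.age_strata]
    age_assoc = mwas_age(mets, samples)
    age_meta = fixed_effect_meta(age_assoc)
    band_assoc = mwas_age_stratified(mets, samples, age_bands=bands)
    band_meta = fixed_effect_meta(band_assoc)
    mort_assoc = mwas_mortality(mets, samples)
    mort_meta = fixed_effect_meta(mort_assoc)
    conc = classify_concordance(age_meta, mort_meta, cfg.significance.q_threshold)
    assoc_to_frame(age_assoc).to_csv(out / "age_assoc.tsv", sep="\t", index=False)
    meta_to_frame(age_meta).to_csv(out / "age_meta.tsv", sep="\t", index=False)
    assoc_to_frame(band_assoc).to_csv(out / "age_band_assoc.tsv", sep="\t", index=False)
    meta_to_frame(band_meta).to_csv(out / "age_band_meta.tsv", sep="\t", index=False)
    assoc_to_frame(mort_assoc).to_csv(out / "mortality_assoc.tsv", sep="\t", index=False)
    meta_to_frame(mort_meta).to_csv(out / "mortality_meta.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"metabolite": c.metabolite, "age_sign": c.age_sign,
          "mortality_sign": c.mortality_sign, "concordant": c.concordant}
         for c in conc]
    ).to_csv(out / "concordance.tsv", sep="\t", index=False)


def _training_view(out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    samples, mets = read_tables(out / "calibrated.csv")
    train = ~samples["birth_cohort"].astype(bool)  # birth cohorts never train
    return samples.loc[train], mets.loc[train]


def stage_prune(cfg: PipelineConfig, out: Path) -> None:
    samples, mets = _training_view(out)
    trace = backward_prune(mets, threshold=cfg.vif.threshold)
    if len(trace.surviving) < 2:
        raise ValueError(
            f"VIF pruning at threshold {cfg.vif.threshold} left "
            f"{len(trace.surviving)} variable(s); cannot train"
        )
    _write_json(out / "vif_trace.json", trace.to_dict())


def stage_train(cfg: PipelineConfig, out: Path) -> None:
    samples, mets = _training_view(out)
    pruned = json.loads((out / "vif_trace.json").read_text())["surviving"]
    x = mets[pruned]
    ages = samples["age"].astype(float)
    mc = cfg.model
    seed = derive_seed(cfg.seed, "train")

    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    enet = fit_elastic_net_age(x, ages, alpha=mc.alpha, cv_folds=mc.cv_folds,
                               seed=seed)
    (models_dir / "elastic_net.json").write_text(model_to_json(enet))

    mars = fit_mars_age(x, ages, max_terms=mc.mars_max_terms,
                        gcv_penalty=mc.gcv_penalty, max_knots=mc.mars_max_knots)
    (models_dir / "mars.json").write_text(model_to_json(mars))

    age_meta_df = pd.read_csv(out / "age_meta.tsv", sep="\t")
    mort_meta_df = pd.read_csv(out / "mortality_meta.tsv", sep="\t")
    from .mwas import MetaResult  # local import avoids a cycle at module load

    def _rows(df):
        return [MetaResult(r.metabolite, r.pooled_estimate, r.pooled_se,
                           r.p, r.q, r.Q, r.I2, int(r.k))
                for r in df.itertuples()]

    factors = build_penalty_factors(_rows(age_meta_df), _rows(mort_meta_df), pruned)
    factors.to_frame().to_csv(out / "penalty_factors.tsv", sep="\t")
    pheno = fit_phenotypic_age(x, ages, factors, alpha=mc.alpha,
                               cv_folds=mc.cv_folds, seed=seed)
    (models_dir / "phenotypic_age.json").write_text(model_to_json(pheno))

    cox, scaler = fit_mortality_score(x, samples, alpha=mc.alpha,
                                      cv_folds=mc.cv_folds, seed=seed)
    (models_dir / "mortality_score.json").write_text(model_to_json(cox, scaler))


def stage_evaluate(cfg: PipelineConfig, out: Path) -> None:
    samples, mets = _training_view(out)
    pruned = json.loads((out / "vif_trace.json").read_text())["surviving"]
    x = mets[pruned]
    mc = cfg.model
    seed = derive_seed(cfg.seed, "evaluate")

    def enet_fitter(tr_mets, tr_samples):
        m = fit_elastic_net_age(tr_mets, tr_samples["age"].astype(float),
                                alpha=mc.alpha, cv_folds=mc.cv_folds, seed=seed)
        return lambda mm: predict(m, mm)

    def mars_fitter(tr_mets, tr_samples):
        m = fit_mars_age(tr_mets, tr_samples["age"].astype(float),
                         max_terms=mc.mars_max_terms,
                         gcv_penalty=mc.gcv_penalty, max_knots=mc.mars_max_knots)
        return lambda mm: predict(m, mm)

    # study-wide penalty factors, as produced by the train stage: the
    # mortality-informed weights are a property of the study MWAS, reused
    # across folds exactly as the pruned variable set is
    factors = pd.read_csv(out / "penalty_factors.tsv", sep="\t",
                          index_col=0)["penalty_factor"]

    def pheno_fitter(tr_mets, tr_samples):
        m = fit_phenotypic_age(tr_mets, tr_samples["age"].astype(float),
                               factors, alpha=mc.alpha, cv_folds=mc.cv_folds,
                               seed=seed)
        return lambda mm: predict(m, mm)

    fitters = {"elastic_net": enet_fitter, "mars": mars_fitter,
               "phenotypic_age": pheno_fitter}
    performance = {}
    for name, fitter in fitters.items():
        for scheme in (CvScheme("kfold", cfg.cv.k), CvScheme("loco")):
            oof, report = cross_validate(fitter, x, samples, scheme, seed=seed)
            tag = f"{name}_{scheme.kind}"
            oof.to_csv(out / f"oof_{tag}.csv", float_format="%.17g")
            performance[tag] = report.to_dict()
    _write_json(out / "performance.json", performance)

    # longitudinal check and age-adjusted associations use full-model scores
    from .clocks import model_from_json

    associations = []
    delta_rows = []
    for name in ("elastic_net", "mars", "phenotypic_age", "mortality_score"):
        loaded = model_from_json((out / "models" / f"{name}.json").read_text())
        model, scaler = loaded if isinstance(loaded, tuple) else (loaded, None)
        scores = pd.Series(predict(model, x, scaler), index=x.index, name=name)
        pairs, _, r = delta_age(scores, samples)
        if len(pairs):
            delta_rows.append({"model": name, "pearson_r_delta": r,
                               "n_pairs": len(pairs)})
        a = associate_risk_factor(scores, samples, "smoking")
        associations.append({"model": name, "outcome": "smoking",
                             "estimate": a.estimate, "se": a.se, "p": a.p,
                             "n": a.n, "adjusted_for": ",".join(a.adjusted_for)})
        inc = associate_incident(scores, samples, label="all-cause mortality")
        associations.append({"model": name, "outcome": "all-cause mortality",
                             "estimate": inc.estimate, "se": inc.se, "p": inc.p,
                             "n": inc.n, "n_events": inc.n_events,
                             "hr_per_year": float(np.exp(inc.estimate)),
                             "adjusted_for": ",".join(inc.adjusted_for)})
    pd.DataFrame(associations).to_csv(out / "associations.tsv", sep="\t", index=False)
    pd.DataFrame(delta_rows).to_csv(out / "delta_age.tsv", sep="\t", index=False)

    lines = ["metaboclock run report", "======================", ""]
    for tag, rep in performance.items():
        lines.append(f"{tag}: r = {rep['pearson_r']:.3f}, MAE = {rep['mae']:.2f} y")
    lines.append("")
    for a in associations:
        if a["outcome"] == "all-cause mortality":
            lines.append(
                f"{a['model']} vs mortality: HR/yr = {a['hr_per_year']:.4f}, "
                f"p = {a['p']:.2e}"
            )
    (out / "report.txt").write_text("\n".join(lines) + "\n")


_STAGE_FNS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "mwas": stage_mwas,
    "prune": stage_prune,
    "train": stage_train,
    "evaluate": stage_evaluate,
}


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    stages: list[str] | None = None,
) -> Path:
    """Run the stage sequence, writing artifacts and a checksum manifest.

    Returns the artifact directory. Any stage error aborts with the stage
    name and the last good artifact state.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    todo = stages if stages is not None else STAGES
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    last_good = "none"
    for stage in STAGES:
        if stage not in todo:
            continue
        try:
            _STAGE_FNS[stage](config, out)
        except Exception as exc:  # noqa: BLE001 — report stage context
            raise StageError(stage, last_good, exc) from exc
        last_good = stage
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "stages": todo,
        "checksums": {
            p.relative_to(out).as_posix(): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    _write_json(out / "manifest.json", manifest)
    return out
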