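"""End-to-end analysis pipeline: cohort in, report tables out.

Stages: load or simulate a cohort -> apply exclusions (missing outcome,
missing MMA, missing OBS components, in that order) -> score the OBS and
dichotomize it -> choose the mediator cutoff from the RCS inflection ->
weighted descriptives -> Model I/II odds-ratio tables for exposure ->
outcome, mediator -> outcome and exposure -> mediator -> mediation with
subgroups -> exposure x mediator interaction -> optional
multiple-imputation sensitivity rerun pooled by Rubin's rules.

Everything is reproducible from the config plus one seed; the report
carries provenance (config hash, seed, per-stage sample sizes).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import patsy
import yaml
from sklearn.linear_model import LinearRegression, LogisticRegression

from .mediation import MediationAnalysis
from .obs import OBSScorer, dichotomize_obs, first_tertile_cutoff, load_registry
from .rcs import RCSLogisticRegression, choose_cutoff
from .survey import (GLMFit, SurveyDesign, fit_weighted_logistic, odds_ratios,
                     rao_scott_chisq, wald_interaction_test, weighted_mean_se)
from .synthetic import TruthParams, generate_cohort, inject_missingness, read_cohort

logger = logging.getLogger(__name__)

MODEL1_COVARIATES = ("age", "gender", "race")
MODEL2_COVARIATES = MODEL1_COVARIATES + (
    "education", "pir_group", "diabetes", "dyslipidemia", "wbc", "energy")

IMPUTABLE_COLUMNS = ("education", "wbc", "vitamin_b12")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_full_analysis` (YAML-mappable)."""

    input: str | None = None
    synthetic: dict | None = None
    registry: str | None = None
    model1_covariates: tuple = MODEL1_COVARIATES
    model2_covariates: tuple = MODEL2_COVARIATES
    obs_cutoff: float | None = None       # None: first tertile of the score
    weighted_tertiles: bool = False
    mediator_column: str = "mma"
    cutoff_policy: str = "nearest_quantile_median"
    nonlinearity_alpha: float = 0.05   # inflection trusted only below this
    n_knots: int = 4
    subgroups: tuple = ("dyslipidemia", "diabetes")
    imputation_enabled: bool = False
    imputation_m: int = 5
    dop_draws: int = 10 ** 6
    single_psu: str = "error"
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if not set(self.model1_covariates) <= set(self.model2_covariates):
            raise ValueError("Model I covariates must be a subset of Model II's")
        if self.imputation_m < 1:
            raise ValueError("imputation_m must be >= 1")
        if (self.input is None) == (self.synthetic is None):
            raise ValueError("exactly one of `input` or `synthetic` must be given")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def apply_exclusions(cohort: pd.DataFrame, component_names: list[str],
                     outcome: str = "cvd", mma: str = "mma"
                     ) -> tuple[pd.DataFrame, dict]:
    """Drop rows missing the outcome, then MMA, then any OBS component.

    Each row is counted once, under the first criterion (in that order)
    it trips.  Returns the analytic cohort and the exclusion log.
    """
    log = {"input_n": int(len(cohort))}
    miss_outcome = cohort[outcome].isna()
    miss_mma = cohort[mma].isna() & ~miss_outcome
    miss_obs = (cohort[component_names].isna().any(axis=1)
                & ~miss_outcome & ~miss_mma)
    log["missing_outcome"] = int(miss_outcome.sum())
    log["missing_mma"] = int(miss_mma.sum())
    log["missing_obs_component"] = int(miss_obs.sum())
    keep = ~(miss_outcome | miss_mma | miss_obs)
    analytic = cohort.loc[keep].reset_index(drop=True)
    log["analytic_n"] = int(len(analytic))
    if analytic.empty:
        raise PipelineError("exclusions removed every participant")
    return analytic, log


def _dummy_frame(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Numeric predictor matrix (treatment-coded categoricals, no intercept)."""
    dm = patsy.dmatrix(" + ".join(cols), df, return_type="dataframe",
                       NA_action=patsy.NAAction(on_NA="raise"))
    return dm.drop(columns="Intercept")


def impute_missing(cohort: pd.DataFrame, m: int = 5,
                   method: str = "chained_regression", seed: int = 0,
                   columns: tuple = IMPUTABLE_COLUMNS,
                   cycles: int = 10) -> list[pd.DataFrame]:
    """Chained-regression multiple imputation for education/WBC/vitamin B12.

    Continuous columns are imputed by linear regression plus a stochastic
    normal residual draw; the categorical education column by a
    multinomial-logit category draw.  Observed cells are never modified.
    """
    if method != "chained_regression":
        raise ValueError(f"unsupported imputation method {method!r}")
    if m < 1:
        raise ValueError("m must be >= 1")
    predictors = ["age", "gender", "race", "diabetes", "dyslipidemia", "energy"]
    masks = {c: cohort[c].isna() for c in columns if c in cohort.columns}
    for c, mask in masks.items():
        if mask.mean() > 0.5:
            logger.warning("column %s is >50%% missing; imputations will be weak", c)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(m):
        df = cohort.copy()
        # initial fill: mode / mean
        for c, mask in masks.items():
            if mask.any():
                if df[c].dtype == object:
                    df.loc[mask, c] = df[c].mode().iloc[0]
                else:
                    df.loc[mask, c] = df[c].mean()
        for _cycle in range(cycles):
            changed = False
            for c, mask in masks.items():
                if not mask.any():
                    continue
                changed = True
                other = [o for o in masks if o != c]
                X = _dummy_frame(df, predictors + other).to_numpy()
                X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0,
                                                    X.std(axis=0), 1.0)
                obs = ~mask.to_numpy()
                if df[c].dtype == object:
                    # weakly regularized multinomial logit; imputation model only
                    clf = LogisticRegression(C=100.0, max_iter=1000)
                    clf.fit(X[obs], df.loc[obs, c])
                    proba = clf.predict_proba(X[~obs])
                    cum = proba.cumsum(axis=1)
                    u = rng.random(proba.shape[0])[:, None]
                    pick = (u > cum).sum(axis=1)
                    df.loc[mask, c] = clf.classes_[pick]
                else:
                    y = df.loc[obs, c].to_numpy(dtype=float)
                    reg = LinearRegression().fit(X[obs], y)
                    resid_sd = float(np.std(y - reg.predict(X[obs]), ddof=X.shape[1] + 1))
                    pred = reg.predict(X[~obs])
                    df.loc[mask, c] = pred + rng.normal(0.0, resid_sd, pred.size)
            if not changed:
                break
        out.append(df)
    return out


@dataclass
class PooledGLMFit(GLMFit):
    """Rubin-pooled fit; ``df`` holds per-term Rubin degrees of freedom."""

    df: np.ndarray | None = None


def rubin_pool(fits: list[GLMFit]) -> PooledGLMFit:
    """Combine m fits by Rubin's rules.

    Pooled coefficient = mean; pooled covariance = mean within-covariance
    plus (1 + 1/m) times the between-imputation covariance; per-term
    degrees of freedom by the standard (m-1)(1 + W/((1+1/m)B))^2 formula.
    """
    if not fits:
        raise ValueError("no fits to pool")
    terms = fits[0].terms
    for f in fits[1:]:
        if f.terms != terms:
            raise ValueError(f"term sets differ: {terms} vs {f.terms}")
    m = len(fits)
    params = np.stack([f.params for f in fits])
    W = np.mean([f.cov for f in fits], axis=0)
    pooled = params.mean(axis=0)
    if m == 1:
        T = W
        df = np.full(len(terms), np.inf)
    else:
        dev = params - pooled
        B = dev.T @ dev / (m - 1)
        T = W + (1 + 1 / m) * B
        with np.errstate(divide="ignore"):
            r = (1 + 1 / m) * np.diag(B) / np.diag(W)
            df = (m - 1) * (1 + 1 / np.where(r > 0, r, np.inf)) ** 2
    return PooledGLMFit(terms=list(terms), params=pooled, cov=T,
                        n=fits[0].n, converged=all(f.converged for f in fits),
                        loglike=float(np.mean([f.loglike for f in fits])),
                        design_df=fits[0].design_df, df=df)


def weighted_descriptives(df: pd.DataFrame, design: SurveyDesign,
                          continuous: list[str], categorical: list[str],
                          by: str = "cvd") -> pd.DataFrame:
    """Weighted means (SE) for continuous and weighted % for categorical
    variables, overall and by outcome group, with design-adjusted p-values."""
    groups = {"overall": np.ones(len(df), bool)}
    for lev in sorted(df[by].dropna().unique(), key=str):
        groups[f"{by}={lev}"] = (df[by] == lev).to_numpy()
    rows = []
    for var in continuous:
        row = {"variable": var, "type": "continuous"}
        for gname, gmask in groups.items():
            mean, se = weighted_mean_se(df.loc[gmask, var], design.subset(gmask))
            row[gname] = f"{mean:.2f} ({se:.2f})"
        try:
            # two-group weighted mean comparison via a design-based z test
            g1, g2 = list(groups)[1], list(groups)[2]
            m1, s1 = weighted_mean_se(df.loc[groups[g1], var], design.subset(groups[g1]))
            m2, s2 = weighted_mean_se(df.loc[groups[g2], var], design.subset(groups[g2]))
            from scipy.stats import norm as _norm
            z = (m1 - m2) / np.hypot(s1, s2)
            row["p"] = float(2 * _norm.sf(abs(z)))
        except (IndexError, ValueError):
            row["p"] = np.nan
        rows.append(row)
    for var in categorical:
        stat_p = np.nan
        try:
            _, stat_p = rao_scott_chisq(df[var], df[by], design)
        except ValueError as exc:
            logger.warning("Rao-Scott test skipped for %s: %s", var, exc)
        for lev in sorted(df[var].dropna().unique(), key=str):
            row = {"variable": f"{var}={lev}", "type": "categorical", "p": stat_p}
            ind = (df[var] == lev).astype(float)
            for gname, gmask in groups.items():
                w = design.weight[gmask]
                row[gname] = f"{100 * np.sum(w * ind[gmask]) / np.sum(w):.2f}%"
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    """All pipeline outputs plus provenance; serializable to JSON/CSVs."""

    provenance: dict
    exclusions: dict
    obs_cutoff: float
    mma_cutoff: float
    rcs: dict
    descriptive: pd.DataFrame
    or_tables: dict[str, pd.DataFrame]
    mediation: pd.DataFrame
    mediation_details: list[dict]
    interaction: dict
    mi_sensitivity: dict | None = None
    rcs_curve: pd.DataFrame | None = field(default=None, repr=False)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not serializable: {type(o)}")
        d = {k: getattr(self, k) for k in
             ("provenance", "exclusions", "obs_cutoff", "mma_cutoff", "rcs",
              "descriptive", "or_tables", "mediation", "mediation_details",
              "interaction", "mi_sensitivity")}
        return json.dumps(d, default=enc, sort_keys=True, indent=2,
                          allow_nan=True)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        self.descriptive.to_csv(outdir / "descriptive.csv", index=False)
        for name, tab in self.or_tables.items():
            tab.round({"OR": 2, "ci_low": 2, "ci_high": 2, "p": 4}).to_csv(
                outdir / f"or_{name}.csv")
        med = self.mediation.copy()
        for c in ("total_or", "direct_or", "indirect_or", "indirect_lo", "indirect_hi"):
            med[c] = med[c].round(2)
        med["mediated_pct"] = med["mediated_pct"].round(1)
        med.to_csv(outdir / "mediation.csv", index=False)
        pd.DataFrame([self.interaction]).to_csv(outdir / "interaction.csv", index=False)
        if self.rcs_curve is not None:
            self.rcs_curve.to_csv(outdir / "rcs_curve.csv", index=False)


def _or_row(fit: GLMFit, term: str) -> pd.DataFrame:
    return odds_ratios(fit).loc[[term]]


def run_full_analysis(config: PipelineConfig) -> AnalysisReport:
    """Execute the whole analysis chain described in the module docstring."""
    config.validate()
    stage = "load"
    try:
        registry = load_registry(config.registry)
        comp_names = [s.name for s in registry]
        if config.synthetic is not None:
            sp = dict(config.synthetic)
            sp.setdefault("seed", config.seed)
            params = TruthParams(**sp)
            cohort = generate_cohort(params)
            if params.missing_rates:
                cohort = inject_missingness(cohort, params.missing_rates,
                                            seed=params.seed + 1)
        else:
            cohort = read_cohort(config.input)

        stage = "exclusions"
        analytic, excl = apply_exclusions(cohort, comp_names)
        design = SurveyDesign.from_frame(analytic)

        stage = "obs_scoring"
        weight_col = "weight" if config.weighted_tertiles else None
        scorer = OBSScorer(registry=registry)
        scored = scorer.fit_transform(analytic) if weight_col is None else \
            scorer.fit(analytic, weight_col=weight_col).transform(analytic)
        analytic = analytic.join(scored[["obs_total"]])
        cutoff = (config.obs_cutoff if config.obs_cutoff is not None
                  else first_tertile_cutoff(analytic["obs_total"]))
        analytic["obs_group"] = dichotomize_obs(analytic["obs_total"], cutoff)
        analytic["obs_low"] = (analytic["obs_group"] == "low").astype(int)

        stage = "rcs"
        cov2 = [c for c in config.model2_covariates]
        cc2 = analytic[cov2].notna().all(axis=1).to_numpy()
        rcs_est = RCSLogisticRegression(n_knots=config.n_knots,
                                        single_psu=config.single_psu)
        rcs_est.fit(analytic.loc[cc2, config.mediator_column].to_numpy(),
                    analytic.loc[cc2, "cvd"].to_numpy(),
                    covariates=_dummy_frame(analytic.loc[cc2].reset_index(drop=True), cov2),
                    design=design.subset(cc2))
        if (rcs_est.inflection_ is not None
                and rcs_est.p_nonlinear_ < config.nonlinearity_alpha):
            mma_cutoff = choose_cutoff(rcs_est.inflection_,
                                       analytic[config.mediator_column],
                                       config.cutoff_policy)
        else:
            # monotone curve, or no evidence of nonlinearity: a detected
            # slope reversal is noise, so fall back to the median
            logger.info("no significant nonlinearity; dichotomizing the "
                        "mediator at its median")
            mma_cutoff = float(analytic[config.mediator_column].median())
        analytic["mma_high"] = (analytic[config.mediator_column] >= mma_cutoff).astype(int)

        stage = "descriptives"
        descriptive = weighted_descriptives(
            analytic, design,
            continuous=["age", "wbc", "energy", "bmi", config.mediator_column,
                        "obs_total"],
            categorical=["gender", "race", "education", "pir_group", "diabetes",
                         "dyslipidemia", "obs_group"])

        stage = "models"
        cov1 = list(config.model1_covariates)
        or_tables = {}
        fits = {}
        for name, outcome, term, covs in (
                ("obs_cvd_model1", "cvd", "obs_low", cov1),
                ("obs_cvd_model2", "cvd", "obs_low", cov2),
                ("mma_cvd_model1", "cvd", "mma_high", cov1),
                ("mma_cvd_model2", "cvd", "mma_high", cov2),
                ("obs_mma_model1", "mma_high", "obs_low", cov1),
                ("obs_mma_model2", "mma_high", "obs_low", cov2)):
            f = fit_weighted_logistic(
                analytic, f"{outcome} ~ {' + '.join([term] + covs)}", design,
                single_psu=config.single_psu)
            fits[name] = f
            or_tables[name] = _or_row(f, term)

        stage = "mediation"
        med = MediationAnalysis(
            exposure="obs_low", mediator="mma_high", outcome="cvd",
            covariates=tuple(cov2), subgroup=None, draws=config.dop_draws,
            seed=config.seed + 2, single_psu=config.single_psu)
        med.fit(analytic, design)
        results = list(med.results_)
        for sub in config.subgroups:
            sub_med = MediationAnalysis(
                exposure="obs_low", mediator="mma_high", outcome="cvd",
                covariates=tuple(c for c in cov2 if c != sub), subgroup=sub,
                draws=config.dop_draws, seed=config.seed + 2,
                single_psu=config.single_psu)
            sub_med.fit(analytic, design)
            results.extend(sub_med.results_[1:])  # keep only subgroup rows
        med.results_ = results
        mediation_table = med.summary()

        stage = "interaction"
        inter_formula = ("cvd ~ obs_low + mma_high + obs_low:mma_high + "
                         + " + ".join(cov2))
        f_int = fit_weighted_logistic(analytic, inter_formula, design,
                                      single_psu=config.single_psu)
        est, p = wald_interaction_test(f_int, "obs_low:mma_high")
        ortab = odds_ratios(f_int).loc["obs_low:mma_high"]
        interaction = {"term": "obs_low:mma_high", "log_or": est,
                       "OR": float(ortab["OR"]), "ci_low": float(ortab["ci_low"]),
                       "ci_high": float(ortab["ci_high"]), "p": p,
                       "n": f_int.n}

        mi = None
        if config.imputation_enabled:
            stage = "mi_sensitivity"
            imputed = impute_missing(analytic, m=config.imputation_m,
                                     seed=config.seed + 3)
            mi = {}
            for name, outcome, term in (("obs_cvd_model2", "cvd", "obs_low"),
                                        ("mma_cvd_model2", "cvd", "mma_high"),
                                        ("obs_mma_model2", "mma_high", "obs_low")):
                per = [fit_weighted_logistic(
                    dfi, f"{outcome} ~ {' + '.join([term] + cov2)}", design,
                    single_psu=config.single_psu) for dfi in imputed]
                pooled = rubin_pool(per)
                mi[name] = _or_row(pooled, term).iloc[0].to_dict() | {"m": len(per)}

        provenance = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "input_n": excl["input_n"],
            "analytic_n": excl["analytic_n"],
            "model_ns": {k: v.n for k, v in fits.items()},
            "mediation_ns": {r.label: r.n for r in results},
        }
        report = AnalysisReport(
            provenance=provenance, exclusions=excl,
            obs_cutoff=float(cutoff), mma_cutoff=float(mma_cutoff),
            rcs={"knots": rcs_est.knots_.tolist(),
                 "p_overall": rcs_est.p_overall_,
                 "p_nonlinear": rcs_est.p_nonlinear_,
                 "inflection": rcs_est.inflection_,
                 "n": rcs_est.fit_.n},
            descriptive=descriptive, or_tables=or_tables,
            mediation=mediation_table,
            mediation_details=[r.to_dict() for r in results],
            interaction=interaction, mi_sensitivity=mi,
            rcs_curve=rcs_est.curve_frame())
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    if config.output_dir:
        report.save(config.output_dir)
    return report
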