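"""Product-of-coefficients mediation for binary exposure/mediator/outcome.

Three survey-weighted logistic regressions on a common analytic sample
give the paths (all on the log-odds scale):

* ``c``  — total effect: outcome ~ exposure + covariates
* ``a``  — exposure on mediator: mediator ~ exposure + covariates
* ``b``, ``c'`` — outcome ~ exposure + mediator + covariates

The indirect effect is the product a*b.  Its confidence interval comes
from the distribution-of-product method: the empirical quantiles of
Z1*Z2 with Z1 ~ N(a, se_a^2), Z2 ~ N(b, se_b^2) independent, by seeded
Monte Carlo.  Mediation is declared when that interval excludes 0
(equivalently, the indirect-effect OR interval excludes 1).  The
mediated proportion is a*b/c, the indirect share of the total effect on
the log-OR scale.

Because log-odds ratios are non-collapsible for binary outcomes, c need
not equal c' + a*b exactly; the decomposition gap c - (c' + a*b) is
always reported rather than hidden.  A normal-theory Sobel interval
(a*b +/- z*sqrt(a^2 se_b^2 + b^2 se_a^2)) is reported alongside for
reference; the two agree when both paths are many SEs from zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survey import ConvergenceError, GLMFit, SurveyDesign, fit_weighted_logistic

logger = logging.getLogger(__name__)


@dataclass
class PathEstimates:
    """Raw path coefficients and SEs from the three model fits."""

    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    c_prime: float
    se_c_prime: float
    n: int
    fits: dict[str, GLMFit] = field(default_factory=dict, repr=False)


@dataclass
class MediationResult:
    """Full mediation summary for one (sub)population."""

    label: str
    n: int
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    c_prime: float
    se_c_prime: float
    ab: float
    ab_ci: tuple[float, float]
    sobel_ci: tuple[float, float]
    proportion_mediated: float
    inconsistent: bool
    decomposition_gap: float

    @property
    def indirect_or(self) -> float:
        return float(np.exp(self.ab))

    @property
    def indirect_or_ci(self) -> tuple[float, float]:
        return (float(np.exp(self.ab_ci[0])), float(np.exp(self.ab_ci[1])))

    @property
    def mediation_present(self) -> bool:
        lo, hi = self.ab_ci
        return not (lo <= 0.0 <= hi)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("label", "n", "a", "se_a", "b", "se_b", "c", "se_c",
              "c_prime", "se_c_prime", "ab", "proportion_mediated",
              "inconsistent", "decomposition_gap")}
        d["ab_ci"] = list(self.ab_ci)
        d["sobel_ci"] = list(self.sobel_ci)
        d["indirect_or"] = self.indirect_or
        d["indirect_or_ci"] = list(self.indirect_or_ci)
        d["total_or"] = float(np.exp(self.c))
        d["direct_or"] = float(np.exp(self.c_prime))
        d["mediation_present"] = self.mediation_present
        return d


def _require_binary(df: pd.DataFrame, col: str) -> None:
    vals = df[col].dropna().unique()
    if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
        raise ValueError(f"column {col!r} must be binary 0/1, found {vals[:5]}")


def estimate_paths(cohort: pd.DataFrame, exposure: str, mediator: str,
                   outcome: str, covariates: list[str] | tuple = (),
                   design: SurveyDesign | None = None,
                   align_rows: bool = True, **fit_kwargs) -> PathEstimates:
    """Fit the three path models on a common complete-case sample."""
    for col in (exposure, mediator, outcome):
        _require_binary(cohort, col)
    used = [outcome, exposure, mediator, *covariates]
    complete = cohort[used].notna().all(axis=1).to_numpy()
    if not align_rows and complete.sum() != len(cohort):
        raise ValueError(
            "analytic samples differ across path models; pass align_rows=True "
            "to fit on the complete-case intersection")
    data = cohort.loc[complete].reset_index(drop=True)
    if design is None:
        design = SurveyDesign.unclustered(len(cohort))
    d = design.subset(complete)

    rhs = " + ".join([exposure, *covariates]) if covariates else exposure
    fit_c = fit_weighted_logistic(data, f"{outcome} ~ {rhs}", d, **fit_kwargs)
    fit_a = fit_weighted_logistic(data, f"{mediator} ~ {rhs}", d, **fit_kwargs)
    fit_b = fit_weighted_logistic(data, f"{outcome} ~ {rhs} + {mediator}", d, **fit_kwargs)
    return PathEstimates(
        a=fit_a.coef(exposure), se_a=fit_a.se(exposure),
        b=fit_b.coef(mediator), se_b=fit_b.se(mediator),
        c=fit_c.coef(exposure), se_c=fit_c.se(exposure),
        c_prime=fit_b.coef(exposure), se_c_prime=fit_b.se(exposure),
        n=int(len(data)),
        fits={"total": fit_c, "mediator": fit_a, "outcome": fit_b},
    )


def distribution_of_product_ci(a: float, se_a: float, b: float, se_b: float,
                               alpha: float = 0.05, draws: int = 10 ** 6,
                               seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo distribution-of-product interval for the indirect effect.

    Quantiles alpha/2 and 1-alpha/2 of Z1*Z2, Z1 ~ N(a, se_a^2) and
    Z2 ~ N(b, se_b^2) independent; deterministic given ``seed``.
    """
    vals = [a, se_a, b, se_b]
    if not all(np.isfinite(vals)):
        raise ValueError(f"path inputs must be finite, got {vals}")
    if se_a <= 0 or se_b <= 0:
        raise ValueError("path standard errors must be positive")
    if draws < 10 ** 4:
        warnings.warn(f"draws={draws} is below 1e4; quantiles will be noisy",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    prod = rng.normal(a, se_a, draws) * rng.normal(b, se_b, draws)
    lo, hi = np.quantile(prod, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def sobel_ci(a: float, se_a: float, b: float, se_b: float,
             alpha: float = 0.05) -> tuple[float, float]:
    """First-order (Sobel) normal-theory interval for a*b."""
    se = np.sqrt(a * a * se_b * se_b + b * b * se_a * se_a)
    z = stats.norm.ppf(1 - alpha / 2)
    return float(a * b - z * se), float(a * b + z * se)


def mediated_proportion(ab: float, c: float) -> float:
    """Indirect over total effect on the log-OR scale (ab / c).

    Raises for c = 0; a sign-discordant ratio (suppression) is returned
    as-is — callers flag it via :attr:`MediationResult.inconsistent`.
    """
    if c == 0:
        raise ZeroDivisionError("total effect c is zero; mediated proportion undefined")
    return float(ab / c)


class MediationAnalysis:
    """Estimator running the full distribution-of-product mediation analysis.

    Parameters name the binary exposure/mediator/outcome columns and the
    adjustment covariates; ``subgroup`` optionally names a categorical
    column, producing one result for the total sample plus one per
    observed level (models refit within each level; exposure/mediator
    cutoffs are whatever the supplied columns already encode, i.e.
    global).  ``fit`` populates ``results_`` (list of
    :class:`MediationResult`, total first).
    """

    def __init__(self, exposure: str, mediator: str, outcome: str,
                 covariates: tuple = (), subgroup: str | None = None,
                 alpha: float = 0.05, draws: int = 10 ** 6, seed: int = 0,
                 single_psu: str = "error"):
        self.exposure = exposure
        self.mediator = mediator
        self.outcome = outcome
        self.covariates = tuple(covariates)
        self.subgroup = subgroup
        self.alpha = alpha
        self.draws = draws
        self.seed = seed
        self.single_psu = single_psu

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("exposure", "mediator", "outcome", "covariates", "subgroup",
                 "alpha", "draws", "seed", "single_psu")}

    def set_params(self, **kw) -> "MediationAnalysis":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _one(self, cohort: pd.DataFrame, design: SurveyDesign,
             label: str) -> MediationResult:
        paths = estimate_paths(cohort, self.exposure, self.mediator,
                               self.outcome, self.covariates, design,
                               single_psu=self.single_psu)
        ab = paths.a * paths.b
        ab_ci = distribution_of_product_ci(paths.a, paths.se_a, paths.b,
                                           paths.se_b, self.alpha, self.draws,
                                           self.seed)
        prop = mediated_proportion(ab, paths.c)
        return MediationResult(
            label=label, n=paths.n,
            a=paths.a, se_a=paths.se_a, b=paths.b, se_b=paths.se_b,
            c=paths.c, se_c=paths.se_c,
            c_prime=paths.c_prime, se_c_prime=paths.se_c_prime,
            ab=ab, ab_ci=ab_ci,
            sobel_ci=sobel_ci(paths.a, paths.se_a, paths.b, paths.se_b, self.alpha),
            proportion_mediated=prop,
            inconsistent=bool(np.sign(ab) * np.sign(paths.c) < 0),
            decomposition_gap=float(paths.c - (paths.c_prime + ab)),
        )

    def fit(self, cohort: pd.DataFrame, design: SurveyDesign | None = None
            ) -> "MediationAnalysis":
        if design is None:
            design = SurveyDesign.unclustered(len(cohort))
        results = [self._one(cohort, design, "total")]
        if self.subgroup is not None:
            levels = pd.unique(cohort[self.subgroup].dropna())
            for lev in sorted(levels, key=str):
                mask = (cohort[self.subgroup] == lev).to_numpy()
                sub = cohort.loc[mask].reset_index(drop=True)
                try:
                    results.append(self._one(sub, design.subset(mask),
                                             f"{self.subgroup}={lev}"))
                except (ValueError, ConvergenceError, ZeroDivisionError) as exc:
                    logger.warning("skipping subgroup %s=%r: %s",
                                   self.subgroup, lev, exc)
        self.results_ = results
        return self

    def summary(self) -> pd.DataFrame:
        """One row per (sub)population, shaped like a mediation report table."""
        rows = []
        for r in self.results_:
            rows.append({
                "group": r.label, "n": r.n,
                "total_or": r.to_dict()["total_or"],
                "direct_or": r.to_dict()["direct_or"],
                "dop_beta": r.ab, "dop_lo": r.ab_ci[0], "dop_hi": r.ab_ci[1],
                "indirect_or": r.indirect_or,
                "indirect_lo": r.indirect_or_ci[0],
                "indirect_hi": r.indirect_or_ci[1],
                "mediated_pct": 100 * r.proportion_mediated,
                "mediation_present": r.mediation_present,
            })
        return pd.DataFrame(rows)


def run_mediation(cohort: pd.DataFrame, exposure: str, mediator: str,
                  outcome: str, covariates: tuple = (),
                  design: SurveyDesign | None = None,
                  subgroup: str | None = None, **kwargs) -> list[MediationResult]:
    """Functional wrapper over :class:`MediationAnalysis`; returns results."""
    est = MediationAnalysis(exposure, mediator, outcome, covariates,
                            subgroup=subgroup, **kwargs)
    est.fit(cohort, design)
    return est.results_
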