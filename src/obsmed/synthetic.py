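"""Synthetic hypertensive survey cohorts with a known mediation structure.

The generator emulates a national-health-survey cohort: a stratified
two-stage design (strata x PSUs with per-person sampling weights),
gender-specific right-skewed intake distributions for the 20 OBS
components, serum methylmalonic acid (MMA), and a self-reported CVD
outcome.  The causal structure is exposure -> mediator -> outcome with a
direct path:

* the *latent low-OBS* indicator ``L`` is the bottom tertile of the true
  OBS computed from the generated component values;
* ``L`` shifts the log-normal MMA distribution upward so that
  dichotomizing MMA at its median yields a log-odds ratio of ``alpha_m``
  (path a) for ``L`` on high MMA;
* CVD follows a logistic model with direct effect ``gamma_direct``
  (path c') for ``L``, effect ``beta_m`` (path b) for latent high MMA,
  plus covariate effects; the intercept is calibrated so the expected
  CVD prevalence equals ``baseline_prevalence``.

Weights are drawn independently of everything else, so weighted and
unweighted estimands coincide in truth and parameter recovery can be
tested.  Default parameters mirror the analytic conditions of a
hypertensive NHANES 2011-2014 cohort: n=4137, CVD prevalence 0.1963,
path odds ratios 1.32 (a), 1.34 (b) and 1.50 (c').
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .obs import OBSScorer, first_tertile_cutoff, load_registry

DIETARY_COMPONENTS = [
    "fiber", "carotene", "riboflavin", "niacin", "vitamin_b6", "total_folate",
    "vitamin_b12_diet", "vitamin_c", "vitamin_e", "calcium", "magnesium",
    "zinc", "copper", "selenium", "total_fat", "iron",
]

# daily-intake scales (median of the log-normal) per dietary component
_DIETARY_SCALE = {
    "fiber": 16.0, "carotene": 2000.0, "riboflavin": 2.0, "niacin": 24.0,
    "vitamin_b6": 2.0, "total_folate": 400.0, "vitamin_b12_diet": 5.0,
    "vitamin_c": 80.0, "vitamin_e": 8.0, "calcium": 900.0, "magnesium": 300.0,
    "zinc": 11.0, "copper": 1.2, "selenium": 110.0, "total_fat": 80.0,
    "iron": 14.0,
}

ANALYSIS_COLUMNS = (
    ["id", "age", "gender", "race", "education", "pir_group", "diabetes",
     "dyslipidemia", "wbc", "vitamin_b12", "energy", "weight", "stratum", "psu"]
    + DIETARY_COMPONENTS
    + ["met_score", "cotinine", "alcohol_g_day", "bmi", "mma", "cvd"]
)
LATENT_COLUMNS = ["latent_low_obs", "latent_high_mma"]

COLUMN_DESCRIPTIONS = {
    "id": "participant identifier",
    "age": "age in years",
    "gender": "male/female",
    "race": "5-level race/ethnicity category",
    "education": "3-level education category",
    "pir_group": "poverty-income ratio group: lt1, ge1, unknown",
    "diabetes": "diabetes flag (0/1)",
    "dyslipidemia": "dyslipidemia flag (0/1)",
    "wbc": "white blood cell count, 1000 cells/uL",
    "vitamin_b12": "serum vitamin B12, pmol/L",
    "energy": "total energy intake, kcal/day",
    "weight": "survey sampling weight",
    "stratum": "sampling stratum",
    "psu": "primary sampling unit within stratum",
    "met_score": "physical activity, MET-minutes/week",
    "cotinine": "serum cotinine, ng/mL (tobacco exposure)",
    "alcohol_g_day": "alcohol intake, g/day",
    "bmi": "body mass index, kg/m^2",
    "mma": "serum methylmalonic acid, nmol/L",
    "cvd": "self-reported cardiovascular disease (0/1)",
    "latent_low_obs": "generator truth: bottom OBS tertile indicator",
    "latent_high_mma": "generator truth: MMA above the calibrated threshold",
}
COLUMN_DESCRIPTIONS.update({c: "dietary intake component (per day)"
                            for c in DIETARY_COMPONENTS})

_COVARIATE_KEYS = ("age10", "male", "diabetes", "dyslipidemia", "wbc", "log_energy")


def _default_covariate_effects() -> dict[str, float]:
    # log-ORs on CVD for (age per decade, male sex, diabetes, dyslipidemia)
    return {"age10": 0.40, "male": 0.26,
            "diabetes": 0.59, "dyslipidemia": 0.34}


def _default_missing_rates() -> dict[str, float]:
    return {"education": 0.03, "wbc": 0.05, "vitamin_b12": 0.05}


@dataclass
class TruthParams:
    """Ground-truth parameters of the generative cohort model.

    ``alpha_m``, ``beta_m`` and ``gamma_direct`` are the latent path
    log-odds ratios a (exposure on high mediator), b (mediator on outcome
    given exposure) and c' (direct exposure on outcome).
    """

    n: int = 4137
    n_strata: int = 14
    psu_per_stratum: int = 2
    weight_range: tuple[float, float] = (8000.0, 60000.0)
    alpha_m: float = math.log(1.32)
    beta_m: float = math.log(1.34)
    gamma_direct: float = math.log(1.50)
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    baseline_prevalence: float = 0.1963
    missing_rates: dict[str, float] = field(default_factory=_default_missing_rates)
    seed: int = 0
    mma_log_median: float = math.log(150.0)
    mma_log_sd: float = 0.45

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.n_strata < 1:
            raise ValueError("n_strata must be positive")
        if self.psu_per_stratum < 1:
            raise ValueError("psu_per_stratum must be positive")
        lo, hi = self.weight_range
        if not (0 < lo <= hi):
            raise ValueError("weight_range must be positive with lo <= hi")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        for col, r in self.missing_rates.items():
            if not 0 <= r < 1:
                raise ValueError(f"missing_rates[{col!r}] must lie in [0, 1)")
        for key in self.covariate_effects:
            if key not in _COVARIATE_KEYS:
                raise ValueError(
                    f"covariate_effects key {key!r} not in {_COVARIATE_KEYS}")
        if self.mma_log_sd <= 0:
            raise ValueError("mma_log_sd must be positive")


def _empty_cohort() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in ANALYSIS_COLUMNS + LATENT_COLUMNS})
    for c in ("gender", "race", "education", "pir_group"):
        df[c] = df[c].astype(object)
    return df


def _covariate_matrix(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "age10": (df["age"].to_numpy() - 58.0) / 10.0,
        "male": (df["gender"].to_numpy() == "male").astype(float),
        "diabetes": df["diabetes"].to_numpy(dtype=float),
        "dyslipidemia": df["dyslipidemia"].to_numpy(dtype=float),
        "wbc": df["wbc"].to_numpy(dtype=float) - 7.2,
        "log_energy": np.log(df["energy"].to_numpy(dtype=float)) - math.log(2000.0),
    }


def _mma_shift(alpha: float, p_low: float, sd: float) -> tuple[float, float]:
    """Solve the MMA location shift and threshold (log scale, relative to mu).

    Returns ``(delta, t_rel)`` such that with log MMA = mu + delta*L + sd*Z
    the indicator {log MMA > mu + t_rel} has marginal rate 0.5 and a
    log-odds ratio ``alpha`` between L=1 and L=0.
    """
    if alpha == 0 or p_low in (0.0, 1.0):
        return 0.0, 0.0
    def gap(p0):
        p1 = expit(logit(p0) + alpha)
        return p_low * p1 + (1 - p_low) * p0 - 0.5
    p0 = brentq(gap, 1e-9, 1 - 1e-9, xtol=1e-12)
    p1 = expit(logit(p0) + alpha)
    q0 = norm.ppf(1 - p0)
    delta = sd * (q0 - norm.ppf(1 - p1))
    return float(delta), float(sd * q0)


def generate_cohort(params: TruthParams) -> pd.DataFrame:
    """Generate a cohort table with known mediation truth (seed-deterministic).

    The returned frame carries the analysis columns plus two latent truth
    columns (``latent_low_obs``, ``latent_high_mma``) for oracle checks.
    """
    params.validate()
    if params.n == 0:
        return _empty_cohort()
    rng = np.random.default_rng(params.seed)
    n = params.n

    df = pd.DataFrame({"id": np.arange(n)})
    df["gender"] = np.where(rng.random(n) < 0.5, "male", "female")
    df["age"] = np.clip(rng.normal(58.0, 12.0, n), 20.0, 85.0)
    df["race"] = rng.choice(
        ["mexican_american", "other_hispanic", "white", "black", "other"],
        size=n, p=[0.10, 0.10, 0.40, 0.25, 0.15])
    df["education"] = rng.choice(
        ["less_than_high_school", "high_school", "above_high_school"],
        size=n, p=[0.25, 0.25, 0.50])
    df["pir_group"] = rng.choice(["lt1", "ge1", "unknown"], size=n, p=[0.20, 0.70, 0.10])
    df["diabetes"] = (rng.random(n) < 0.30).astype(int)
    df["dyslipidemia"] = (rng.random(n) < 0.80).astype(int)
    df["wbc"] = np.clip(rng.normal(7.2, 1.9, n), 2.0, 20.0)
    df["vitamin_b12"] = np.exp(rng.normal(math.log(400.0), 0.40, n))
    male = df["gender"].to_numpy() == "male"
    df["energy"] = np.exp(rng.normal(math.log(2000.0) + 0.15 * male, 0.35, n))

    for comp in DIETARY_COMPONENTS:
        mu = math.log(_DIETARY_SCALE[comp]) + 0.20 * male
        df[comp] = np.exp(rng.normal(mu, 0.50, n))
    df["met_score"] = np.exp(rng.normal(math.log(600.0) + 0.10 * male, 0.80, n))
    smoker = rng.random(n) < 0.25
    df["cotinine"] = np.exp(np.where(smoker,
                                     rng.normal(math.log(150.0), 0.6, n),
                                     rng.normal(math.log(0.05), 1.0, n)))
    drinker = rng.random(n) < 0.60
    df["alcohol_g_day"] = np.where(drinker, np.exp(rng.normal(math.log(8.0), 1.0, n)), 0.0)
    df["bmi"] = np.clip(rng.normal(30.5, 6.0, n), 15.0, 60.0)

    # two-stage design: balanced stratum/PSU assignment, weights independent
    idx = np.arange(n)
    df["stratum"] = idx % params.n_strata
    df["psu"] = (idx // params.n_strata) % params.psu_per_stratum
    df["weight"] = rng.uniform(*params.weight_range, n)

    # latent exposure: bottom tertile of the true OBS on this sample
    scored = OBSScorer(registry=load_registry()).fit_transform(df)
    totals = scored["obs_total"]
    L = (totals < first_tertile_cutoff(totals)).to_numpy().astype(int)
    df["latent_low_obs"] = L
    p_low = float(L.mean())

    delta, t_rel = _mma_shift(params.alpha_m, p_low, params.mma_log_sd)
    log_mma = params.mma_log_median + delta * L + params.mma_log_sd * rng.standard_normal(n)
    df["mma"] = np.exp(log_mma)
    M = (log_mma > params.mma_log_median + t_rel).astype(int)
    df["latent_high_mma"] = M

    covs = _covariate_matrix(df)
    eta = params.gamma_direct * L + params.beta_m * M
    for key, eff in params.covariate_effects.items():
        eta = eta + eff * covs[key]
    b0 = brentq(lambda b: expit(b + eta).mean() - params.baseline_prevalence, -30, 30)
    df["cvd"] = (rng.random(n) < expit(b0 + eta)).astype(int)

    return df[ANALYSIS_COLUMNS + LATENT_COLUMNS]


def inject_missingness(cohort: pd.DataFrame, rates: dict[str, float],
                       mechanism: str = "MCAR", seed: int = 0) -> pd.DataFrame:
    """Blank out cells completely at random at the given per-column rates."""
    if mechanism != "MCAR":
        raise ValueError(f"unsupported missingness mechanism {mechanism!r}")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    for col, rate in rates.items():
        if col not in out.columns:
            raise KeyError(f"missingness requested for unknown column {col!r}")
        if not 0 <= rate < 1:
            raise ValueError(f"rate for {col!r} must lie in [0, 1)")
        mask = rng.random(len(out)) < rate
        if out[col].dtype.kind in "iub":
            out[col] = out[col].astype(float)
        out.loc[mask, col] = np.nan
    return out


def write_cohort(cohort: pd.DataFrame, path: str | Path,
                 data_dictionary: bool = True) -> None:
    """Write a cohort as CSV or Parquet, with a JSON data dictionary alongside."""
    path = Path(path)
    if path.suffix == ".csv":
        cohort.to_csv(path, index=False)
    elif path.suffix == ".parquet":
        cohort.to_parquet(path, index=False)
    else:
        raise ValueError(f"unsupported cohort format {path.suffix!r}")
    if data_dictionary:
        dd = {c: {"dtype": str(cohort[c].dtype),
                  "description": COLUMN_DESCRIPTIONS.get(c, "")}
              for c in cohort.columns}
        path.with_suffix(path.suffix + ".dict.json").write_text(json.dumps(dd, indent=2))


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    raise ValueError(f"unsupported cohort format {path.suffix!r}")
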