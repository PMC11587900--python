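"""Oxidative balance score (OBS) construction.

The OBS sums points over 20 components — 16 dietary and 4 lifestyle, of
which 5 are pro-oxidant and 15 antioxidant.  Every component except
alcohol is scored against gender-specific tertiles of the analytic
sample: antioxidants earn 0/1/2 points from the lowest to the highest
tertile, pro-oxidants 2/1/0.  Alcohol is scored categorically:
nondrinkers 2 points, moderate drinkers 1 (below 15 g/day for women,
30 g/day for men), heavy drinkers 0 at or above those thresholds.  The
total (0-40) is dichotomized into a low/high exposure group at the first
tertile of the score distribution (or any externally supplied cutoff).

Tie rule: a value exactly at a tertile cutoff falls in the *lower*
tertile; cutoffs are the 1/3 and 2/3 empirical quantiles (inverted-CDF
convention) computed within gender.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

PRO, ANTI = "prooxidant", "antioxidant"

#: thresholds (g/day) above which drinking is "heavy", by gender
ALCOHOL_HEAVY_G_PER_DAY = {"female": 15.0, "male": 30.0}


class DegenerateCutoffError(ValueError):
    """A gender stratum whose values are all identical has no tertiles."""


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    cls: str          # "dietary" or "lifestyle"
    direction: str    # "antioxidant" or "prooxidant"
    scoring: str = "tertile"  # or "alcohol_category"


def load_registry(path=None) -> list[ComponentSpec]:
    """Load and validate the 20-component registry (default: packaged YAML)."""
    if path is None:
        text = importlib.resources.files("obsmed").joinpath("components.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    specs = [ComponentSpec(name=r["name"], cls=r["class"],
                           direction=r["direction"],
                           scoring=r.get("scoring", "tertile"))
             for r in raw["components"]]
    _validate_registry(specs)
    return specs


def _validate_registry(specs: list[ComponentSpec]) -> None:
    if len(specs) != 20:
        raise ValueError(f"registry must hold 20 components, got {len(specs)}")
    n_diet = sum(s.cls == "dietary" for s in specs)
    n_life = sum(s.cls == "lifestyle" for s in specs)
    n_pro = sum(s.direction == PRO for s in specs)
    n_anti = sum(s.direction == ANTI for s in specs)
    n_alc = sum(s.scoring == "alcohol_category" for s in specs)
    if (n_diet, n_life) != (16, 4):
        raise ValueError(f"need 16 dietary + 4 lifestyle, got {n_diet}/{n_life}")
    if (n_pro, n_anti) != (5, 15):
        raise ValueError(f"need 5 prooxidant + 15 antioxidant, got {n_pro}/{n_anti}")
    if n_alc != 1:
        raise ValueError("exactly one component must use alcohol_category scoring")
    for s in specs:
        if s.direction not in (PRO, ANTI):
            raise ValueError(f"bad direction {s.direction!r} for {s.name}")


def _weighted_quantile(v: np.ndarray, w: np.ndarray, q: float) -> float:
    """Weighted inverted-CDF quantile: smallest v with cumulative weight >= q."""
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order]) / w.sum()
    return float(v[order][np.searchsorted(cum, q, side="left")])


def gender_tertiles(values, gender, weights=None) -> pd.DataFrame:
    """Gender-specific tertile cutoffs (1/3 and 2/3 inverted-CDF quantiles).

    ``weights`` switches to survey-weighted quantiles.  Returns a frame
    indexed by gender with columns ``lower``/``upper``.
    """
    values = np.asarray(values, dtype=float)
    gender = np.asarray(gender)
    rows = {}
    for g in pd.unique(gender):
        sel = (gender == g) & np.isfinite(values)
        v = values[sel]
        if v.size < 3:
            raise ValueError(f"need >=3 non-missing values in gender {g!r}, got {v.size}")
        if v.min() == v.max():
            raise DegenerateCutoffError(f"all values identical in gender {g!r}")
        if weights is None:
            lo, hi = np.quantile(v, [1 / 3, 2 / 3], method="inverted_cdf")
        else:
            w = np.asarray(weights, dtype=float)[sel]
            lo = _weighted_quantile(v, w, 1 / 3)
            hi = _weighted_quantile(v, w, 2 / 3)
        rows[g] = (float(lo), float(hi))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["lower", "upper"])


def tertile_of(value, lower: float, upper: float) -> np.ndarray:
    """Tertile index 0/1/2 with values <= cutoff assigned to the lower tertile."""
    value = np.asarray(value, dtype=float)
    return np.where(value <= lower, 0, np.where(value <= upper, 1, 2))


def score_component(value, lower: float, upper: float, direction: str) -> np.ndarray:
    """Points in {0,1,2}: antioxidants ascend with tertile, prooxidants descend.

    Missing values yield NaN points (participant excluded from the score).
    """
    value = np.asarray(value, dtype=float)
    t = tertile_of(value, lower, upper).astype(float)
    pts = t if direction == ANTI else 2.0 - t
    return np.where(np.isfinite(value), pts, np.nan)


def score_alcohol(grams_per_day, gender) -> np.ndarray:
    """Categorical alcohol points: 0 g/day -> 2; moderate -> 1; heavy -> 0."""
    g = np.asarray(grams_per_day, dtype=float)
    if np.any(g[np.isfinite(g)] < 0):
        raise ValueError("alcohol intake cannot be negative")
    sex = np.asarray(gender)
    thr = np.where(sex == "female", ALCOHOL_HEAVY_G_PER_DAY["female"],
                   ALCOHOL_HEAVY_G_PER_DAY["male"])
    pts = np.where(g == 0, 2.0, np.where(g < thr, 1.0, 0.0))
    return np.where(np.isfinite(g), pts, np.nan)


class OBSScorer:
    """Transformer computing the 20-component oxidative balance score.

    ``fit`` learns gender-specific tertile cutoffs for every
    tertile-scored component on the supplied (analytic) sample;
    ``transform`` emits per-component point columns ``<name>_pts``, the
    ``obs_total`` (0-40, NaN for participants missing any component) and
    the boolean ``obs_excluded`` flag.

    Parameters
    ----------
    registry : list of :class:`ComponentSpec` (default: packaged registry).
    gender_col : name of the two-level gender column.
    """

    def __init__(self, registry: list[ComponentSpec] | None = None,
                 gender_col: str = "gender"):
        self.registry = registry
        self.gender_col = gender_col

    def get_params(self, deep: bool = True) -> dict:
        return {"registry": self.registry, "gender_col": self.gender_col}

    def set_params(self, **kw) -> "OBSScorer":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _specs(self) -> list[ComponentSpec]:
        specs = self.registry if self.registry is not None else load_registry()
        _validate_registry(specs)
        return specs

    def fit(self, cohort: pd.DataFrame, y=None, weight_col: str | None = None
            ) -> "OBSScorer":
        specs = self._specs()
        missing = [s.name for s in specs if s.name not in cohort.columns]
        if missing:
            raise KeyError(f"cohort lacks component columns: {missing}")
        if self.gender_col not in cohort.columns:
            raise KeyError(f"cohort lacks gender column {self.gender_col!r}")
        levels = pd.unique(cohort[self.gender_col].dropna())
        if len(levels) != 2:
            raise ValueError(f"gender must have exactly two levels, got {list(levels)}")
        weights = cohort[weight_col] if weight_col is not None else None
        cuts = {}
        for s in specs:
            if s.scoring == "tertile":
                cuts[s.name] = gender_tertiles(cohort[s.name],
                                               cohort[self.gender_col], weights)
        self.cutoffs_ = cuts
        self.specs_ = specs
        return self

    def transform(self, cohort: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "cutoffs_"):
            raise RuntimeError("OBSScorer is not fitted")
        out = pd.DataFrame(index=cohort.index)
        sex = cohort[self.gender_col].to_numpy()
        for s in self.specs_:
            if s.scoring == "alcohol_category":
                pts = score_alcohol(cohort[s.name], sex)
            else:
                cuts = self.cutoffs_[s.name]
                pts = np.full(len(cohort), np.nan)
                for g, row in cuts.iterrows():
                    m = sex == g
                    pts[m] = score_component(cohort[s.name].to_numpy()[m],
                                             row["lower"], row["upper"], s.direction)
            out[f"{s.name}_pts"] = pts
        pts_cols = out.columns
        out["obs_total"] = out[pts_cols].sum(axis=1, min_count=len(pts_cols))
        out["obs_excluded"] = out["obs_total"].isna()
        return out

    def fit_transform(self, cohort: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(cohort).transform(cohort)


def compute_obs(cohort: pd.DataFrame, registry: list[ComponentSpec] | None = None,
                gender_col: str = "gender") -> pd.DataFrame:
    """Fit-and-score convenience wrapper around :class:`OBSScorer`."""
    return OBSScorer(registry=registry, gender_col=gender_col).fit_transform(cohort)


def first_tertile_cutoff(totals) -> float:
    """First-tertile cutoff of the score distribution in the analytic sample."""
    t = np.asarray(totals, dtype=float)
    t = t[np.isfinite(t)]
    return float(np.quantile(t, 1 / 3, method="inverted_cdf"))


def dichotomize_obs(totals, cutoff: float | None = None) -> pd.Series:
    """Binary exposure group: ``low`` iff total < cutoff, else ``high``.

    ``cutoff=None`` recomputes the first tertile of the totals.  A total
    exactly equal to the cutoff is ``high`` (the >= rule); note this
    differs from the tertile tie rule, which is a <= rule on raw intakes.
    """
    t = pd.Series(np.asarray(totals, dtype=float))
    if cutoff is None:
        cutoff = first_tertile_cutoff(t)
    grp = pd.Series(pd.NA, index=t.index, dtype="object")
    grp[t < cutoff] = "low"
    grp[t >= cutoff] = "high"
    return grp
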