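"""Restricted cubic splines for nonlinear dose-response on the logit scale.

A restricted (natural) cubic spline with knots t_1 < ... < t_k is linear
beyond the boundary knots and cubic between them; with k knots it
contributes k-1 regression columns (the linear term plus k-2 restricted
cubic terms of the truncated-power form, normalized by (t_k - t_1)^2).
The spline enters a survey-weighted logistic regression; a joint Wald
test of all spline terms gives the overall-association p-value and a
Wald test of the nonlinear terms alone gives the nonlinearity p-value.

The fitted log-odds curve is scanned on a uniform grid to locate an
inflection point — the predictor value where the curve's slope changes
sign — which is then used to pick a dichotomization cutoff for the
variable (typically snapping to the sample median when the two agree).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import SurveyDesign, SurveyLogit

logger = logging.getLogger(__name__)

_KNOT_PERCENTILES = {3: (10, 50, 90), 4: (5, 35, 65, 95), 5: (5, 27.5, 50, 72.5, 95)}

#: slope magnitudes below this are treated as a flat plateau, not a crossing
SLOPE_TOL = 1e-8


def default_knots(x, n_knots: int = 4) -> np.ndarray:
    """Knot placement at the conventional outer/inner percentiles."""
    if n_knots not in _KNOT_PERCENTILES:
        raise ValueError(f"n_knots must be one of {sorted(_KNOT_PERCENTILES)}")
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    knots = np.percentile(x, _KNOT_PERCENTILES[n_knots])
    if np.any(np.diff(knots) <= 0):
        raise ValueError("data too discrete for distinct knots at default percentiles")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted-cubic-spline basis matrix: k knots -> k-1 columns.

    Column 0 is x itself; column j (1..k-2) is the truncated-power
    restricted cubic term anchored at knot j, scaled by (t_k - t_1)^2 so
    all columns share x's units.  The implied function is linear outside
    [t_1, t_k] for every coefficient vector.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    if t.ndim != 1 or t.size < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")
    k = t.size
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        cube = lambda u: np.maximum(u, 0.0) ** 3
        term = (cube(x - t[j])
                - cube(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + cube(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2]))
        cols.append(term / norm)
    return np.column_stack(cols)


@dataclass
class RCSResult:
    """Fitted spline-logistic model with nonlinearity tests and inflection."""

    knots: np.ndarray
    terms: list[str]
    params: np.ndarray
    cov: np.ndarray
    p_overall: float
    p_nonlinear: float
    n: int
    inflection: float | None = None
    cutoff: float | None = None

    def spline_curve(self, grid) -> np.ndarray:
        """Fitted log-odds contribution of the spline terms on ``grid``.

        Covariates are held at zero; the intercept is included, so the
        curve is the fitted logit profile at reference covariate values.
        """
        B = rcs_basis(np.asarray(grid, dtype=float), self.knots)
        n_spline = len(self.knots) - 1
        beta = self.params[: n_spline + 1]  # intercept + spline columns
        return beta[0] + B @ beta[1:]


class RCSLogisticRegression:
    """Survey-weighted logistic regression of a binary outcome on an RCS.

    Parameters
    ----------
    n_knots : 3, 4 or 5 knots at conventional percentiles (default 4 at
        the 5th/35th/65th/95th).
    knots : explicit knot locations, overriding ``n_knots``.
    grid_size : grid resolution for inflection detection (default 512).

    After ``fit``: ``result_`` (:class:`RCSResult`), ``p_overall_``,
    ``p_nonlinear_``, ``inflection_``, ``knots_``.
    """

    def __init__(self, n_knots: int = 4, knots=None, grid_size: int = 512,
                 single_psu: str = "error"):
        self.n_knots = n_knots
        self.knots = knots
        self.grid_size = grid_size
        self.single_psu = single_psu

    def get_params(self, deep: bool = True) -> dict:
        return {"n_knots": self.n_knots, "knots": self.knots,
                "grid_size": self.grid_size, "single_psu": self.single_psu}

    def set_params(self, **kw) -> "RCSLogisticRegression":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, x, y, covariates: pd.DataFrame | None = None,
            design: SurveyDesign | None = None) -> "RCSLogisticRegression":
        x = np.asarray(x, dtype=float)
        knots = (np.asarray(self.knots, dtype=float) if self.knots is not None
                 else default_knots(x, self.n_knots))
        if np.unique(x[np.isfinite(x)]).size < knots.size:
            raise ValueError("x has fewer distinct values than knots")
        B = rcs_basis(x, knots)
        spline_names = ["x"] + [f"x_rcs{j}" for j in range(1, B.shape[1])]
        X = pd.DataFrame(B, columns=spline_names)
        if covariates is not None:
            cov_df = covariates.reset_index(drop=True)
            X = pd.concat([X, cov_df], axis=1)
        est = SurveyLogit(add_intercept=True, single_psu=self.single_psu)
        est.fit(X, y, design)
        fit = est.fit_
        _, p_overall = fit.wald_joint(spline_names)
        _, p_nonlinear = fit.wald_joint(spline_names[1:])
        self.result_ = RCSResult(knots=knots, terms=fit.terms, params=fit.params,
                                 cov=fit.cov, p_overall=p_overall,
                                 p_nonlinear=p_nonlinear, n=fit.n)
        self.result_.inflection = find_inflection(self.result_, self.grid_size)
        self.knots_ = knots
        self.p_overall_ = p_overall
        self.p_nonlinear_ = p_nonlinear
        self.inflection_ = self.result_.inflection
        self.fit_ = fit
        return self

    def curve_frame(self, grid_size: int = 200) -> pd.DataFrame:
        """(x, log-odds, 95% CI) along the knot range, for plotting/export."""
        r = self.result_
        grid = np.linspace(r.knots[0], r.knots[-1], grid_size)
        B = np.column_stack([np.ones(grid_size), rcs_basis(grid, r.knots)])
        n_spline = len(r.knots)  # intercept + k-1 spline columns
        V = r.cov[:n_spline, :n_spline]
        eta = B @ r.params[:n_spline]
        se = np.sqrt(np.einsum("ij,jk,ik->i", B, V, B))
        return pd.DataFrame({"x": grid, "log_odds": eta,
                             "ci_low": eta - 1.959964 * se,
                             "ci_high": eta + 1.959964 * se})


def fit_rcs_logistic(y, x, covariates: pd.DataFrame | None = None,
                     design: SurveyDesign | None = None, n_knots: int = 4,
                     **kwargs) -> RCSResult:
    """Functional wrapper around :class:`RCSLogisticRegression`."""
    est = RCSLogisticRegression(n_knots=n_knots, **kwargs)
    est.fit(x, y, covariates=covariates, design=design)
    return est.result_


def find_inflection(result: RCSResult, grid_size: int = 512) -> float | None:
    """First predictor value where the fitted log-odds slope changes sign.

    The curve is evaluated on a uniform grid between the boundary knots;
    slope segments flatter than ``SLOPE_TOL`` are ignored (plateaus are
    not crossings).  Returns None for a monotone curve; with several
    crossings the first is returned and all are logged.
    """
    grid = np.linspace(result.knots[0], result.knots[-1], grid_size)
    eta = result.spline_curve(grid)
    d = np.diff(eta) / np.diff(grid)
    live = np.flatnonzero(np.abs(d) >= SLOPE_TOL)
    if live.size < 2:
        return None
    s = np.sign(d[live])
    flips = np.flatnonzero(s[:-1] != s[1:])
    if flips.size == 0:
        return None
    crossings = [float(grid[live[i] + 1]) for i in flips]
    if len(crossings) > 1:
        logger.warning("multiple slope sign changes at %s; returning the first",
                       crossings)
    return crossings[0]


def choose_cutoff(inflection: float, x, policy: str = "nearest_quantile_median",
                  tol_frac: float = 0.10) -> float:
    """Dichotomization cutoff from a detected inflection point.

    ``nearest_quantile_median`` snaps to the sample median when it lies
    within ``tol_frac`` of the IQR from the inflection (the inflection
    "corresponds to the median"); otherwise the inflection itself is
    used.  ``inflection_exact`` always returns the inflection.
    """
    if policy == "inflection_exact":
        return float(inflection)
    if policy != "nearest_quantile_median":
        raise ValueError(f"unknown cutoff policy {policy!r}")
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    med = float(np.median(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr > 0 and abs(med - inflection) <= tol_frac * iqr:
        return med
    logger.info("median %.4g farther than %.0f%% of IQR from inflection %.4g; "
                "using the inflection", med, 100 * tol_frac, inflection)
    return float(inflection)
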