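"""Design-based estimation for complex-survey data.

Implements the estimation layer used throughout the package: logistic
regression fitted by weighted pseudo-maximum-likelihood with a
Taylor-linearization ("with replacement" PSU) variance estimator over
(stratum, PSU) clusters, weighted means with linearized standard errors,
a first-order Rao-Scott design-adjusted chi-square test, and Wald tests
on fitted terms.

The variance convention follows the standard survey-sampling sandwich:
with score contributions ``u_i = w_i (y_i - p_i) x_i`` the estimated
covariance of the coefficient vector is ``B^{-1} G B^{-1}`` where ``B``
is the weighted information matrix and ``G`` accumulates, stratum by
stratum, ``n_h/(n_h-1)`` times the scatter of PSU score totals about
their stratum mean.  With equal weights and one PSU per observation in a
single stratum every estimator here reduces to its classical iid
counterpart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr


class ConvergenceError(RuntimeError):
    """Raised when a weighted logistic fit fails to converge (e.g. separation)."""


class DesignError(ValueError):
    """Raised for invalid survey-design structures (weights, strata, PSUs)."""


@dataclass(frozen=True)
class SurveyDesign:
    """Sampling weights plus the (stratum, PSU) clustering used for variance.

    Parameters
    ----------
    weight : array of positive sampling weights, one per row.
    stratum : stratum identifier per row.
    psu : primary-sampling-unit identifier per row, nested in stratum.
    """

    weight: np.ndarray
    stratum: np.ndarray
    psu: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weight, dtype=float)
        s = np.asarray(self.stratum)
        p = np.asarray(self.psu)
        if not (w.ndim == 1 and s.shape == w.shape and p.shape == w.shape):
            raise DesignError("weight, stratum and psu must be 1-d and equal length")
        if w.size and (not np.all(np.isfinite(w)) or np.any(w <= 0)):
            raise DesignError("survey weights must be finite and strictly positive")
        object.__setattr__(self, "weight", w)
        object.__setattr__(self, "stratum", s)
        object.__setattr__(self, "psu", p)

    def __len__(self) -> int:
        return self.weight.size

    @classmethod
    def from_frame(cls, df: pd.DataFrame, weight: str = "weight",
                   stratum: str = "stratum", psu: str = "psu") -> "SurveyDesign":
        return cls(df[weight].to_numpy(dtype=float),
                   df[stratum].to_numpy(), df[psu].to_numpy())

    @classmethod
    def unclustered(cls, n: int) -> "SurveyDesign":
        """Equal weights, one PSU per row, one stratum: the iid design."""
        return cls(np.ones(n), np.zeros(n, dtype=int), np.arange(n))

    def subset(self, idx) -> "SurveyDesign":
        return SurveyDesign(self.weight[idx], self.stratum[idx], self.psu[idx])

    @property
    def n_psu(self) -> int:
        pairs = {(s, p) for s, p in zip(self.stratum, self.psu)}
        return len(pairs)

    @property
    def n_strata(self) -> int:
        return len(set(self.stratum.tolist()))

    @property
    def design_df(self) -> int:
        """Design degrees of freedom: #PSUs - #strata."""
        return self.n_psu - self.n_strata


@dataclass
class GLMFit:
    """A fitted weighted logistic regression with design-based covariance."""

    terms: list[str]
    params: np.ndarray
    cov: np.ndarray
    n: int
    converged: bool
    loglike: float
    design_df: int | None = None
    row_index: np.ndarray | None = field(default=None, repr=False)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def coef(self, term: str) -> float:
        return float(self.params[self._loc(term)])

    def se(self, term: str) -> float:
        return float(self.bse[self._loc(term)])

    def _loc(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in fit (have {self.terms})") from None

    def wald_joint(self, terms: list[str]) -> tuple[float, float]:
        """Joint Wald chi-square test that the named coefficients are all zero."""
        idx = [self._loc(t) for t in terms]
        beta = self.params[idx]
        V = self.cov[np.ix_(idx, idx)]
        stat = float(beta @ np.linalg.solve(V, beta))
        return stat, float(stats.chi2.sf(stat, len(idx)))


def _cluster_score_cov(u: np.ndarray, stratum: np.ndarray, psu: np.ndarray,
                       single_psu: str = "error") -> np.ndarray:
    """Between-PSU covariance of score totals, stratum by stratum.

    ``single_psu='grand_mean'`` centers lone-PSU strata at the grand mean
    of all PSU totals instead of raising.
    """
    u = np.atleast_2d(u.T).T  # ensure n x p
    p = u.shape[1]
    key = pd.MultiIndex.from_arrays([stratum, psu])
    totals = pd.DataFrame(u, index=key).groupby(level=[0, 1], sort=False).sum()
    strata = totals.index.get_level_values(0)
    G = np.zeros((p, p))
    lone = []
    grand_mean = totals.to_numpy().mean(axis=0)
    for h in pd.unique(strata):
        z = totals.to_numpy()[strata == h]
        n_h = z.shape[0]
        if n_h < 2:
            if single_psu == "grand_mean":
                d = z[0] - grand_mean
                G += np.outer(d, d)
                continue
            lone.append(h)
            continue
        d = z - z.mean(axis=0)
        G += (n_h / (n_h - 1)) * (d.T @ d)
    if lone:
        raise DesignError(
            f"strata with a single PSU: {lone!r}; design-based variance needs >=2 "
            "PSUs per stratum (or pass single_psu='grand_mean')"
        )
    return G


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, pivoting=True, mode="economic")
        aliased = [names[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"model matrix is rank deficient; aliased terms: {aliased}"
        )


class SurveyLogit:
    """Survey-weighted logistic regression (sklearn-style estimator).

    Maximizes the weighted pseudo-likelihood and attaches a design-based
    Taylor-linearized covariance over the design's (stratum, PSU) clusters.

    Parameters
    ----------
    add_intercept : prepend an intercept column to X if True.
    single_psu : "error" (default) or "grand_mean" handling for strata
        containing a single PSU.
    df_reference : "normal" (default) for large-sample z p-values, or
        "design_t" for a t reference on #PSUs - #strata degrees of freedom.

    Attributes (after fit)
    ----------------------
    params_, cov_, bse_ : coefficients (log-odds), covariance, SEs.
    term_names_, n_obs_, converged_, fit_ : metadata; ``fit_`` is the
        :class:`GLMFit` container consumed by downstream modules.
    """

    def __init__(self, add_intercept: bool = True, single_psu: str = "error",
                 df_reference: str = "normal", max_iter: int = 200):
        self.add_intercept = add_intercept
        self.single_psu = single_psu
        self.df_reference = df_reference
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"add_intercept": self.add_intercept, "single_psu": self.single_psu,
                "df_reference": self.df_reference, "max_iter": self.max_iter}

    def set_params(self, **kw) -> "SurveyLogit":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, design: SurveyDesign | None = None) -> "SurveyLogit":
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xm = X.to_numpy(dtype=float)
        else:
            Xm = np.asarray(X, dtype=float)
            if Xm.ndim == 1:
                Xm = Xm[:, None]
            names = [f"x{j}" for j in range(Xm.shape[1])]
        y = np.asarray(y, dtype=float)
        if Xm.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        if not np.isin(y, [0.0, 1.0]).all():
            raise ValueError("outcome must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("outcome is degenerate (all 0 or all 1)")
        if design is None:
            design = SurveyDesign.unclustered(len(y))
        if len(design) != len(y):
            raise DesignError("design length does not match data")
        if self.add_intercept:
            Xm = np.column_stack([np.ones(len(y)), Xm])
            names = ["Intercept"] + names
        _check_full_rank(Xm, names)

        w = design.weight / design.weight.mean()  # scale-invariant; tames numerics
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            try:
                model = sm.GLM(y, Xm, family=sm.families.Binomial(), var_weights=w)
                res = model.fit(maxiter=self.max_iter, tol=1e-10)
            except (sm.tools.sm_exceptions.PerfectSeparationError,
                    sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
                raise ConvergenceError(f"perfect separation detected: {exc}") from exc
        if not res.converged:
            raise ConvergenceError("IRLS did not converge")
        beta = np.asarray(res.params, dtype=float)

        mu = 1.0 / (1.0 + np.exp(-(Xm @ beta)))
        info = (Xm * (w * mu * (1 - mu))[:, None]).T @ Xm
        u = Xm * (w * (y - mu))[:, None]
        G = _cluster_score_cov(u, design.stratum, design.psu, self.single_psu)
        Binv = np.linalg.inv(info)
        cov = Binv @ G @ Binv
        cov = (cov + cov.T) / 2.0

        self.term_names_ = names
        self.params_ = beta
        self.cov_ = cov
        self.bse_ = np.sqrt(np.diag(cov))
        self.n_obs_ = int(len(y))
        self.converged_ = True
        self.design_ = design
        self.fit_ = GLMFit(terms=names, params=beta, cov=cov, n=int(len(y)),
                           converged=True, loglike=float(res.llf),
                           design_df=design.design_df)
        return self

    def predict_proba(self, X) -> np.ndarray:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        if self.add_intercept:
            Xm = np.column_stack([np.ones(Xm.shape[0]), Xm])
        p1 = 1.0 / (1.0 + np.exp(-(Xm @ self.params_)))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def model_frame(data: pd.DataFrame, formula: str) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Build (y, X, row positions) from a patsy formula, dropping missing rows."""
    ym, Xm = patsy.dmatrices(formula, data, return_type="dataframe")
    pos = data.index.get_indexer(Xm.index)
    return ym.to_numpy().ravel(), Xm, pos


def fit_weighted_logistic(data: pd.DataFrame, formula: str, design: SurveyDesign,
                          **kwargs) -> GLMFit:
    """Fit ``formula`` (patsy) on ``data`` by survey-weighted logistic regression.

    Rows with missing values in any model variable are dropped (complete-case);
    the design is subset to match.  Returns a :class:`GLMFit`.
    """
    y, X, pos = model_frame(data, formula)
    est = SurveyLogit(add_intercept=False, **kwargs)  # patsy already adds one
    est.fit(X, y, design.subset(pos))
    est.fit_.row_index = pos
    return est.fit_


def odds_ratios(fit: GLMFit, alpha: float = 0.05) -> pd.DataFrame:
    """OR table: exp(coef) with Wald CI and p-value per term.

    The reference distribution is normal unless the fit carries design
    degrees of freedom and the caller asks for a t reference via
    ``fit.design_df`` (handled by the pipeline config).
    """
    if not fit.converged:
        raise ConvergenceError("cannot report odds ratios for a non-converged fit")
    z = stats.norm.ppf(1 - alpha / 2)
    se = fit.bse
    zstat = np.divide(fit.params, se, out=np.zeros_like(fit.params), where=se > 0)
    return pd.DataFrame(
        {
            "OR": np.exp(fit.params),
            "ci_low": np.exp(fit.params - z * se),
            "ci_high": np.exp(fit.params + z * se),
            "p": 2 * stats.norm.sf(np.abs(zstat)),
        },
        index=pd.Index(fit.terms, name="term"),
    )


def weighted_mean_se(values, design: SurveyDesign) -> tuple[float, float]:
    """Survey-weighted mean with Taylor-linearized standard error."""
    x = np.asarray(values, dtype=float)
    keep = np.isfinite(x)
    if not keep.any():
        raise ValueError("all values missing")
    x = x[keep]
    d = design.subset(keep)
    wsum = d.weight.sum()
    mean = float(np.sum(d.weight * x) / wsum)
    u = d.weight * (x - mean) / wsum
    G = _cluster_score_cov(u[:, None], d.stratum, d.psu)
    return mean, float(np.sqrt(G[0, 0]))


def rao_scott_chisq(a, b, design: SurveyDesign) -> tuple[float, float]:
    """First-order Rao-Scott design-adjusted chi-square test of independence.

    The Pearson statistic is computed from the weighted cell proportions at
    the actual sample size, then divided by the mean generalized design
    effect ``tr(V0^+ Vhat)/(K-1)`` where ``Vhat`` is the linearized
    covariance of the cell-proportion vector and ``V0`` its multinomial
    counterpart.  With equal weights and no clustering the correction is
    exactly 1 and the statistic is the ordinary Pearson chi-square.
    """
    a = pd.Series(np.asarray(a, dtype=object))
    b = pd.Series(np.asarray(b, dtype=object))
    keep = a.notna().to_numpy() & b.notna().to_numpy()
    a, b = a[keep], b[keep]
    d = design.subset(keep)
    ra, ca = pd.factorize(a, sort=True)
    rb, cb = pd.factorize(b, sort=True)
    R, C = len(ca), len(cb)
    if R < 2 or C < 2:
        raise ValueError("both variables need at least two observed levels")
    n = len(a)
    K = R * C
    cell = ra * C + rb
    Z = np.zeros((n, K))
    Z[np.arange(n), cell] = 1.0
    wsum = d.weight.sum()
    p = (d.weight @ Z) / wsum
    P = p.reshape(R, C)
    pr, pc = P.sum(axis=1), P.sum(axis=0)
    if np.any(pr == 0) or np.any(pc == 0):
        raise ValueError("empty row or column margin")
    expected = np.outer(pr, pc)
    X2 = n * float(((P - expected) ** 2 / expected).sum())

    U = d.weight[:, None] * (Z - p) / wsum
    Vhat = _cluster_score_cov(U, d.stratum, d.psu)
    V0 = (np.diag(p) - np.outer(p, p)) / (n - 1)
    delta_bar = float(np.trace(np.linalg.pinv(V0) @ Vhat)) / (K - 1)
    stat = X2 / delta_bar
    df = (R - 1) * (C - 1)
    return stat, float(stats.chi2.sf(stat, df))


def wald_interaction_test(fit: GLMFit, term: str) -> tuple[float, float]:
    """Wald z test for one term (used for exposure-by-mediator interactions)."""
    est = fit.coef(term)
    se = fit.se(term)
    z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
    return est, float(2 * stats.norm.sf(abs(z)))
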