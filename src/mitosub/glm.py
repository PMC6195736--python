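"""Poisson and negative-binomial count regressions with offsets.

Both families use a log link; offsets enter the linear predictor with
coefficient fixed at 1.  The negative binomial is the NB2 (Gamma-mixed
Poisson) parameterization with variance ``mu + alpha * mu**2`` and
``alpha`` estimated by maximum likelihood; its dispersion counts as one
parameter in the AIC.  Categorical predictors are dummy-coded against the
lexicographically first level with a deterministic column order, and
perfectly collinear columns are dropped (and recorded) before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.tools.sm_exceptions import ConvergenceWarning

FAMILIES = ("poisson", "negbin")

#: convergence bounds for the iterative fits; a fit that exhausts them is
#: flagged converged=False and the caller applies the saturated fallback
MAXITER = 100
TOL = 1e-8


@dataclass
class PredictorSpec:
    """Which table columns enter the design matrix.

    ``categorical`` columns are expanded to indicator variables (first
    level by sorted order is the reference); ``numeric`` columns enter as
    given.  The intercept is always present.
    """

    categorical: Sequence[str] = ()
    numeric: Sequence[str] = ()


@dataclass
class FitResult:
    family: str
    coefficients: "pd.Series[float]"
    log_likelihood: float
    n_params: int
    aic: float
    converged: bool
    n_rows: int
    alpha: float | None = None
    bse: "pd.Series[float] | None" = None
    dropped_columns: list[str] = field(default_factory=list)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Wald confidence intervals for the coefficients."""
        if self.bse is None:
            raise ValueError("no standard errors available")
        z = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {
                "lower": self.coefficients - z * self.bse,
                "upper": self.coefficients + z * self.bse,
            }
        )


def build_design(
    df: pd.DataFrame, predictors: PredictorSpec
) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-coded design matrix with intercept; drops aliased columns.

    Column order is deterministic: intercept, then each categorical factor's
    sorted non-reference levels in the order the factors are listed, then
    numeric columns.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
    for factor in predictors.categorical:
        values = df[factor].astype(str).to_numpy()
        levels = sorted(set(values))
        for level in levels[1:]:
            cols[f"{factor}[{level}]"] = (values == level).astype(float)
    for col in predictors.numeric:
        cols[col] = df[col].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    dropped: list[str] = []
    # order-preserving rank filter: keep each column only if it adds to the
    # span of the columns already kept (earlier columns win ties)
    if X.shape[1] > 1:
        arr = X.to_numpy()
        n = arr.shape[0]
        basis = np.empty((n, 0))
        keep = []
        tol = 1e-8
        for j in range(arr.shape[1]):
            v = arr[:, j].astype(float)
            norm_v = np.linalg.norm(v)
            if norm_v == 0:
                dropped.append(str(X.columns[j]))
                continue
            resid = v - basis @ (basis.T @ v)
            resid -= basis @ (basis.T @ resid)  # re-orthogonalize
            if np.linalg.norm(resid) / norm_v < tol or basis.shape[1] >= n:
                dropped.append(str(X.columns[j]))
                continue
            basis = np.column_stack([basis, resid / np.linalg.norm(resid)])
            keep.append(j)
        X = X.iloc[:, keep]
    return X, dropped


def fit_count_glm(
    df: pd.DataFrame,
    response: str | np.ndarray,
    predictors: PredictorSpec,
    offset: np.ndarray | None = None,
    family: str = "poisson",
) -> FitResult:
    """Fit a log-link count regression of ``response`` on the predictors.

    ``offset`` is added to the linear predictor with coefficient 1.
    Returns a :class:`FitResult` with ``converged=False`` (never raises)
    when the iteration budget is exhausted, so callers can apply fallback
    scoring.
    """
    return fit_families(df, response, predictors, offset, (family,))[family]


def fit_families(
    df: pd.DataFrame,
    response: str | np.ndarray,
    predictors: PredictorSpec,
    offset: np.ndarray | None = None,
    families: Sequence[str] = FAMILIES,
) -> dict[str, FitResult]:
    """Fit one or both count families on a shared design matrix.

    The Poisson fit doubles as the negative binomial's starting point, so
    requesting both families costs little more than one.
    """
    for family in families:
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
    y = (
        df[response].to_numpy(dtype=float)
        if isinstance(response, str)
        else np.asarray(response, dtype=float)
    )
    if len(y) == 0:
        raise ValueError("empty table")
    X, dropped = build_design(df, predictors)
    offset = np.zeros(len(y)) if offset is None else np.asarray(offset, float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            start = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(
                maxiter=MAXITER, tol=TOL
            )
        except Exception:
            start = None

    out: dict[str, FitResult] = {}
    if start is None:
        for family in families:
            out[family] = _failed_fit(family, X, len(y), dropped)
        return out

    llf_p = float(start.llf)
    if "poisson" in families:
        k = X.shape[1]
        out["poisson"] = FitResult(
            family="poisson",
            coefficients=pd.Series(np.asarray(start.params), index=X.columns),
            log_likelihood=llf_p,
            n_params=k,
            aic=2 * k - 2 * llf_p,
            converged=bool(start.converged) and np.isfinite(llf_p),
            n_rows=len(y),
            bse=pd.Series(np.asarray(start.bse), index=X.columns),
            dropped_columns=dropped,
        )
    if "negbin" in families:
        out["negbin"] = _fit_negbin(y, X, offset, dropped, start)
    return out


def _fit_negbin(
    y: np.ndarray,
    X: pd.DataFrame,
    offset: np.ndarray,
    dropped: list[str],
    start,
) -> FitResult:
    """NB2 fit seeded from the Poisson solution.

    The score for overdispersion at alpha=0 is 0.5 * sum((y - mu)^2 - y);
    when it is non-positive the NB likelihood is maximized at the
    equidispersion boundary and equals the Poisson likelihood, so the
    Poisson solution is returned with alpha = 0 and one extra parameter.
    Otherwise alpha is estimated jointly by BFGS, with a bounded
    profile-likelihood search (alpha fixed per IRLS fit) as a fallback.
    """
    mu = np.asarray(start.fittedvalues)
    score_alpha0 = 0.5 * float(np.sum((y - mu) ** 2 - y))
    k = X.shape[1] + 1  # dispersion counts as a parameter
    if score_alpha0 <= 0 and start.converged:
        llf = float(start.llf)
        return FitResult(
            family="negbin",
            coefficients=pd.Series(np.asarray(start.params), index=X.columns),
            log_likelihood=llf,
            n_params=k,
            aic=2 * k - 2 * llf,
            converged=np.isfinite(llf),
            n_rows=len(y),
            alpha=0.0,
            bse=pd.Series(np.asarray(start.bse), index=X.columns),
            dropped_columns=dropped,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = NegativeBinomial(y, X, loglike_method="nb2", offset=offset)
            res = model.fit(
                start_params=np.r_[np.asarray(start.params), 0.1],
                method="bfgs",
                maxiter=MAXITER,
                gtol=TOL,
                disp=0,
            )
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = None
            converged = False
    if (
        res is not None
        and converged
        and np.asarray(res.params)[-1] > 0
        and np.isfinite(res.llf)
    ):
        params = np.asarray(res.params)
        llf = float(res.llf)
        bse = np.asarray(res.bse)
        return FitResult(
            family="negbin",
            coefficients=pd.Series(params[:-1], index=X.columns),
            log_likelihood=llf,
            n_params=k,
            aic=2 * k - 2 * llf,
            converged=True,
            n_rows=len(y),
            alpha=float(params[-1]),
            bse=pd.Series(bse[:-1], index=X.columns),
            dropped_columns=dropped,
        )
    # Joint BFGS failed away from the boundary: profile the likelihood over
    # fixed alpha, where the model is an ordinary IRLS-fit GLM.
    return _negbin_profile_fit(y, X, offset, dropped)


_LOG_ALPHA_LO, _LOG_ALPHA_HI = -8.0, 3.0


def _negbin_profile_fit(
    y: np.ndarray, X: pd.DataFrame, offset: np.ndarray, dropped: list[str]
) -> FitResult:
    from scipy.optimize import minimize_scalar

    def profile_llf(log10_alpha: float) -> float:
        fam = sm.families.NegativeBinomial(alpha=10.0 ** log10_alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=fam, offset=offset).fit(
                maxiter=MAXITER, tol=TOL
            )
        return float(res.llf)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            opt = minimize_scalar(
                lambda a: -profile_llf(a),
                bounds=(_LOG_ALPHA_LO, _LOG_ALPHA_HI),
                method="bounded",
                options={"xatol": 1e-2, "maxiter": 30},
            )
            alpha = 10.0 ** float(opt.x)
            fam = sm.families.NegativeBinomial(alpha=alpha)
            res = sm.GLM(y, X, family=fam, offset=offset).fit(
                maxiter=MAXITER, tol=TOL
            )
    except Exception:
        return _failed_fit("negbin", X, len(y), dropped)
    llf = float(res.llf)
    k = X.shape[1] + 1
    return FitResult(
        family="negbin",
        coefficients=pd.Series(np.asarray(res.params), index=X.columns),
        log_likelihood=llf,
        n_params=k,
        aic=2 * k - 2 * llf,
        converged=bool(res.converged) and np.isfinite(llf),
        n_rows=len(y),
        alpha=alpha,
        bse=pd.Series(np.asarray(res.bse), index=X.columns),
        dropped_columns=dropped,
    )


def _failed_fit(
    family: str, X: pd.DataFrame, n: int, dropped: list[str]
) -> FitResult:
    k = X.shape[1] + (1 if family == "negbin" else 0)
    return FitResult(
        family=family,
        coefficients=pd.Series(np.nan, index=X.columns),
        log_likelihood=-np.inf,
        n_params=k,
        aic=np.inf,
        converged=False,
        n_rows=n,
        dropped_columns=dropped,
    )


def glr_test(fit_null: FitResult, fit_alt: FitResult) -> float:
    """Generalized likelihood-ratio p-value for nested fits.

    The statistic ``2 * (llf_alt - llf_null)`` is referred to a chi-square
    with degrees of freedom equal to the difference in parameter counts.  A
    clearly negative statistic signals that the models are not nested.
    """
    df = fit_alt.n_params - fit_null.n_params
    if df < 0:
        raise ValueError("alternative has fewer parameters than the null")
    stat = 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood)
    tol = 1e-6 * max(1.0, abs(fit_alt.log_likelihood))
    if stat < -tol:
        raise ValueError(
            f"negative GLR statistic ({stat:.3g}); models are not nested"
        )
    stat = max(stat, 0.0)
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(stat, df))


def kruskal_wallis(groups: Iterable[Sequence[float]]) -> float:
    """Kruskal-Wallis p-value across groups of per-site counts.

    Uses the tie-corrected H statistic with the chi-square approximation;
    the degenerate all-identical case yields H = 0 and p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 1.0
    _, p = stats.kruskal(*arrays)
    return float(p)
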