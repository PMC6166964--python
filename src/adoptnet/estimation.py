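"""Linear probability models of adoption: OLS and 2SLS with diagnostics.

The outcome model regresses the binary adoption flag on physician covariates
and the four peer adoption rates.  Because each physician influences peers
who simultaneously influence them (the reflection problem), and peers may
share unobserved shocks, the peer rates are endogenous; they are instrumented
with the per-network means of exogenous peer characteristics, estimated by
two-stage least squares with heteroskedasticity-robust (HC1) standard errors.

The diagnostic suite mirrors standard IV practice: per-endogenous first-stage
F statistics on the excluded instruments (robust Wald by default, classical
available), the Cragg-Donald minimum-eigenvalue statistic for joint weak-
instrument assessment, and the Sargan overidentification test of the
"no confounding" null.  Networks whose first-stage F falls below 10 are
flagged so their peer-effect estimates are reported as not reliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .measures import ModelSpec, SpecificationError

WEAK_F_THRESHOLD = 10.0


class SingularDesignError(ValueError):
    """Design matrix is rank deficient; lists the collinear columns."""


@dataclass
class FirstStage:
    """First-stage artifacts for one endogenous column."""

    endog_name: str
    params: pd.Series
    resid: np.ndarray
    f_robust: float
    f_classical: float
    p_robust: float


@dataclass
class IVEstimate:
    """Fitted coefficients with robust covariance and residuals."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    nobs: int
    estimator: str  # "OLS" or "2SLS"
    resid: np.ndarray
    fitted: np.ndarray
    spec: ModelSpec | None
    first_stage: dict[str, FirstStage] = field(default_factory=dict)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * scipy.stats.norm.sf(np.abs(self.tvalues)), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        zcrit = scipy.stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - zcrit * self.bse,
                "upper": self.params + zcrit * self.bse,
            }
        )

    def to_frame(self, unreliable: Sequence[str] = ()) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "estimate": self.params,
                "robust_se": self.bse,
                "z": self.tvalues,
                "p": self.pvalues,
            }
        )
        out["reliable"] = [name not in set(unreliable) for name in out.index]
        return out


@dataclass
class OveridResult:
    statistic: float
    df: int
    pvalue: float
    message: str = ""


@dataclass
class DiagnosticsReport:
    """First-stage relevance, joint weak-instrument and overidentification tests."""

    first_stage_f: dict[str, float]
    first_stage_f_classical: dict[str, float]
    cragg_donald: float | None
    overid: OveridResult
    reliable: dict[str, bool]
    unreliable_endog: list[str]
    lpm_logit: dict | None = None

    def to_dict(self) -> dict:
        return {
            "first_stage_f": self.first_stage_f,
            "first_stage_f_classical": self.first_stage_f_classical,
            "cragg_donald": self.cragg_donald,
            "overid": {
                "statistic": self.overid.statistic,
                "df": self.overid.df,
                "pvalue": self.overid.pvalue,
                "message": self.overid.message,
            },
            "reliable": self.reliable,
            "unreliable_endog": self.unreliable_endog,
            "lpm_logit": self.lpm_logit,
        }


# ----------------------------------------------------------------------
# design-matrix helpers
# ----------------------------------------------------------------------

def _design(data: pd.DataFrame, columns: Sequence[str], label: str) -> np.ndarray:
    missing = [c for c in columns if c not in data.columns]
    if missing:
        raise SpecificationError(f"{label} columns absent from data: {missing}")
    return data[list(columns)].to_numpy(float)


def _check_rank(mat: np.ndarray, names: Sequence[str], label: str) -> None:
    r = np.linalg.qr(mat, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(mat.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[i] for i in np.flatnonzero(diag < tol)]
    if bad:
        raise SingularDesignError(f"{label} design is rank deficient near columns {bad}")


def _hc1_cov(xhat: np.ndarray, resid: np.ndarray, robust: str) -> np.ndarray:
    n, k = xhat.shape
    bread = np.linalg.inv(xhat.T @ xhat)
    if robust in {"HC1", "HC0"}:
        meat = (xhat * resid[:, None] ** 2).T @ xhat
        cov = bread @ meat @ bread
        if robust == "HC1":
            cov *= n / (n - k)
    elif robust in {"nonrobust", "classical"}:
        sigma2 = resid @ resid / (n - k)
        cov = bread * sigma2
    else:
        raise ValueError(f"unknown robust flavor {robust!r}")
    return cov


# ----------------------------------------------------------------------
# estimators
# ----------------------------------------------------------------------

class PeerEffectsOLS(BaseEstimator):
    """Linear probability model fit by OLS with robust standard errors.

    Endogenous columns are entered as-is, so on data with simultaneity or
    peer-correlated confounding the peer-effect coefficients are biased;
    this estimator is the benchmark against which 2SLS is compared.
    """

    def __init__(self, endog=(), exog=(), robust: str = "HC1"):
        self.endog = endog
        self.exog = exog
        self.robust = robust

    def fit(self, X: pd.DataFrame, y) -> "PeerEffectsOLS":
        if isinstance(y, str):
            y = X[y]
        yv = np.asarray(y, float)
        names = ["const"] + list(self.exog) + list(self.endog)
        mat = sm.add_constant(
            _design(X, list(self.exog) + list(self.endog), "regressor"),
            has_constant="add",
        )
        _check_rank(mat, names, "OLS")
        cov_type = "nonrobust" if self.robust in {"nonrobust", "classical"} else self.robust
        res = sm.OLS(yv, mat).fit(cov_type=cov_type)
        self.result_ = IVEstimate(
            params=pd.Series(res.params, index=names),
            bse=pd.Series(res.bse, index=names),
            cov=pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names),
            nobs=len(yv),
            estimator="OLS",
            resid=np.asarray(res.resid),
            fitted=np.asarray(res.fittedvalues),
            spec=None,
        )
        self.coef_ = self.result_.params
        self.bse_ = self.result_.bse
        self.nobs_ = len(yv)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        mat = sm.add_constant(
            _design(X, list(self.exog) + list(self.endog), "regressor"),
            has_constant="add",
        )
        return mat @ self.coef_.to_numpy()


class PeerEffectsIV(BaseEstimator):
    """Two-stage least squares with peer-mean instruments.

    First stage: each endogenous peer adoption rate is regressed on all
    instruments plus every included exogenous column.  Second stage: the
    fitted rates replace the observed ones.  Coefficients equal the closed
    form (X' P_Z X)^-1 X' P_Z y; standard errors use the proper 2SLS
    residual y - X b (observed endogenous values), HC1 by default.
    """

    def __init__(self, endog=(), exog=(), instruments=(), robust: str = "HC1"):
        self.endog = endog
        self.exog = exog
        self.instruments = instruments
        self.robust = robust

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y) -> "PeerEffectsIV":
        endog = list(self.endog)
        exog = list(self.exog)
        instruments = list(self.instruments)
        if not endog:
            raise SpecificationError("2SLS requires at least one endogenous column")
        if len(instruments) < len(endog):
            raise SpecificationError(
                f"under-identified: {len(instruments)} instruments for {len(endog)} "
                "endogenous columns"
            )
        if isinstance(y, str):
            y = X[y]
        yv = np.asarray(y, float)

        xnames = ["const"] + exog + endog
        znames = ["const"] + exog + instruments
        xmat = sm.add_constant(_design(X, exog + endog, "regressor"), has_constant="add")
        zmat = sm.add_constant(_design(X, exog + instruments, "instrument"), has_constant="add")
        _check_rank(xmat, xnames, "structural")
        _check_rank(zmat, znames, "instrument")

        # first stages (statsmodels OLS per endogenous column)
        first_stage: dict[str, FirstStage] = {}
        zfit = np.linalg.lstsq(zmat, xmat, rcond=None)[0]
        xhat = zmat @ zfit
        n_excl = len(instruments)
        restr = np.zeros((n_excl, zmat.shape[1]))
        restr[np.arange(n_excl), 1 + len(exog) + np.arange(n_excl)] = 1.0
        for j, name in enumerate(endog):
            col = xmat[:, 1 + len(exog) + j]
            res_r = sm.OLS(col, zmat).fit(cov_type="HC1")
            res_c = sm.OLS(col, zmat).fit()
            ftest_r = res_r.f_test(restr)
            ftest_c = res_c.f_test(restr)
            first_stage[name] = FirstStage(
                endog_name=name,
                params=pd.Series(res_c.params, index=znames),
                resid=np.asarray(res_c.resid),
                f_robust=float(np.squeeze(ftest_r.fvalue)),
                f_classical=float(np.squeeze(ftest_c.fvalue)),
                p_robust=float(np.squeeze(ftest_r.pvalue)),
            )

        xtx = xhat.T @ xhat
        cond = np.linalg.cond(xtx)
        if cond > 1e10:
            warnings.warn(
                f"instrument projection of the design is near-singular "
                f"(condition number {cond:.2e}); estimates may be unstable",
                RuntimeWarning,
                stacklevel=2,
            )
        beta = np.linalg.solve(xtx, xhat.T @ yv)
        resid = yv - xmat @ beta  # observed endogenous values in the residual
        cov = _hc1_cov(xhat, resid, self.robust)

        self.result_ = IVEstimate(
            params=pd.Series(beta, index=xnames),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=xnames),
            cov=pd.DataFrame(cov, index=xnames, columns=xnames),
            nobs=len(yv),
            estimator="2SLS",
            resid=resid,
            fitted=xmat @ beta,
            spec=ModelSpec("y", endog, exog, instruments, self.robust),
            first_stage=first_stage,
        )
        self.coef_ = self.result_.params
        self.bse_ = self.result_.bse
        self.nobs_ = len(yv)
        self._data_cache = (X, yv)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        mat = sm.add_constant(
            _design(X, list(self.exog) + list(self.endog), "regressor"),
            has_constant="add",
        )
        return mat @ self.coef_.to_numpy()

    # ------------------------------------------------------------------
    def diagnostics(
        self,
        cd_subset: Sequence[str] | None = None,
        lpm_logit: bool = False,
    ) -> DiagnosticsReport:
        """Weak-instrument and overidentification diagnostics for this fit."""
        est = self.result_
        X, yv = self._data_cache
        f_rob = {k: fs.f_robust for k, fs in est.first_stage.items()}
        f_cls = {k: fs.f_classical for k, fs in est.first_stage.items()}
        reliable = {k: f > WEAK_F_THRESHOLD for k, f in f_rob.items()}
        cd = cragg_donald(
            X, list(self.endog) if cd_subset is None else list(cd_subset),
            list(self.exog), list(self.instruments),
        )
        overid = overidentification_test(est, est.spec, X)
        comparison = None
        if lpm_logit:
            comparison = compare_lpm_logit(est.spec, X.assign(_y=yv), outcome="_y")
        return DiagnosticsReport(
            first_stage_f=f_rob,
            first_stage_f_classical=f_cls,
            cragg_donald=cd,
            overid=overid,
            reliable=reliable,
            unreliable_endog=[k for k, ok in reliable.items() if not ok],
            lpm_logit=comparison,
        )


# ----------------------------------------------------------------------
# module-level operations
# ----------------------------------------------------------------------

def fit_ols(spec: ModelSpec, data: pd.DataFrame) -> IVEstimate:
    """OLS fit of the linear probability model (endogenous columns as-is)."""
    model = PeerEffectsOLS(endog=spec.endog, exog=spec.exog, robust=spec.robust)
    model.fit(data, spec.outcome)
    result = model.result_
    result.spec = spec
    return result


def fit_2sls(spec: ModelSpec, data: pd.DataFrame) -> IVEstimate:
    """2SLS fit of the linear probability model with peer-mean instruments."""
    model = PeerEffectsIV(
        endog=spec.endog, exog=spec.exog, instruments=spec.instruments, robust=spec.robust
    )
    model.fit(data, spec.outcome)
    result = model.result_
    result.spec = spec
    return result


def weak_instrument_diagnostics(
    estimate: IVEstimate,
    data: pd.DataFrame | None = None,
    cd_subset: Sequence[str] | None = None,
) -> DiagnosticsReport:
    """Per-endogenous first-stage F and optional Cragg-Donald statistic.

    Networks with F <= 10 are flagged; their peer-effect estimates should be
    reported as not reliable.
    """
    spec = estimate.spec
    f_rob = {k: fs.f_robust for k, fs in estimate.first_stage.items()}
    f_cls = {k: fs.f_classical for k, fs in estimate.first_stage.items()}
    reliable = {k: f > WEAK_F_THRESHOLD for k, f in f_rob.items()}
    cd = None
    if data is not None:
        cd = cragg_donald(
            data,
            spec.endog if cd_subset is None else list(cd_subset),
            spec.exog,
            spec.instruments,
        )
    overid = (
        overidentification_test(estimate, spec, data)
        if data is not None
        else OveridResult(float("nan"), 0, float("nan"), "data not supplied")
    )
    return DiagnosticsReport(
        first_stage_f=f_rob,
        first_stage_f_classical=f_cls,
        cragg_donald=cd,
        overid=overid,
        reliable=reliable,
        unreliable_endog=[k for k, ok in reliable.items() if not ok],
    )


def cragg_donald(
    data: pd.DataFrame,
    endog: Sequence[str],
    exog: Sequence[str],
    instruments: Sequence[str],
) -> float:
    """Cragg-Donald minimum-eigenvalue weak-instrument statistic.

    Both the endogenous block and the excluded instruments are partialled on
    the included exogenous columns (plus constant); the statistic is the
    minimum eigenvalue of the concentration matrix and reduces to the
    classical first-stage partial F when there is a single endogenous column.
    """
    ymat = _design(data, endog, "endogenous")
    xmat = sm.add_constant(
        _design(data, exog, "exogenous") if exog else np.empty((len(data), 0)),
        has_constant="add",
    )
    zmat = _design(data, instruments, "instrument")
    n = len(data)
    k_x, k_z = xmat.shape[1], zmat.shape[1]

    def resid_on_x(block: np.ndarray) -> np.ndarray:
        coef = np.linalg.lstsq(xmat, block, rcond=None)[0]
        return block - xmat @ coef

    yp = resid_on_x(ymat)
    zp = resid_on_x(zmat)
    proj = zp @ np.linalg.lstsq(zp, yp, rcond=None)[0]
    num = yp.T @ proj
    sigma = (yp - proj).T @ (yp - proj) / (n - k_x - k_z)
    # min eig of sigma^-1/2 num sigma^-1/2 / k_z == min generalized eig
    vals = scipy.linalg.eigvalsh(num / k_z, sigma)
    return float(np.min(vals))


def overidentification_test(
    estimate: IVEstimate, spec: ModelSpec, data: pd.DataFrame
) -> OveridResult:
    """Sargan test of the "no confounding" null.

    Regresses the 2SLS residual on all instruments and included exogenous
    columns; the statistic is n R-squared, chi-square with (instruments -
    endogenous) degrees of freedom.  Just-identified models return df 0 with
    an undefined p-value rather than raising.
    """
    df = len(spec.instruments) - len(spec.endog)
    if df <= 0:
        return OveridResult(
            float("nan"), 0, float("nan"), "test undefined for a just-identified model"
        )
    zmat = sm.add_constant(
        _design(data, list(spec.exog) + list(spec.instruments), "instrument"),
        has_constant="add",
    )
    u = estimate.resid
    res = sm.OLS(u, zmat).fit()
    stat = float(len(u) * res.rsquared)
    p = float(scipy.stats.chi2.sf(stat, df))
    return OveridResult(stat, df, p)


def compare_lpm_logit(
    spec: ModelSpec, data: pd.DataFrame, outcome: str | None = None
) -> dict:
    """Fitted-probability differences between the LPM and a logistic fit.

    Both models use the same specification with endogenous columns entered
    as-is; reports mean, median and quartiles of the per-physician fitted
    difference (LPM minus logit).  Logistic separation or non-convergence is
    flagged and the summary is computed only on a converged fit.
    """
    outcome = outcome or spec.outcome
    yv = np.asarray(data[outcome], float)
    uniq = np.unique(yv)
    if not set(uniq).issubset({0.0, 1.0}) or len(uniq) < 2:
        raise ValueError("outcome must be binary and non-degenerate")
    cols = list(spec.exog) + list(spec.endog)
    mat = sm.add_constant(
        _design(data, cols, "regressor") if cols else np.empty((len(data), 0)),
        has_constant="add",
    )
    lpm = sm.OLS(yv, mat).fit()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logit = sm.Logit(yv, mat).fit(disp=False, maxiter=200)
        converged = bool(logit.mle_retvals.get("converged", True))
        logit_fit = np.asarray(logit.predict())
    except Exception:
        converged = False
        logit_fit = None
    if not converged or logit_fit is None:
        return {
            "converged": False,
            "mean": float("nan"),
            "median": float("nan"),
            "q1": float("nan"),
            "q3": float("nan"),
        }
    diff = np.asarray(lpm.fittedvalues) - logit_fit
    return {
        "converged": True,
        "mean": float(np.mean(diff)),
        "median": float(np.median(diff)),
        "q1": float(np.quantile(diff, 0.25)),
        "q3": float(np.quantile(diff, 0.75)),
    }
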