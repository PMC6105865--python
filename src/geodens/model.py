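"""Poisson ecological-regression models of app-user density.

The density outcome of each sampling buffer is modelled as a Poisson count
with a log link. Buffer covariates are the areal population-weighted
averages from :mod:`geodens.areal`; a six-level sampling-time categorical
(day-of-week crossed with before/after 8 pm, reference Monday before 8 pm)
is always forced into the model to control for when a location was sampled.

The estimator layer follows scikit-learn conventions (:class:`PoissonGLM`,
:class:`BackwardAICSelector`), and the term-aware layer
(:func:`fit_poisson`, :func:`backward_eliminate_aic`, ...) wraps it for
named design-matrix columns, multi-level term blocks, and reporting:
incidence-rate ratios with Wald intervals, likelihood-ratio tests, McFadden
pseudo r-squared, and the Bonferroni outlier test used to flag buffers with
statistically unexpected densities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .types import SLOT_LABELS

#: name of the forced sampling-time term; expands to one indicator column
#: per non-reference slot
TIME_TERM = "sampling_time"
_SLOT_COLUMNS = tuple(f"slot_{s}" for s in SLOT_LABELS[1:])

_ETA_MAX = 30.0  # exp(30) ~ 1e13; caps the linear predictor during IRLS


class ConvergenceWarning(UserWarning):
    pass


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _poisson_llf(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


class PoissonGLM(RegressorMixin, BaseEstimator):
    """Poisson regression with log link, fitted by IRLS.

    Parameters
    ----------
    fit_intercept : bool, default True
        Prepend a constant column.
    tol : float, default 1e-8
        Convergence threshold on the absolute change in deviance.
    max_iter : int, default 100
        IRLS iteration cap; non-convergence raises a warning and is recorded
        in ``converged_``.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Coefficients on the log scale.
    intercept_ : float
        Intercept (0.0 when ``fit_intercept=False``).
    cov_params_ : ndarray of shape (k, k)
        Inverse Fisher information at the optimum, ordered
        ``[intercept, features...]`` when an intercept is fitted.
    llf_ : float
        Maximized log-likelihood (including the ``log y!`` constant).
    aic_ : float
        ``-2 llf + 2 k``.
    mu_ : ndarray
        Fitted means on the training data.
    hat_ : ndarray
        GLM leverage (hat) values on the training data.
    deviance_ : float
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-8, max_iter: int = 100):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, offset=None) -> "PoissonGLM":
        X, y = check_X_y(X, y, dtype=float, y_numeric=True, ensure_min_features=0)
        if np.any(y < 0):
            raise ValueError("Poisson outcome must be non-negative")
        n, p = X.shape
        Xd = np.column_stack([np.ones(n), X]) if self.fit_intercept else X.copy()
        k = Xd.shape[1]
        if n <= k:
            raise ValueError(f"need n_obs > n_params ({n} <= {k})")
        if np.linalg.matrix_rank(Xd) < k:
            raise ValueError(
                "design is rank deficient (constant or collinear column); "
                "the affected coefficient is inestimable"
            )
        off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
        if off.shape != (n,):
            raise ValueError("offset must have one value per observation")

        mu = (y + np.mean(y)) / 2.0
        mu = np.clip(mu, 1e-8, None)
        eta = np.log(mu) - off
        dev = np.inf
        converged = False
        beta = np.zeros(k)
        for it in range(1, self.max_iter + 1):
            mu = np.exp(np.clip(eta + off, -_ETA_MAX, _ETA_MAX))
            w = np.clip(mu, 1e-10, None)
            z = eta + (y - mu) / w
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(Xd * sw[:, None], z * sw, rcond=None)
            eta = Xd @ beta
            mu = np.exp(np.clip(eta + off, -_ETA_MAX, _ETA_MAX))
            dev_new = _poisson_deviance(y, mu)
            if abs(dev - dev_new) < self.tol:
                dev = dev_new
                converged = True
                break
            dev = dev_new
        if not converged:
            warnings.warn(
                f"IRLS did not converge in {self.max_iter} iterations "
                f"(deviance {dev:.6g})",
                ConvergenceWarning,
                stacklevel=2,
            )

        w = np.clip(mu, 1e-10, None)
        fisher = (Xd * w[:, None]).T @ Xd
        cov = np.linalg.inv(fisher)
        # leverage: diag of W^1/2 X (X'WX)^-1 X' W^1/2
        A = Xd * np.sqrt(w)[:, None]
        hat = np.einsum("ij,jk,ik->i", A, cov, A)

        self.n_features_in_ = p
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.params_ = beta.copy()
        self.cov_params_ = cov
        self.mu_ = mu
        self.hat_ = hat
        self.deviance_ = dev
        self.llf_ = _poisson_llf(y, w)
        self.aic_ = -2.0 * self.llf_ + 2.0 * k
        self.df_model_ = k
        self.n_obs_ = n
        self.n_iter_ = it
        self.converged_ = converged
        self._offset_used = offset is not None
        return self

    def predict(self, X, offset=None) -> np.ndarray:
        """Expected outcome ``exp(X beta [+ offset])``."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        eta = X @ self.coef_ + self.intercept_
        if offset is not None:
            eta = eta + np.asarray(offset, dtype=float)
        return np.exp(eta)

    def bse(self) -> np.ndarray:
        """Standard errors ordered like ``params_``."""
        check_is_fitted(self, "cov_params_")
        return np.sqrt(np.diag(self.cov_params_))


# ---------------------------------------------------------------------------
# term-aware layer


def term_columns(term: str) -> list[str]:
    """Design-matrix columns spanned by a term (the sampling-time term is a
    block of slot indicators; every other term is its own column)."""
    return list(_SLOT_COLUMNS) if term == TIME_TERM else [term]


@dataclass
class ModelFit:
    """A fitted Poisson model over named design-matrix terms.

    Wraps the :class:`PoissonGLM` estimator together with the term list (the
    forced sampling-time block marked), the outcome used, and the training
    frame, so that downstream reports (IRR tables, LRTs, outlier tests) can
    be computed without refitting.
    """

    terms: tuple[str, ...]
    forced_terms: tuple[str, ...]
    outcome: str
    columns: tuple[str, ...]
    glm: PoissonGLM
    y: np.ndarray
    X: np.ndarray
    offset: Optional[np.ndarray] = None
    design_index: Optional[pd.Index] = None

    @property
    def params(self) -> pd.Series:
        names = ["intercept", *self.columns]
        return pd.Series(self.glm.params_, index=names)

    @property
    def bse(self) -> pd.Series:
        names = ["intercept", *self.columns]
        return pd.Series(self.glm.bse(), index=names)

    @property
    def cov_params(self) -> pd.DataFrame:
        names = ["intercept", *self.columns]
        return pd.DataFrame(self.glm.cov_params_, index=names, columns=names)

    @property
    def llf(self) -> float:
        return self.glm.llf_

    @property
    def aic(self) -> float:
        return self.glm.aic_

    @property
    def k(self) -> int:
        return self.glm.df_model_

    @property
    def n_obs(self) -> int:
        return self.glm.n_obs_

    @property
    def mu(self) -> np.ndarray:
        return self.glm.mu_

    def quasi_poisson_scale(self) -> float:
        """Pearson chi-square / residual df — logged as an overdispersion
        diagnostic only; no adjustment is applied."""
        pearson = float(np.sum((self.y - self.mu) ** 2 / self.mu))
        return pearson / (self.n_obs - self.k)


def fit_poisson(
    design: pd.DataFrame,
    terms: Sequence[str],
    outcome: str = "density",
    forced_terms: Sequence[str] = (TIME_TERM,),
    offset_col: Optional[str] = None,
) -> ModelFit:
    """Fit a Poisson GLM of ``outcome`` on the named terms.

    ``terms`` are design-matrix column names plus optionally the
    ``sampling_time`` block term. When ``offset_col`` is given its log is
    used as an offset (the count-with-offset model variant).
    """
    terms = tuple(terms)
    for t in forced_terms:
        if t not in terms:
            raise ValueError(f"forced term {t!r} missing from terms")
    cols: list[str] = []
    for t in terms:
        for c in term_columns(t):
            if c not in design.columns:
                raise KeyError(f"design matrix lacks column {c!r}")
            cols.append(c)
    X = design[cols].to_numpy(float)
    y = design[outcome].to_numpy(float)
    offset = None
    if offset_col is not None:
        off_vals = design[offset_col].to_numpy(float)
        if np.any(off_vals <= 0):
            raise ValueError(f"offset column {offset_col!r} must be positive")
        offset = np.log(off_vals)
    glm = PoissonGLM().fit(X, y, offset=offset)
    return ModelFit(
        terms=terms,
        forced_terms=tuple(forced_terms),
        outcome=outcome,
        columns=tuple(cols),
        glm=glm,
        y=y,
        X=X,
        offset=offset,
        design_index=design.index,
    )


class BackwardAICSelector(BaseEstimator):
    """Greedy backward elimination of model terms by AIC.

    From the full model, the drop (a multi-level categorical drops as a
    block) whose removal yields the lowest AIC is taken, provided that AIC
    is below the current model's; this repeats until no drop improves.
    Forced terms (the sampling-time block and the intercept) are never
    candidates. AIC ties within ``tie_tol`` resolve to the term listed first
    in the candidate order.

    Fitting requires a named design frame; use :meth:`fit_design`.
    ``selected_terms_`` and ``fit_`` hold the result.
    """

    def __init__(
        self,
        candidate_terms: Sequence[str] = (),
        forced_terms: Sequence[str] = (TIME_TERM,),
        outcome: str = "density",
        offset_col: Optional[str] = None,
        tie_tol: float = 1e-10,
    ):
        self.candidate_terms = candidate_terms
        self.forced_terms = forced_terms
        self.outcome = outcome
        self.offset_col = offset_col
        self.tie_tol = tie_tol

    def fit_design(self, design: pd.DataFrame) -> "BackwardAICSelector":
        candidates = list(self.candidate_terms)
        forced = tuple(self.forced_terms)
        current = fit_poisson(
            design, (*forced, *candidates), self.outcome, forced, self.offset_col
        )
        path = [(None, current.aic)]
        while candidates:
            best_term = None
            best_fit = None
            for t in candidates:
                reduced_terms = (*forced, *(c for c in candidates if c != t))
                trial = fit_poisson(
                    design, reduced_terms, self.outcome, forced, self.offset_col
                )
                if best_fit is None or trial.aic < best_fit.aic - self.tie_tol:
                    best_term, best_fit = t, trial
            if best_fit is not None and best_fit.aic < current.aic - self.tie_tol:
                candidates.remove(best_term)
                current = best_fit
                path.append((best_term, current.aic))
            else:
                break
        self.selected_terms_ = current.terms
        self.dropped_terms_ = tuple(t for t, _ in path[1:])
        self.aic_path_ = tuple(a for _, a in path)
        self.fit_ = current
        return self

    def fit(self, X, y=None):  # pragma: no cover - sklearn API shim
        raise TypeError("BackwardAICSelector operates on named designs; use fit_design")


def backward_eliminate_aic(
    design: pd.DataFrame,
    candidate_terms: Sequence[str],
    forced_terms: Sequence[str] = (TIME_TERM,),
    outcome: str = "density",
    offset_col: Optional[str] = None,
) -> ModelFit:
    """Functional wrapper over :class:`BackwardAICSelector`; returns the final fit."""
    sel = BackwardAICSelector(
        candidate_terms, forced_terms, outcome=outcome, offset_col=offset_col
    ).fit_design(design)
    return sel.fit_


# ---------------------------------------------------------------------------
# inference & reporting


@dataclass(frozen=True)
class IrrEntry:
    term: str
    irr: float
    ci_low: float
    ci_high: float
    percent_change: float


def irr_table(fit: ModelFit, z: float = 1.96) -> pd.DataFrame:
    """Incidence-rate ratios with Wald 95% intervals for every non-intercept
    coefficient: ``exp(beta -/+ z SE)``."""
    rows = []
    for name, b, se in zip(fit.params.index, fit.params, fit.bse):
        if name == "intercept":
            continue
        irr = math.exp(b)
        rows.append(
            {
                "term": name,
                "irr": irr,
                "ci_low": math.exp(b - z * se),
                "ci_high": math.exp(b + z * se),
                "percent_change": 100.0 * (irr - 1.0),
            }
        )
    return pd.DataFrame(rows).set_index("term")


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def irr_to_percent_change(irr: float, rounded: bool = True) -> float | int:
    """Convert an incidence-rate ratio to the percent change in expected
    density per unit covariate increase: ``100 (IRR - 1)``, reported to the
    nearest integer percent by default."""
    if irr <= 0:
        raise ValueError("IRR must be positive")
    pct = 100.0 * (irr - 1.0)
    return _round_half_away(pct) if rounded else pct


def likelihood_ratio_test(full: ModelFit, reduced: ModelFit) -> tuple[float, int, float]:
    """LRT of nested Poisson fits: ``2 (llf_full - llf_reduced)`` against
    chi-square with the difference in parameter counts.

    Identical models give statistic 0 with p = 1.
    """
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested (reduced terms not a subset)")
    if full.n_obs != reduced.n_obs or not np.array_equal(full.y, reduced.y):
        raise ValueError("models were fitted on different observations")
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = full.k - reduced.k
    if df == 0:
        return 0.0, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def mcfadden_r2(fit: ModelFit, null_fit: ModelFit) -> float:
    """McFadden likelihood-based pseudo r-squared: ``1 - llf / llf_null``
    against the intercept-only model on the same observations."""
    if null_fit.k != 1:
        raise ValueError("null_fit must be the intercept-only model")
    if not np.array_equal(fit.y, null_fit.y):
        raise ValueError("fits use different observations")
    if null_fit.llf == 0:
        raise ValueError("degenerate null log-likelihood of zero")
    return 1.0 - fit.llf / null_fit.llf


def fit_null(design: pd.DataFrame, outcome: str = "density",
             offset_col: Optional[str] = None) -> ModelFit:
    """Intercept-only fit used as the pseudo-r-squared reference."""
    return fit_poisson(design, terms=(), outcome=outcome, forced_terms=(),
                       offset_col=offset_col)


@dataclass
class OutlierReport:
    """Studentized-residual outlier screen with Bonferroni adjustment."""

    table: pd.DataFrame  # residual, p, p_bonferroni, outlier
    alpha: float

    @property
    def n_flagged(self) -> int:
        return int(self.table["outlier"].sum())

    @property
    def flagged_ids(self) -> list:
        return list(self.table.index[self.table["outlier"]])


def bonferroni_outlier_test(fit: ModelFit, alpha: float = 0.05) -> OutlierReport:
    """Flag observations with statistically unexpected outcomes.

    Residuals are studentized deviance residuals
    ``r_i / sqrt(1 - h_i)`` with ``h_i`` the GLM leverage; two-sided p-values
    come from the standard normal reference and are Bonferroni-multiplied by
    the number of observations. Flags fall at adjusted p < ``alpha``.
    """
    if fit.n_obs < 3:
        raise ValueError("outlier test needs at least 3 observations")
    y, mu, h = fit.y, fit.mu, fit.glm.hat_
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("degenerate leverage (h = 1) encountered")
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
    dev_res = np.sign(y - mu) * np.sqrt(np.clip(2.0 * unit, 0.0, None))
    student = dev_res / np.sqrt(1.0 - h)
    p = 2.0 * stats.norm.sf(np.abs(student))
    p_bonf = np.minimum(1.0, fit.n_obs * p)
    table = pd.DataFrame(
        {
            "residual": student,
            "leverage": h,
            "p": p,
            "p_bonferroni": p_bonf,
            "outlier": p_bonf < alpha,
        },
        index=fit.design_index
        if fit.design_index is not None
        else pd.RangeIndex(fit.n_obs),
    )
    return OutlierReport(table=table, alpha=alpha)
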