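"""Cumulative logit (proportional-odds) models for 4-level Frankl ratings.

Model.  For an ordinal response :math:`Y \\in \\{1,\\dots,K\\}` (here the
four Frankl categories) and covariate vector :math:`x`, the
proportional-odds cumulative logit model is

.. math::

    \\mathrm{logit}\\, P(Y \\le j \\mid x) = \\theta_j - x'\\beta,
    \\qquad j = 1, \\dots, K-1,

with strictly increasing thresholds :math:`\\theta_1 < \\dots <
\\theta_{K-1}` and a single slope vector :math:`\\beta` shared across the
:math:`K-1` cumulative logits.  Under this sign convention a positive
slope shifts probability mass toward *higher* (more cooperative)
categories.  The unconstrained alternative used to test the
proportional-odds assumption gives each cumulative logit its own slope
vector (:class:`NonProportionalLogitModel`).

Estimation is by maximum likelihood with an analytic gradient; the
threshold ordering is enforced by the log-increment reparameterization
:math:`\\theta_1,\\ \\theta_1 + e^{\\gamma_2},\\ \\theta_1 + e^{\\gamma_2}
+ e^{\\gamma_3}`.  The observed-information covariance matrix is obtained
by differentiating the analytic gradient numerically at the optimum.

The module follows the Model / Results split: construct a model from data
(``CumulativeLogitModel.from_long``), call :meth:`~CumulativeLogitModel.fit`,
and read estimates, standard errors, information criteria and predictions
off the returned results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "STUDY_PREDICTORS",
    "ModelSpec",
    "design_matrix",
    "CumulativeLogitModel",
    "CumulativeLogitResults",
    "NonProportionalLogitModel",
    "NonProportionalResults",
    "fit_proportional",
    "fit_nonproportional",
    "predict_probs",
    "wald_ci",
    "bic",
    "lrt_proportionality",
    "pearson_gof",
]

#: the ten study predictors eligible for modelling
STUDY_PREDICTORS = (
    "Phase",
    "Init.Rating",
    "Age",
    "Gender",
    "Natural birth",
    "Medications",
    "Previous anesthesia",
    "Dental health status",
    "Gingival status",
    "Plaque index",
)

_K = 4  # Frankl categories


@dataclass(frozen=True)
class ModelSpec:
    """A candidate regression: main effects plus at most one Phase x X
    interaction (X must itself be a main effect)."""

    main_effects: tuple[str, ...]
    interaction: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "main_effects", tuple(self.main_effects))
        unknown = [p for p in self.main_effects if p not in STUDY_PREDICTORS]
        if unknown:
            raise ValueError(f"unknown predictors {unknown}; vocabulary is "
                             f"{STUDY_PREDICTORS}")
        if len(set(self.main_effects)) != len(self.main_effects):
            raise ValueError("duplicate main effects")
        if self.interaction is not None:
            if "Phase" not in self.main_effects:
                raise ValueError("interaction requires Phase as a main effect")
            if self.interaction not in self.main_effects:
                raise ValueError("interaction partner must be a main effect")
            if self.interaction == "Phase":
                raise ValueError("Phase cannot interact with itself")

    def label(self) -> str:
        parts = list(self.main_effects)
        if self.interaction:
            parts.append(f"Phase:{self.interaction}")
        return " + ".join(parts) if parts else "1"


# per-predictor design-column builders; categorical predictors are dummy
# coded with the first level as reference
def _dummy(series: pd.Series, positive: str) -> pd.Series:
    mapped = series.map(lambda v: np.nan if pd.isna(v)
                        else (1.0 if str(v).lower() == positive else 0.0))
    return mapped.astype(float)


def _level_dummies(series: pd.Series, levels: Sequence[int], prefix: str):
    out = {}
    for lev in levels[1:]:
        out[f"{prefix} {lev}"] = series.map(
            lambda v, lev=lev: np.nan if pd.isna(v)
            else (1.0 if int(v) == lev else 0.0)).astype(float)
    return out


def _builder(name: str, df: pd.DataFrame) -> dict[str, pd.Series]:
    if name == "Phase":
        return {"Phase": df["phase"].astype(float)}
    if name == "Init.Rating":
        return {"Init.Rating": df["init_rating"].astype(float)}
    if name == "Age":
        return {"Age": df["age"].astype(float)}
    if name == "Gender":
        return {"Gender (female)": _dummy(df["gender"], "female")}
    if name == "Natural birth":
        return {"Natural birth (yes)": _dummy(df["natural_birth"], "yes")}
    if name == "Medications":
        return {"Medications (no)": _dummy(df["medication"], "no")}
    if name == "Previous anesthesia":
        return {"Previous anesthesia (yes)":
                _dummy(df["previous_anesthesia"], "yes")}
    if name == "Dental health status":
        return {"Dental health status": df["dmft"].astype(float)}
    if name == "Gingival status":
        return _level_dummies(df["gingival_status"], [1, 2, 3], "Gingival")
    if name == "Plaque index":
        return _level_dummies(df["plaque_index"], [1, 2, 3, 4], "Plaque")
    raise ValueError(f"unknown predictor {name!r}")


def design_matrix(long_df: pd.DataFrame, spec: ModelSpec):
    """Build ``(y, X, names, index)`` for a spec on long-format data.

    Rows with a missing value in any design column are dropped
    (complete-case analysis restricted to the spec's own predictors).
    ``index`` is the surviving index of ``long_df``.
    """
    cols: dict[str, pd.Series] = {}
    for name in spec.main_effects:
        cols.update(_builder(name, long_df))
    if spec.interaction is not None:
        phase = cols["Phase"]
        for cname, series in _builder(spec.interaction, long_df).items():
            cols[f"Phase:{cname}"] = phase * series
    X = pd.DataFrame(cols, index=long_df.index) if cols else \
        pd.DataFrame(index=long_df.index)
    keep = ~X.isna().any(axis=1) if len(cols) else pd.Series(True, index=long_df.index)
    y = long_df.loc[keep, "rating"].to_numpy(dtype=int)
    Xk = X.loc[keep].to_numpy(dtype=float) if len(cols) else \
        np.empty((int(keep.sum()), 0))
    return y, Xk, list(X.columns), long_df.index[keep]


def _start_thresholds(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Empirical cumulative logits (lightly smoothed) as starting values."""
    totals = np.array([w[y == k].sum() for k in range(1, _K + 1)]) + 0.25
    cum = np.cumsum(totals)[:-1] / totals.sum()
    theta = np.log(cum / (1 - cum))
    # force strict ordering in degenerate cases
    for j in range(1, _K - 1):
        theta[j] = max(theta[j], theta[j - 1] + 1e-3)
    return theta


def _theta_from_gamma(gamma: np.ndarray) -> np.ndarray:
    return np.concatenate([[gamma[0]],
                           gamma[0] + np.cumsum(np.exp(gamma[1:]))])


def _gamma_from_theta(theta: np.ndarray) -> np.ndarray:
    return np.concatenate([[theta[0]], np.log(np.diff(theta))])


class CumulativeLogitModel:
    """Proportional-odds cumulative logit model for a 4-level ordinal
    response.

    Parameters
    ----------
    endog : array of int
        Ratings in 1..4.
    exog : 2-d array
        Design matrix (may have zero columns for the null model).
    exog_names : list of str, optional
    weights : array, optional
        Frequency weights (grouped-data fitting).  The likelihood of
        row-expanded and count-weighted data is identical.
    spec : ModelSpec, optional
        Retained for bookkeeping when built via :meth:`from_long`.
    """

    def __init__(self, endog, exog, exog_names=None, weights=None, spec=None):
        self.endog = np.asarray(endog, dtype=int)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        if len(self.endog) == 0:
            raise ValueError("no observations")
        if self.endog.min() < 1 or self.endog.max() > _K:
            raise ValueError("ratings must be in 1..4")
        n, p = self.exog.shape
        if n != len(self.endog):
            raise ValueError("endog and exog lengths differ")
        self.exog_names = list(exog_names) if exog_names is not None else \
            [f"x{j}" for j in range(p)]
        w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        self.weights = w
        self.spec = spec
        self.k_exog = p
        # collapse to unique (x, y) patterns: the log-likelihood only
        # depends on pattern counts, and bootstrap refits become cheap
        key = np.column_stack([self.exog, self.endog[:, None]])
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        cw = np.zeros(len(uniq))
        np.add.at(cw, inv, w)
        self._X = uniq[:, :p]
        self._y = uniq[:, p].astype(int)
        self._w = cw
        self.nobs = float(w.sum())

    # ------------------------------------------------------------------
    @classmethod
    def from_long(cls, long_df: pd.DataFrame, spec: ModelSpec,
                  weights=None) -> "CumulativeLogitModel":
        """Build the model from long-format data for a given spec,
        restricting to complete cases on the spec's own predictors."""
        y, X, names, index = design_matrix(long_df, spec)
        w = None
        if weights is not None:
            w = np.asarray(pd.Series(weights, index=long_df.index).loc[index],
                           dtype=float)
        model = cls(y, X, exog_names=names, weights=w, spec=spec)
        model.used_index = index
        return model

    # ------------------------------------------------------------------
    def _nll_grad_full(self, params: np.ndarray):
        """Negative log-likelihood and gradient in (theta, beta) space."""
        theta = params[:_K - 1]
        beta = params[_K - 1:]
        X, y, w = self._X, self._y, self._w
        xb = X @ beta if self.k_exog else np.zeros(len(y))
        # F_j = P(Y <= j), padded with F_0 = 0, F_K = 1
        F = np.empty((len(y), _K + 1))
        F[:, 0] = 0.0
        F[:, -1] = 1.0
        F[:, 1:_K] = expit(theta[None, :] - xb[:, None])
        f = F[:, 1:_K] * (1.0 - F[:, 1:_K])  # logistic density at each cut
        idx = np.arange(len(y))
        p = F[idx, y] - F[idx, y - 1]
        p_safe = np.clip(p, 1e-300, None)
        nll = -np.dot(w, np.log(p_safe))
        # gradient
        f_up = np.where(y <= _K - 1, f[idx, np.minimum(y, _K - 1) - 1], 0.0)
        f_up = np.where(y == _K, 0.0, f_up)
        f_lo = np.where(y >= 2, f[idx, np.maximum(y - 1, 1) - 1], 0.0)
        r = w / p_safe
        g_theta = np.zeros(_K - 1)
        up_mask = y <= _K - 1
        np.add.at(g_theta, y[up_mask] - 1, -(r * f_up)[up_mask])
        lo_mask = y >= 2
        np.add.at(g_theta, y[lo_mask] - 2, (r * f_lo)[lo_mask])
        if self.k_exog:
            g_beta = X.T @ (r * (f_up - f_lo))
        else:
            g_beta = np.zeros(0)
        return nll, np.concatenate([g_theta, g_beta])

    def negloglik(self, params: np.ndarray) -> float:
        """Negative log-likelihood at ``params = (theta_1..theta_3, beta)``."""
        return self._nll_grad_full(np.asarray(params, dtype=float))[0]

    def score(self, params: np.ndarray) -> np.ndarray:
        """Gradient of the *negative* log-likelihood."""
        return self._nll_grad_full(np.asarray(params, dtype=float))[1]

    def _nll_grad_gamma(self, q: np.ndarray):
        gamma, beta = q[:_K - 1], q[_K - 1:]
        theta = _theta_from_gamma(gamma)
        nll, g = self._nll_grad_full(np.concatenate([theta, beta]))
        gt = g[:_K - 1]
        gg = np.empty(_K - 1)
        gg[0] = gt.sum()
        for j in range(1, _K - 1):
            gg[j] = gt[j:].sum() * np.exp(gamma[j])
        return nll, np.concatenate([gg, g[_K - 1:]])

    def _hessian_analytic(self, params: np.ndarray) -> np.ndarray:
        """Observed information (Hessian of the negative log-likelihood)
        in (theta, beta) space, exact.

        With eta_j = theta_j - x'beta linear in the parameters, the
        Hessian of each log cell probability is a quadratic form in the
        gradients of the two adjacent cut linear predictors.
        """
        theta = params[:_K - 1]
        beta = params[_K - 1:]
        X, y, w = self._X, self._y, self._w
        n, p = X.shape
        xb = X @ beta if p else np.zeros(n)
        F = np.empty((n, _K + 1))
        F[:, 0] = 0.0
        F[:, -1] = 1.0
        F[:, 1:_K] = expit(theta[None, :] - xb[:, None])
        idx = np.arange(n)
        prob = np.clip(F[idx, y] - F[idx, y - 1], 1e-300, None)
        has_u = y <= _K - 1
        has_l = y >= 2
        Fu = np.where(has_u, F[idx, np.minimum(y, _K - 1)], 0.0)
        Fl = np.where(has_l, F[idx, np.maximum(y - 1, 1)], 0.0)
        u = np.where(has_u, Fu * (1 - Fu), 0.0)
        l = np.where(has_l, Fl * (1 - Fl), 0.0)
        du = u * (1 - 2 * Fu)      # d f / d eta at the upper cut
        dl = l * (1 - 2 * Fl)
        # second derivatives of log prob wrt the two cut etas
        Auu = np.where(has_u, du / prob - (u / prob) ** 2, 0.0)
        All = np.where(has_l, -dl / prob - (l / prob) ** 2, 0.0)
        Aul = np.where(has_u & has_l, u * l / prob ** 2, 0.0)
        k = len(params)
        H = np.zeros((k, k))
        a = np.where(has_u, y - 1, 0)       # 0-based upper-cut index
        b = np.where(has_l, y - 2, 0)       # 0-based lower-cut index
        # theta-theta block
        np.add.at(H, (a[has_u], a[has_u]), (w * Auu)[has_u])
        np.add.at(H, (b[has_l], b[has_l]), (w * All)[has_l])
        both = has_u & has_l
        np.add.at(H, (a[both], b[both]), (w * Aul)[both])
        np.add.at(H, (b[both], a[both]), (w * Aul)[both])
        if p:
            # theta-beta block: row a gets -(Auu + Aul) x, row b -(All + Aul) x
            cu = w * (Auu + Aul)
            cl = w * (All + Aul)
            for j in range(_K - 1):
                mu = has_u & (a == j)
                ml = has_l & (b == j)
                row = -(X[mu].T @ cu[mu]) - (X[ml].T @ cl[ml])
                H[j, _K - 1:] += row
                H[_K - 1:, j] += row
            s = w * (Auu + 2 * Aul + All)
            H[_K - 1:, _K - 1:] = (X * s[:, None]).T @ X
        return -H  # Hessian of the NEGATIVE log-likelihood

    def _fit_newton(self, q0_full: np.ndarray, tol: float, max_iter: int):
        """Newton iteration in (theta, beta) space with step halving;
        returns (params, nll, gnorm, n_iter) or None on failure."""
        params = q0_full.copy()
        nll, g = self._nll_grad_full(params)
        if not np.isfinite(nll):
            return None
        for it in range(max_iter):
            gnorm = float(np.linalg.norm(g, np.inf))
            if gnorm < tol * max(1.0, abs(nll)):
                return params, nll, gnorm, it
            H = self._hessian_analytic(params)
            scale = max(1.0, float(np.trace(H)) / len(params))
            cand = None
            for damp in (0.0, 1e-6, 1e-3, 1e-1, 1e1):
                try:
                    step = np.linalg.solve(
                        H + damp * scale * np.eye(len(params)), -g)
                except np.linalg.LinAlgError:
                    continue
                if not np.all(np.isfinite(step)) or step @ g >= 0:
                    continue
                lam = 1.0
                for _ in range(30):
                    trial = params + lam * step
                    theta = trial[:_K - 1]
                    if np.all(np.diff(theta) > 0):
                        t_nll, t_g = self._nll_grad_full(trial)
                        if np.isfinite(t_nll) and t_nll <= nll + 1e-12:
                            cand, cand_nll, cand_g = trial, t_nll, t_g
                            break
                    lam *= 0.5
                if cand is not None:
                    break
            if cand is None:
                return None
            if abs(nll - cand_nll) < 1e-13 * max(1.0, abs(nll)) and \
                    float(np.linalg.norm(cand_g, np.inf)) < 1e-6:
                return cand, cand_nll, float(np.linalg.norm(cand_g, np.inf)), it
            params, nll, g = cand, cand_nll, cand_g
        gnorm = float(np.linalg.norm(g, np.inf))
        return (params, nll, gnorm, max_iter) if gnorm < 1e-5 else None

    def _hessian(self, params: np.ndarray, step: float = 1e-5) -> np.ndarray:
        """Observed information: central differences of the analytic score."""
        k = len(params)
        H = np.empty((k, k))
        for i in range(k):
            h = step * max(1.0, abs(params[i]))
            up = params.copy(); up[i] += h
            dn = params.copy(); dn[i] -= h
            H[i] = (self.score(up) - self.score(dn)) / (2 * h)
        return 0.5 * (H + H.T)

    def fit(self, tol: float = 1e-8, max_iter: int = 500,
            start_params=None, compute_vcov: bool = True
            ) -> "CumulativeLogitResults":
        """Maximum-likelihood fit (BFGS on the order-enforcing
        reparameterization, analytic gradient).

        ``compute_vcov=False`` skips the observed-information matrix
        (used by bootstrap refits, which only need point estimates)."""
        y, w = self._y, self._w
        cat_totals = np.array([w[y == k].sum() for k in range(1, _K + 1)])
        degenerate = bool(np.any(cat_totals == 0))
        if np.count_nonzero(cat_totals) < 2:
            raise ValueError("response must take at least 2 categories")
        if start_params is not None:
            start_full = np.asarray(start_params, dtype=float).copy()
        else:
            start_full = np.concatenate([_start_thresholds(y, w),
                                         np.zeros(self.k_exog)])
        newton = None if degenerate else \
            self._fit_newton(start_full, tol, max_iter)
        if newton is not None:
            params, nll, gnorm, n_iter = newton
            converged = True
        else:
            q0 = np.concatenate([_gamma_from_theta(start_full[:_K - 1]),
                                 start_full[_K - 1:]])
            res = optimize.minimize(self._nll_grad_gamma, q0, jac=True,
                                    method="BFGS",
                                    options={"gtol": tol,
                                             "maxiter": max_iter})
            theta = _theta_from_gamma(res.x[:_K - 1])
            params = np.concatenate([theta, res.x[_K - 1:]])
            nll = float(res.fun)
            n_iter = int(res.nit)
            gnorm = float(np.linalg.norm(self.score(params), np.inf))
            converged = bool(res.success or gnorm < 1e-5)
        beta = params[_K - 1:]
        if compute_vcov:
            H = self._hessian_analytic(params)
            try:
                vcov = np.linalg.inv(H)
                psd = bool(np.all(np.linalg.eigvalsh(vcov) > -1e-8))
            except np.linalg.LinAlgError:
                vcov = np.linalg.pinv(H)
                psd = False
        else:
            vcov = np.full((len(params), len(params)), np.nan)
            psd = True
        separation = bool(np.any(np.abs(beta) > 30))
        if not psd:
            degenerate = True
        return CumulativeLogitResults(
            model=self, params=params, llf=-float(nll), vcov=vcov,
            converged=converged and not separation,
            degenerate=degenerate, separation=separation, gnorm=gnorm,
            n_iter=n_iter)


class CumulativeLogitResults:
    """MLE results for a proportional-odds cumulative logit fit.

    Attributes
    ----------
    params : ndarray
        ``(theta_1, theta_2, theta_3, beta_1, ..., beta_p)``.
    llf : float
        Maximized log-likelihood.
    vcov : ndarray
        Inverse observed information, same ordering as ``params``.
    """

    def __init__(self, model, params, llf, vcov, converged, degenerate,
                 separation=False, gnorm=np.nan, n_iter=0):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.llf = float(llf)
        self.vcov = np.asarray(vcov, dtype=float)
        self.converged = bool(converged)
        self.degenerate = bool(degenerate)
        self.separation = bool(separation)
        self.gnorm = gnorm
        self.n_iter = n_iter
        self.nobs = model.nobs
        self.k_params = len(self.params)

    # -- parameter views ----------------------------------------------
    @property
    def thresholds(self) -> np.ndarray:
        return self.params[:_K - 1]

    @property
    def slopes(self) -> pd.Series:
        return pd.Series(self.params[_K - 1:], index=self.model.exog_names)

    @property
    def param_names(self) -> list[str]:
        return [f"theta_{j}" for j in range(1, _K)] + list(self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))
        return pd.Series(se, index=self.param_names)

    @property
    def zvalues(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names) / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.param_names)

    @property
    def bic(self) -> float:
        """-2 loglik + k log(n), n = number of long-format rows fitted."""
        return -2.0 * self.llf + self.k_params * np.log(self.nobs)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    # -- inference ----------------------------------------------------
    def conf_int(self, alpha: float = 0.05, method: str = "wald"
                 ) -> pd.DataFrame:
        """Confidence intervals for all parameters.

        ``method="wald"`` gives symmetric normal-theory intervals;
        ``method="profile"`` inverts the signed likelihood-ratio statistic
        for the slope parameters (thresholds keep Wald intervals), which
        is what mainstream ordinal-regression software prints.
        """
        if not self.converged:
            raise ValueError("confidence intervals require a converged fit")
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.bse.to_numpy()
        lo = self.params - z * se
        hi = self.params + z * se
        if method == "profile":
            for j in range(_K - 1, self.k_params):
                lo[j], hi[j] = self._profile_interval(j, alpha)
        elif method != "wald":
            raise ValueError(f"unknown CI method {method!r}")
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.param_names)

    def _profile_llf(self, j: int, value: float) -> float:
        """Maximized log-likelihood with parameter j fixed at ``value``."""
        m = self.model
        col = j - (_K - 1)
        keep = [c for c in range(m.k_exog) if c != col]
        offset = m._X[:, col] * value
        sub = CumulativeLogitModel.__new__(CumulativeLogitModel)
        sub.endog = m.endog
        sub._X = m._X[:, keep]
        sub._y = m._y
        sub._w = m._w
        sub.k_exog = len(keep)
        sub.exog_names = [m.exog_names[c] for c in keep]
        sub.nobs = m.nobs
        sub.spec = None

        # profile out the remaining parameters with column j held fixed,
        # implemented as a fixed-slope offset column
        def shifted(params):
            theta = params[:_K - 1]
            beta = params[_K - 1:]
            # evaluate on the shifted linear predictor by temporarily
            # appending the offset as a fixed-slope column
            full_X = np.column_stack([sub._X, offset]) if sub.k_exog else \
                offset[:, None]
            tmp = CumulativeLogitModel.__new__(CumulativeLogitModel)
            tmp._X = full_X
            tmp._y = sub._y
            tmp._w = sub._w
            tmp.k_exog = full_X.shape[1]
            nll, g = tmp._nll_grad_full(
                np.concatenate([theta, beta, [1.0]]))
            return nll, g[:len(params)]
        start = np.concatenate([self.thresholds,
                                np.delete(self.params[_K - 1:], col)])
        q0 = np.concatenate([_gamma_from_theta(start[:_K - 1]),
                             start[_K - 1:]])

        def in_gamma(q):
            gamma, beta = q[:_K - 1], q[_K - 1:]
            theta = _theta_from_gamma(gamma)
            nll, g = shifted(np.concatenate([theta, beta]))
            gt = g[:_K - 1]
            gg = np.empty(_K - 1)
            gg[0] = gt.sum()
            for k in range(1, _K - 1):
                gg[k] = gt[k:].sum() * np.exp(gamma[k])
            return nll, np.concatenate([gg, g[_K - 1:]])
        res = optimize.minimize(in_gamma, q0, jac=True, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 500})
        return -float(res.fun)

    def _profile_interval(self, j: int, alpha: float):
        target = stats.chi2.ppf(1 - alpha, 1) / 2.0
        mle = self.params[j]
        se = max(self.bse.iloc[j], 1e-6)

        def deficit(v):
            return (self.llf - self._profile_llf(j, v)) - target
        bounds = []
        for sign in (-1.0, 1.0):
            lo_mult, hi_mult = 0.5, 6.0
            a = mle + sign * lo_mult * se
            b = mle + sign * hi_mult * se
            fa, fb = deficit(a), deficit(b)
            while fb < 0 and hi_mult < 50:
                hi_mult *= 2
                b = mle + sign * hi_mult * se
                fb = deficit(b)
            if fa > 0:
                a = mle
                fa = -target
            try:
                root = optimize.brentq(deficit, min(a, b), max(a, b),
                                       xtol=1e-6)
            except ValueError:
                root = mle + sign * 1.96 * se
            bounds.append(root)
        return min(bounds), max(bounds)

    # -- prediction ---------------------------------------------------
    def _design_row(self, x) -> np.ndarray:
        names = self.model.exog_names
        if isinstance(x, Mapping):
            row = np.empty(len(names))
            for i, name in enumerate(names):
                if name in x:
                    row[i] = float(x[name])
                elif name.startswith("Phase:") and name[6:] in x and "Phase" in x:
                    row[i] = float(x["Phase"]) * float(x[name[6:]])
                else:
                    raise ValueError(f"covariate setting for {name!r} missing")
            extra = set(x) - set(names) - {n[6:] for n in names
                                           if n.startswith("Phase:")}
            if extra:
                raise ValueError(f"unknown covariates {sorted(extra)}")
            return row
        row = np.asarray(x, dtype=float)
        if row.shape != (len(names),):
            raise ValueError(f"expected {len(names)} covariate values")
        return row

    def predict(self, x) -> np.ndarray:
        """Category probabilities :math:`(P(Y=1),\\dots,P(Y=4))` at a
        covariate setting ``x`` (mapping of design names, or a vector)."""
        row = self._design_row(x)
        xb = float(row @ self.params[_K - 1:]) if self.model.k_exog else 0.0
        F = np.concatenate([[0.0], expit(self.thresholds - xb), [1.0]])
        return np.diff(F)

    def cumulative(self, x) -> np.ndarray:
        """:math:`P(Y \\le j)` for j = 1..3 at a covariate setting."""
        row = self._design_row(x)
        xb = float(row @ self.params[_K - 1:]) if self.model.k_exog else 0.0
        return expit(self.thresholds - xb)

    # -- reporting ----------------------------------------------------
    def summary(self, alpha: float = 0.05, ci_method: str = "wald") -> str:
        ci = self.conf_int(alpha=alpha, method=ci_method) if self.converged \
            else None
        lines = []
        label = self.model.spec.label() if self.model.spec else \
            " + ".join(self.model.exog_names) or "1"
        lines.append("Cumulative logit model (proportional odds)")
        lines.append(f"  predictors: {label}")
        lines.append(f"  n obs (long rows): {self.nobs:.0f}"
                     f"   loglik: {self.llf:.3f}   BIC: {self.bic:.2f}")
        lines.append(f"  converged: {self.converged}"
                     f"   degenerate: {self.degenerate}")
        lines.append(f"  {'param':<26}{'est':>9}{'se':>9}"
                     f"{'ci_low':>9}{'ci_high':>9}{'p':>10}")
        se = self.bse
        pv = self.pvalues
        for i, name in enumerate(self.param_names):
            lo = ci.iloc[i, 0] if ci is not None else np.nan
            hi = ci.iloc[i, 1] if ci is not None else np.nan
            lines.append(f"  {name:<26}{self.params[i]:>9.3f}"
                         f"{se.iloc[i]:>9.3f}{lo:>9.3f}{hi:>9.3f}"
                         f"{pv.iloc[i]:>10.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable view of the fit."""
        return {
            "spec": self.model.spec.label() if self.model.spec else None,
            "param_names": self.param_names,
            "params": self.params.tolist(),
            "thresholds": self.thresholds.tolist(),
            "slopes": self.slopes.to_dict(),
            "vcov": self.vcov.tolist(),
            "loglik": self.llf,
            "bic": self.bic,
            "nobs": self.nobs,
            "converged": self.converged,
            "degenerate": self.degenerate,
        }


class NonProportionalLogitModel:
    """Unconstrained cumulative logit model: each of the three cumulative
    logits has its own threshold and slope vector,

    .. math:: \\mathrm{logit}\\, P(Y \\le j \\mid x) = \\theta_j - x'\\beta_j.

    Monotonicity of the implied cumulative probabilities in j is *not*
    enforced; this is the standard unconstrained alternative for the
    likelihood-ratio test of the proportional-odds assumption.  Parameter
    layout: ``(theta_1..theta_3, beta_1 (p), beta_2 (p), beta_3 (p))``.
    """

    def __init__(self, endog, exog, exog_names=None, weights=None, spec=None):
        base = CumulativeLogitModel(endog, exog, exog_names=exog_names,
                                    weights=weights, spec=spec)
        self._base = base
        self.endog, self.exog = base.endog, base.exog
        self.exog_names = base.exog_names
        self.weights = base.weights
        self.spec = spec
        self.k_exog = base.k_exog
        self._X, self._y, self._w = base._X, base._y, base._w
        self.nobs = base.nobs

    @classmethod
    def from_long(cls, long_df, spec, weights=None):
        y, X, names, index = design_matrix(long_df, spec)
        w = None
        if weights is not None:
            w = np.asarray(pd.Series(weights, index=long_df.index).loc[index],
                           dtype=float)
        model = cls(y, X, exog_names=names, weights=w, spec=spec)
        model.used_index = index
        return model

    def _unpack(self, params):
        p = self.k_exog
        theta = params[:_K - 1]
        B = params[_K - 1:].reshape(_K - 1, p) if p else \
            np.zeros((_K - 1, 0))
        return theta, B

    def _nll_grad(self, params):
        theta, B = self._unpack(params)
        X, y, w = self._X, self._y, self._w
        n, p = X.shape
        eta = theta[None, :] - (X @ B.T if p else np.zeros((n, _K - 1)))
        F = np.empty((n, _K + 1))
        F[:, 0] = 0.0
        F[:, -1] = 1.0
        F[:, 1:_K] = expit(eta)
        idx = np.arange(n)
        prob = F[idx, y] - F[idx, y - 1]
        if np.any(prob <= 0):
            # infeasible configuration of the unconstrained model
            return 1e10 + float(np.sum(np.clip(-prob, 0, None))), \
                np.zeros_like(params)
        f = F[:, 1:_K] * (1 - F[:, 1:_K])
        nll = -np.dot(w, np.log(prob))
        r = w / prob
        g_theta = np.zeros(_K - 1)
        gB = np.zeros((_K - 1, p))
        up = y <= _K - 1
        lo = y >= 2
        ju = y[up] - 1          # 0-based cut index for F_y
        jl = y[lo] - 2          # 0-based cut index for F_{y-1}
        np.add.at(g_theta, ju, -(r[up] * f[up, ju]))
        np.add.at(g_theta, jl, (r[lo] * f[lo, jl]))
        if p:
            for j in range(_K - 1):
                mu = up & (y - 1 == j)
                ml = lo & (y - 2 == j)
                contrib = np.zeros(n)
                contrib[mu] += (r * f[:, j])[mu]
                contrib[ml] -= (r * f[:, j])[ml]
                gB[j] = X.T @ contrib
        return nll, np.concatenate([g_theta, gB.ravel()])

    def fit(self, tol: float = 1e-8, max_iter: int = 1000,
            start: Optional[CumulativeLogitResults] = None
            ) -> "NonProportionalResults":
        """MLE starting from the proportional fit (fitted internally when
        ``start`` is not supplied)."""
        if start is None:
            start = CumulativeLogitModel(
                self.endog, self.exog, exog_names=self.exog_names,
                weights=self.weights, spec=self.spec).fit()
        p = self.k_exog
        x0 = np.concatenate([start.thresholds,
                             np.tile(start.params[_K - 1:], _K - 1)])
        res = optimize.minimize(self._nll_grad, x0, jac=True, method="BFGS",
                                options={"gtol": tol, "maxiter": max_iter})
        params = res.x
        gnorm = float(np.linalg.norm(self._nll_grad(params)[1], np.inf))
        theta, B = self._unpack(params)
        # flag non-monotone fitted cumulative probabilities at observed x
        eta = theta[None, :] - (self._X @ B.T if p else
                                np.zeros((len(self._y), _K - 1)))
        nonmonotone = bool(np.any(np.diff(expit(eta), axis=1) < -1e-12))
        return NonProportionalResults(
            model=self, params=params, llf=-float(res.fun),
            converged=bool(res.success or gnorm < 1e-4),
            nonmonotone=nonmonotone)


class NonProportionalResults:
    """Results of the unconstrained (per-logit slopes) cumulative logit fit."""

    def __init__(self, model, params, llf, converged, nonmonotone):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.nonmonotone = bool(nonmonotone)
        self.nobs = model.nobs
        self.k_params = (_K - 1) * (1 + model.k_exog)

    @property
    def thresholds(self) -> np.ndarray:
        return self.params[:_K - 1]

    @property
    def slopes(self) -> pd.DataFrame:
        p = self.model.k_exog
        B = self.params[_K - 1:].reshape(_K - 1, p) if p else \
            np.zeros((_K - 1, 0))
        return pd.DataFrame(B, index=[f"logit_{j}" for j in range(1, _K)],
                            columns=self.model.exog_names)

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.nobs)


# ----------------------------------------------------------------------
# convenience functional layer

def fit_proportional(spec: ModelSpec, long_df: pd.DataFrame,
                     tol: float = 1e-8, max_iter: int = 500,
                     weights=None) -> CumulativeLogitResults:
    """Fit a proportional-odds model for ``spec`` on long-format data."""
    return CumulativeLogitModel.from_long(long_df, spec,
                                          weights=weights).fit(
        tol=tol, max_iter=max_iter)


def fit_nonproportional(spec: ModelSpec, long_df: pd.DataFrame,
                        weights=None) -> NonProportionalResults:
    """Fit the per-logit-slopes alternative for ``spec``."""
    return NonProportionalLogitModel.from_long(long_df, spec,
                                               weights=weights).fit()


def predict_probs(fit: CumulativeLogitResults, x) -> np.ndarray:
    """Category probabilities at covariate setting ``x`` (sums to 1)."""
    return fit.predict(x)


def wald_ci(fit: CumulativeLogitResults, coef: str, level: float = 0.95):
    """Wald interval and two-sided p-value for one named coefficient."""
    ci = fit.conf_int(alpha=1 - level, method="wald")
    if coef not in ci.index:
        raise KeyError(f"no parameter named {coef!r}")
    se = fit.bse[coef]
    if se == 0:
        warnings.warn(f"degenerate (zero-SE) interval for {coef!r}")
    return float(ci.loc[coef, "lower"]), float(ci.loc[coef, "upper"])


def bic(fit) -> float:
    """Bayesian information criterion of a fitted model."""
    return fit.bic


def lrt_proportionality(prop: CumulativeLogitResults,
                        nonprop: NonProportionalResults):
    """LRT of the proportional-odds assumption.

    Returns ``(statistic, df, p)`` where ``statistic = 2 (llf_nonprop -
    llf_prop)`` and ``df`` is the difference in free parameters
    (= 2 x number of slope columns).
    """
    if prop.model.exog_names != nonprop.model.exog_names or \
            prop.nobs != nonprop.nobs:
        raise ValueError("fits must share the same spec and data")
    stat = max(0.0, 2.0 * (nonprop.llf - prop.llf))
    df = nonprop.k_params - prop.k_params
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return float(stat), int(df), p


def pearson_gof(fit: CumulativeLogitResults, floor: float = 1.0):
    """Pearson chi-square goodness of fit over observed covariate patterns.

    Cells are the distinct covariate patterns crossed with the 4 response
    categories; ``df = patterns * 3 - k_params``.  Cells with expected
    count below ``floor`` trigger a warning (no automatic merging).
    """
    m = fit.model
    patterns, inv = np.unique(m._X, axis=0, return_inverse=True)
    n_pat = len(patterns)
    O = np.zeros((n_pat, _K))
    np.add.at(O, (inv, m._y - 1), m._w)
    totals = O.sum(axis=1)
    E = np.empty_like(O)
    for g in range(n_pat):
        E[g] = totals[g] * fit.predict(patterns[g])
    low = E < floor
    if np.any(low):
        warnings.warn(f"{int(low.sum())} cells have expected count below "
                      f"{floor}; chi-square approximation may be poor")
    stat = float(np.sum((O - E) ** 2 / np.clip(E, 1e-12, None)))
    df = int(n_pat * (_K - 1) - fit.k_params)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else np.nan
    return stat, df, p
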