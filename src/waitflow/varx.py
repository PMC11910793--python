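"""Vector autoregression with exogenous inputs (VARX) for waiting lists.

The pending stock (one series, or one per elective type) is modelled as a
linear function of its own lagged values and of the contemporaneous flows:

    y[t] = c + sum_{l in L} Phi_l y[t-l] + B x[t] + eps[t],
    eps[t] ~ N(0, Sigma)

with lag set L a subset of {1, 2, 3, 4} (quarterly data; four lags span a
year of seasonal memory) and x[t] the additions and removals in quarter t.
Estimation is conditional Gaussian maximum likelihood: presample values
are conditioned upon, so the coefficient estimates coincide with ordinary
least squares per equation and Sigma is the residual covariance with
divisor n.  Candidate lag sets are compared by AIC = 2k - 2 loglik on a
common estimation sample; k counts all free coefficients plus the free
elements of Sigma.

The estimator follows scikit-learn conventions: construct with
hyper-parameters, ``fit`` a quarterly model frame (see
:meth:`waitflow.panel.WaitlistPanel.to_model_frame`), read fitted
attributes with trailing underscores.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.base import BaseEstimator

__all__ = [
    "VARX",
    "RankDeficientDesignError",
    "build_design",
    "fit_varx",
    "select_model",
    "CANDIDATE_LAG_SETS",
]

#: the candidate lag structures compared during model selection
CANDIDATE_LAG_SETS = ((1,), (4,), (1, 4), (1, 2, 3, 4))

MAX_LAG = 4

#: residuals below this fraction of the response scale mean the design
#: explains the response exactly (e.g. an accounting identity); the
#: Gaussian likelihood then degenerates and is reported as +inf
EXACT_FIT_RTOL = 1e-8


class RankDeficientDesignError(ValueError):
    """Raised when the regression design has collinear columns."""


@dataclass(frozen=True)
class Design:
    """Aligned response/regressor matrices for one lag specification."""

    response: np.ndarray  # (n, m)
    regressors: np.ndarray  # (n, q)
    index: pd.PeriodIndex
    regressor_names: tuple[str, ...]
    endog_names: tuple[str, ...]


def _check_lags(lags: Sequence[int]) -> tuple[int, ...]:
    lags = tuple(sorted(set(int(l) for l in lags)))
    if not lags:
        raise ValueError("lag set must be non-empty")
    if lags[0] < 1 or lags[-1] > MAX_LAG:
        raise ValueError(f"lags must lie in 1..{MAX_LAG}, got {lags}")
    return lags


def build_design(
    frame: pd.DataFrame,
    *,
    endog: Sequence[str] = ("pending",),
    exog: Sequence[str] = ("additions", "removals"),
    lags: Sequence[int] = (1, 4),
    include_intercept: bool = True,
    n_presample: int | None = None,
) -> Design:
    """Build the stacked regression design for the VARX model.

    Row t has response y[t] and regressors {y[t-l] : l in lags}, the
    contemporaneous exogenous values, and an intercept column.  The first
    ``n_presample`` quarters (default max(lags)) are consumed as presample;
    passing a larger value aligns estimation samples across candidate lag
    sets so their AICs are comparable.
    """
    lags = _check_lags(lags)
    endog = tuple(endog)
    exog = tuple(exog)
    missing = [c for c in (*endog, *exog) if c not in frame.columns]
    if missing:
        raise KeyError(f"model frame lacks columns {missing}")
    presample = max(lags) if n_presample is None else int(n_presample)
    if presample < max(lags):
        raise ValueError(f"n_presample must be >= max lag {max(lags)}")
    T = len(frame)
    if T - presample < 1:
        raise ValueError(
            f"panel of {T} quarters too short: need at least {presample + 1} "
            f"quarters for lag set {lags}"
        )
    Y = frame.loc[:, list(endog)].to_numpy(dtype=float)[presample:]
    blocks = []
    names: list[str] = []
    ynum = frame.loc[:, list(endog)].to_numpy(dtype=float)
    for l in lags:
        blocks.append(ynum[presample - l : T - l])
        names.extend(f"{c}.L{l}" for c in endog)
    xnum = frame.loc[:, list(exog)].to_numpy(dtype=float)[presample:]
    if exog:
        blocks.append(xnum)
        names.extend(exog)
    if include_intercept:
        blocks.append(np.ones((T - presample, 1)))
        names.append("const")
    X = np.hstack(blocks)
    return Design(
        response=Y,
        regressors=X,
        index=frame.index[presample:],
        regressor_names=tuple(names),
        endog_names=endog,
    )


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[piv[i]] for i in range(rank, len(names))]


class VARX(BaseEstimator):
    """VARX estimator for quarterly stock-flow frames.

    Parameters
    ----------
    lags:
        Endogenous lag set, a subset of {1, 2, 3, 4}.
    endog, exog:
        Column names of the endogenous block and the contemporaneous
        exogenous inputs in the fitted frame.
    include_intercept:
        Include a constant term per equation.
    n_presample:
        Quarters to condition on (defaults to max(lags)); set explicitly
        when comparing lag sets so samples align.

    Attributes (after ``fit``)
    --------------------------
    coef_ar_ : dict[int, ndarray (m, m)]
        Phi_l per lag; entry [i, j] multiplies endog j at lag l in the
        equation for endog i.
    coef_exog_ : ndarray (m, p)
        B; intercept_ : ndarray (m,); sigma_ : ndarray (m, m);
        loglik_, k_, aic_, nobs_; resid_ and fitted_ as DataFrames;
        exact_fit_ : bool, True when residuals vanish to numerical
        precision (the likelihood degenerates, AIC is reported as -inf).
    """

    def __init__(
        self,
        lags: Sequence[int] = (1, 4),
        endog: Sequence[str] = ("pending",),
        exog: Sequence[str] = ("additions", "removals"),
        include_intercept: bool = True,
        n_presample: int | None = None,
    ):
        self.lags = lags
        self.endog = endog
        self.exog = exog
        self.include_intercept = include_intercept
        self.n_presample = n_presample

    # -- fitting -------------------------------------------------------

    def fit(self, frame: pd.DataFrame, y=None) -> "VARX":
        design = build_design(
            frame,
            endog=self.endog,
            exog=self.exog,
            lags=self.lags,
            include_intercept=self.include_intercept,
            n_presample=self.n_presample,
        )
        X, Y = design.regressors, design.response
        n, q = X.shape
        m = Y.shape[1]
        if n < q + 1:
            raise ValueError(
                f"{n} usable rows is too few to estimate {q} regressors; "
                f"need at least {q + 1}"
            )
        bad = _collinear_columns(X, design.regressor_names)
        if bad:
            raise RankDeficientDesignError(
                f"design is rank deficient; collinear column(s): {bad}"
            )
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        sigma = resid.T @ resid / n

        scale = max(float(np.abs(Y).max()), 1.0)
        exact = bool(np.abs(resid).max() <= EXACT_FIT_RTOL * scale)
        if exact:
            loglik = math.inf
        else:
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                loglik = math.inf
                exact = True
            else:
                loglik = -0.5 * n * (m * math.log(2 * math.pi) + logdet) - 0.5 * n * m

        lags = _check_lags(self.lags)
        self.design_ = design
        self.lags_ = lags
        self.endog_ = design.endog_names
        self.exog_ = tuple(self.exog)
        self.coef_ = beta  # (q, m), rows follow design.regressor_names
        self.coef_ar_ = {
            l: beta[i * m : (i + 1) * m, :].T for i, l in enumerate(lags)
        }
        p = len(self.exog_)
        off = len(lags) * m
        self.coef_exog_ = beta[off : off + p, :].T
        self.intercept_ = (
            beta[off + p, :] if self.include_intercept else np.zeros(m)
        )
        self.sigma_ = sigma
        self.resid_ = pd.DataFrame(resid, index=design.index, columns=self.endog_)
        self.fitted_ = pd.DataFrame(Y - resid, index=design.index, columns=self.endog_)
        self.nobs_ = n
        self.exact_fit_ = exact
        self.loglik_ = float(loglik)
        self.k_ = m * q + m * (m + 1) // 2
        self.aic_ = 2 * self.k_ - 2 * self.loglik_
        return self

    # -- synthetic fits (known dynamics) -------------------------------

    @classmethod
    def from_params(
        cls,
        phi: Mapping[int, np.ndarray | float],
        coef_exog: Sequence[float] | np.ndarray,
        intercept: float | np.ndarray = 0.0,
        sigma: float | np.ndarray = 0.0,
        *,
        endog: Sequence[str] = ("pending",),
        exog: Sequence[str] = ("additions", "removals"),
    ) -> "VARX":
        """Construct a fitted-looking model from known coefficients.

        Used for scenario analysis with postulated dynamics (e.g. the pure
        accounting identity phi_1 = 1, B = (1, -1)) and as an oracle anchor
        in tests.  No likelihood quantities are populated.
        """
        m = len(tuple(endog))
        model = cls(lags=tuple(sorted(phi)), endog=endog, exog=exog)
        model.lags_ = tuple(sorted(int(l) for l in phi))
        model.endog_ = tuple(endog)
        model.exog_ = tuple(exog)
        model.coef_ar_ = {
            int(l): np.atleast_2d(np.asarray(v, dtype=float)) for l, v in phi.items()
        }
        model.coef_exog_ = np.atleast_2d(np.asarray(coef_exog, dtype=float)).reshape(
            m, len(model.exog_)
        )
        model.intercept_ = np.broadcast_to(
            np.asarray(intercept, dtype=float), (m,)
        ).copy()
        sig = np.asarray(sigma, dtype=float)
        model.sigma_ = sig * np.eye(m) if sig.ndim == 0 else sig
        model.exact_fit_ = False
        return model

    # -- forecasting ---------------------------------------------------

    def step(self, lagged: np.ndarray, exog_t: np.ndarray) -> np.ndarray:
        """Conditional mean of y[t] given lagged endogenous values.

        ``lagged`` has shape (max_lag, m) (or (..., max_lag, m) for a batch
        of simulation states), with row l-1 holding y[t-l]; ``exog_t`` is
        the exogenous vector for quarter t.
        """
        lagged = np.asarray(lagged, dtype=float)
        out = self.intercept_ + np.asarray(exog_t, dtype=float) @ self.coef_exog_.T
        for l in self.lags_:
            out = out + lagged[..., l - 1, :] @ self.coef_ar_[l].T
        return out

    # -- reporting -----------------------------------------------------

    def to_report(self) -> dict:
        """JSON-serialisable fit report sufficient to re-run projections."""
        rep = {
            "endog": list(self.endog_),
            "exog": list(self.exog_),
            "lags": list(self.lags_),
            "intercept": np.asarray(self.intercept_).tolist(),
            "coef_ar": {str(l): m.tolist() for l, m in self.coef_ar_.items()},
            "coef_exog": np.asarray(self.coef_exog_).tolist(),
            "sigma": np.asarray(self.sigma_).tolist(),
        }
        for attr in ("loglik_", "k_", "aic_", "nobs_", "exact_fit_"):
            if hasattr(self, attr):
                rep[attr.rstrip("_")] = getattr(self, attr)
        if hasattr(self, "design_"):
            rep["sample"] = [str(self.design_.index[0]), str(self.design_.index[-1])]
        return rep

    def save_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=2)


def fit_varx(
    frame: pd.DataFrame,
    lags: Sequence[int] = (1, 4),
    *,
    endog: Sequence[str] = ("pending",),
    exog: Sequence[str] = ("additions", "removals"),
    include_intercept: bool = True,
    n_presample: int | None = None,
) -> VARX:
    """Fit a VARX model; thin functional wrapper over :class:`VARX`."""
    return VARX(
        lags=lags,
        endog=endog,
        exog=exog,
        include_intercept=include_intercept,
        n_presample=n_presample,
    ).fit(frame)


def select_model(
    frame: pd.DataFrame,
    candidates: Sequence[Sequence[int]] = CANDIDATE_LAG_SETS,
    *,
    endog: Sequence[str] = ("pending",),
    exog: Sequence[str] = ("additions", "removals"),
    include_intercept: bool = True,
) -> tuple[VARX, pd.DataFrame]:
    """Fit every candidate lag set and return the minimum-AIC model.

    All candidates are estimated on an identical sample (presample = the
    largest max-lag across candidates) so AICs are comparable.  Ties —
    including the degenerate all-exact-fit case — break toward fewer
    parameters, then the smaller maximum lag.  Unfittable candidates are
    excluded with their reason recorded in the comparison table.
    """
    candidates = [tuple(_check_lags(c)) for c in candidates]
    presample = max(max(c) for c in candidates)
    fits: list[tuple[tuple[int, ...], VARX | None, str]] = []
    for cand in candidates:
        try:
            fit = VARX(
                lags=cand,
                endog=endog,
                exog=exog,
                include_intercept=include_intercept,
                n_presample=presample,
            ).fit(frame)
            fits.append((cand, fit, ""))
        except (ValueError, KeyError) as err:
            fits.append((cand, None, str(err)))
    table = pd.DataFrame(
        [
            {
                "lags": c,
                "k": f.k_ if f else np.nan,
                "loglik": f.loglik_ if f else np.nan,
                "aic": f.aic_ if f else np.nan,
                "nobs": f.nobs_ if f else np.nan,
                "exact_fit": f.exact_fit_ if f else pd.NA,
                "error": msg,
            }
            for c, f, msg in fits
        ]
    )
    usable = [(c, f) for c, f, _ in fits if f is not None]
    if not usable:
        raise ValueError("no candidate lag set could be fitted:\n" + table.to_string())
    samples = {f.nobs_ for _, f in usable}
    assert len(samples) == 1, "candidates estimated on different samples"
    best = min(usable, key=lambda cf: (cf[1].aic_, cf[1].k_, max(cf[0])))[1]
    return best, table
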