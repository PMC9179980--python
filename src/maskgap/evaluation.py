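"""Model comparison and diagnostics.

DIC and WAIC compare the four count models; MAPE and MSE measure how close
the posterior-mean relative risks sit to the raw (observed/expected) ones;
VIF screens the covariates for multicollinearity before modeling.

DIC here is the conditional variant: the point deviance is evaluated at
the posterior means of *all* parameters, random effects included, matching
the convention of hierarchical disease-mapping software. MAPE and MSE are
computed on the relative-risk scale; the count-scale versions are also
returned for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bhm import PosteriorFit, log_likelihood


@dataclass
class ModelScore:
    model: str
    dic: float
    waic: float
    mape: float
    mse: float
    p_dic: float
    p_waic: float
    mape_excluded: int  # villages with raw RR = 0 excluded from MAPE
    mape_counts: float  # count-scale MAPE, for transparency
    mse_counts: float


def dic(fit: PosteriorFit, Y=None, E=None) -> tuple[float, float]:
    """Deviance information criterion: DIC = Dbar + p_D.

    Dbar is the posterior mean deviance (-2 log-likelihood); the point
    deviance is taken at the posterior means of all parameters including
    random effects; p_D = Dbar - D(point).
    """
    Y = fit.Y if Y is None else np.asarray(Y)
    E = fit.E if E is None else np.asarray(E, dtype=float)
    ll = fit.loglik_matrix()
    dbar = float(-2.0 * ll.sum(axis=1).mean())
    pt = fit.point_estimates()
    ll_hat = log_likelihood(
        Y,
        E,
        {"X": fit.X, "b": pt["b"], "u": pt["u"], "v": pt["v"], "theta": pt["theta"]},
        fit.spec.family,
    )
    d_hat = float(-2.0 * ll_hat.sum())
    p_d = dbar - d_hat
    return dbar + p_d, p_d


def waic(fit: PosteriorFit, Y=None, E=None) -> tuple[float, float]:
    """Watanabe-Akaike criterion: WAIC = -2(lppd - p_WAIC), with
    p_WAIC the summed posterior variance of the pointwise log-likelihood."""
    ll = fit.loglik_matrix()
    lppd = float(np.sum(_log_mean_exp(ll, axis=0)))
    p_w_i = ll.var(axis=0, ddof=1) if ll.shape[0] > 1 else np.zeros(ll.shape[1])
    if np.any(p_w_i > 0.4):
        warnings.warn(
            f"{int((p_w_i > 0.4).sum())} observations have p_WAIC_i > 0.4; "
            "WAIC may be unreliable for them",
            stacklevel=2,
        )
    p_w = float(p_w_i.sum())
    return -2.0 * (lppd - p_w), p_w


def _log_mean_exp(x: np.ndarray, axis: int) -> np.ndarray:
    m = x.max(axis=axis, keepdims=True)
    return (m + np.log(np.mean(np.exp(x - m), axis=axis, keepdims=True))).squeeze(axis)


def predictive_error(
    fit: PosteriorFit, rho_raw: np.ndarray
) -> tuple[float, float, dict]:
    """MAPE and MSE of posterior-mean RR against raw RR.

    MAPE averages |rho_hat - rho_raw| / rho_raw over villages with positive
    raw RR (zeros are excluded and counted); MSE averages the squared error
    over all modeled villages. Count-scale versions (on lam_hat vs Y) are
    returned in the extras dict.
    """
    rho_raw = np.asarray(rho_raw, dtype=float)
    rho_hat = fit.rho_draws().mean(axis=0)
    if len(rho_raw) != len(rho_hat):
        raise ValueError("rho_raw length does not match modeled villages")
    pos = rho_raw > 0
    if not np.any(pos):
        raise ValueError("all raw RR are zero; MAPE undefined")
    mape = float(np.mean(np.abs(rho_hat[pos] - rho_raw[pos]) / rho_raw[pos]))
    mse = float(np.mean((rho_hat - rho_raw) ** 2))
    lam_hat = fit.E * rho_hat
    ypos = fit.Y > 0
    extras = {
        "excluded": int((~pos).sum()),
        "mape_counts": float(
            np.mean(np.abs(lam_hat[ypos] - fit.Y[ypos]) / fit.Y[ypos])
        ),
        "mse_counts": float(np.mean((lam_hat - fit.Y) ** 2)),
    }
    return mape, mse, extras


def score(fit: PosteriorFit, rho_raw: np.ndarray) -> ModelScore:
    """All four comparison statistics for one fitted model."""
    d, p_d = dic(fit)
    w, p_w = waic(fit)
    mape, mse, extras = predictive_error(fit, rho_raw)
    return ModelScore(
        model=fit.spec.label,
        dic=d,
        waic=w,
        mape=mape,
        mse=mse,
        p_dic=p_d,
        p_waic=p_w,
        mape_excluded=extras["excluded"],
        mape_counts=extras["mape_counts"],
        mse_counts=extras["mse_counts"],
    )


def comparison_table(scores: list[ModelScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": s.model,
                "DIC": s.dic,
                "WAIC": s.waic,
                "MAPE": s.mape,
                "MSE": s.mse,
                "p_DIC": s.p_dic,
                "p_WAIC": s.p_waic,
            }
            for s in scores
        ]
    )


def vif(villages: pd.DataFrame, columns=None) -> pd.Series:
    """Variance inflation factors for the model covariates.

    VIF_j = 1/(1 - R_j^2) from an OLS regression of covariate j on the
    others plus an intercept. Values near 1 mean no collinearity; above 10
    is the usual alarm threshold.
    """
    import statsmodels.api as sm

    from .bhm import DESIGN_NAMES, design_matrix

    if columns is None:
        X = design_matrix(villages)[:, 1:]
        names = list(DESIGN_NAMES[1:])
    else:
        X = villages[list(columns)].to_numpy(dtype=float)
        names = list(columns)
    n, k = X.shape
    if n < k + 2:
        raise ValueError("too few rows to estimate VIF")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
    if rank < k + 1:
        corr = np.corrcoef(X, rowvar=False)
        bad = [
            f"{names[i]}~{names[j]}"
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"design is rank deficient; collinear: {bad or 'unknown'}")
    out = {}
    for j in range(k):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[names[j]] = 1.0 / (1.0 - r2) if r2 < 1 else np.inf
    return pd.Series(out, name="vif")
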