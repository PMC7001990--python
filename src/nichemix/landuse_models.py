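"""Linear models relating diet responses to land-use covariates.

Covers the covariate transforms used to meet homogeneity-of-variance
assumptions, ordinary least squares fits with factors and interactions
(via statsmodels formulas), AIC ranking with Akaike weights, and a Pearson
correlation screen for collinear covariates.

AIC bookkeeping: for a Gaussian OLS fit, AIC = 2k − 2·logLik with k equal
to the number of regression coefficients plus one for the residual
variance. Akaike weights depend only on ΔAIC within the candidate set, so
any consistent k convention yields the same weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .errors import ConfigurationError, DegenerateDataError

TRANSFORM_KINDS = ("sqrt", "square", "log", "arcsine_sqrt")


def _offending(labels: pd.Index, mask: np.ndarray) -> str:
    bad = list(labels[mask])
    return ", ".join(str(b) for b in bad[:5]) + ("..." if len(bad) > 5 else "")


def transform_covariate(
    values: pd.Series | Sequence[float],
    kind: str,
    log_offset: float | None = None,
) -> pd.Series:
    """Elementwise variance-stabilising transform.

    ``sqrt``/``square`` for the scat-level models; ``log``/``arcsine_sqrt``
    for the isotope-level models. log of an exact zero is an error unless a
    positive ``log_offset`` is configured (no silent offsets: real buffer
    tables contain exact zeros, e.g. fully natural buffers).
    """
    s = pd.Series(values, dtype=float)
    x = s.to_numpy()
    if kind == "sqrt":
        if (x < 0).any():
            raise ConfigurationError(
                f"sqrt transform: negative values at {_offending(s.index, x < 0)}"
            )
        return pd.Series(np.sqrt(x), index=s.index)
    if kind == "square":
        return pd.Series(x**2, index=s.index)
    if kind == "log":
        if log_offset is not None:
            if log_offset <= 0:
                raise ConfigurationError("log_offset must be positive")
            x = x + log_offset
        if (x <= 0).any():
            raise ConfigurationError(
                "log transform: non-positive values at "
                f"{_offending(s.index, x <= 0)}; configure a log_offset"
            )
        return pd.Series(np.log(x), index=s.index)
    if kind == "arcsine_sqrt":
        if ((x < 0) | (x > 1)).any():
            raise ConfigurationError(
                "arcsine_sqrt transform: values outside [0, 1] at "
                f"{_offending(s.index, (x < 0) | (x > 1))}"
            )
        return pd.Series(np.arcsin(np.sqrt(x)), index=s.index)
    raise ConfigurationError(f"unknown transform kind {kind!r}; use {TRANSFORM_KINDS}")


@dataclass(frozen=True)
class LinearFit:
    """One OLS fit: coefficients, Gaussian MLE log-likelihood, and AIC."""

    formula: str
    params: pd.Series
    loglik: float
    k: int  # coefficients + 1 (residual variance)
    aic: float
    nobs: int
    resid_var: float  # MLE (1/n) residual variance
    rsquared: float
    response_key: tuple  # identifies the response data for comparability checks


def _response_key(y: np.ndarray, name: str) -> tuple:
    return (name, y.size, round(float(y.sum()), 10), round(float((y**2).sum()), 10))


def fit_linear_model(data: pd.DataFrame, formula: str) -> LinearFit:
    """OLS with treatment-coded factors and formula-defined interactions.

    Factors use treatment contrasts with the alphabetically first level as
    reference (the patsy/statsmodels default). Rank-deficient designs raise
    an error naming the aliased columns.
    """
    model = smf.ols(formula, data=data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # Identify aliased columns with a pivoted QR on the design matrix.
        from scipy.linalg import qr

        _, _, piv = qr(exog, mode="economic", pivoting=True)
        aliased = [model.exog_names[j] for j in sorted(piv[rank:])]
        raise ConfigurationError(
            f"design matrix is rank deficient; aliased terms: {aliased}"
        )
    n = exog.shape[0]
    if n <= exog.shape[1]:
        raise ConfigurationError(
            f"n = {n} observations cannot identify {exog.shape[1]} coefficients"
        )
    res = model.fit()
    k = len(res.params) + 1  # + residual variance
    loglik = float(res.llf)  # Gaussian log-likelihood at the MLE
    return LinearFit(
        formula=formula,
        params=res.params,
        loglik=loglik,
        k=k,
        aic=2.0 * k - 2.0 * loglik,
        nobs=int(n),
        resid_var=float(res.ssr / n),
        rsquared=float(res.rsquared),
        response_key=_response_key(model.endog, model.endog_names),
    )


def aic_rank(fits: Sequence[LinearFit]) -> pd.DataFrame:
    """Rank fitted models by AIC with Akaike weights.

    ΔAIC = AIC − min AIC; relative likelihood = exp(−ΔAIC/2); weight ω =
    relative likelihood normalised over the candidate set. All fits must be
    on the same response data.
    """
    if not fits:
        raise ConfigurationError("need at least one fit")
    keys = {f.response_key for f in fits}
    if len(keys) > 1:
        raise ConfigurationError(
            "fits are not comparable: responses differ across models"
        )
    table = rank_from_aic(
        [f.aic for f in fits],
        names=[f.formula for f in fits],
        k=[f.k for f in fits],
        loglik=[f.loglik for f in fits],
    )
    return table


def rank_from_aic(
    aic: Sequence[float],
    names: Sequence[str] | None = None,
    k: Sequence[int] | None = None,
    loglik: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Model-comparison table from raw AIC values (or any common offset)."""
    aic = np.asarray(aic, dtype=float)
    if aic.size < 1:
        raise ConfigurationError("need at least one AIC value")
    delta = aic - aic.min()
    return rank_from_delta_aic(delta, names=names, k=k, loglik=loglik, _aic=aic)


def rank_from_delta_aic(
    delta_aic: Sequence[float],
    names: Sequence[str] | None = None,
    k: Sequence[int] | None = None,
    loglik: Sequence[float] | None = None,
    _aic: np.ndarray | None = None,
) -> pd.DataFrame:
    """Akaike weights and relative likelihoods from a ΔAIC column alone.

    Weights are a function of ΔAIC only, so a published ΔAIC column fully
    determines the ωAIC and relative-likelihood columns.
    """
    delta = np.asarray(delta_aic, dtype=float)
    if (delta < 0).any():
        raise ConfigurationError("ΔAIC values must be non-negative")
    if delta.min() != 0:
        raise ConfigurationError("the best model must have ΔAIC = 0")
    rel = np.exp(-delta / 2.0)
    weights = rel / rel.sum()
    out = pd.DataFrame(
        {
            "model": list(names) if names is not None else [
                f"model_{i + 1}" for i in range(delta.size)
            ],
            "K": list(k) if k is not None else pd.NA,
            "logLik": list(loglik) if loglik is not None else pd.NA,
            "AIC": _aic if _aic is not None else pd.NA,
            "dAIC": delta,
            "rel_likelihood": rel,
            "weight": weights,
        }
    )
    return out.sort_values("dAIC", kind="stable").reset_index(drop=True)


def correlation_screen(
    table: pd.DataFrame, pairs: Iterable[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson r with two-sided t-based p per covariate pair."""
    rows = []
    for a, b in pairs:
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            raise DegenerateDataError(f"pair ({a}, {b}): need >= 3 complete rows")
        if sub[a].nunique() == 1 or sub[b].nunique() == 1:
            raise DegenerateDataError(
                f"pair ({a}, {b}): constant column, correlation undefined"
            )
        r, p = stats.pearsonr(sub[a], sub[b])
        rows.append({"x": a, "y": b, "n": len(sub), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
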