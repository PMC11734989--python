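"""Binomial-logit modelling of observer agreement against image attributes.

Each aggregate annotation contributes a binomial response: the number of
member votes matching the consensus class out of the total votes in its
cluster.  Covariates are first screened for multicollinearity by iterative
variance-inflation-factor (VIF) removal (drop the worst column while any
VIF exceeds the threshold, default 5), then the model

    logit(pi) = X beta

is fit by maximum likelihood.  Coefficients are reported with Wald standard
errors and p-values, and converted to interpretable odds changes via
exp(beta * delta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .aggregation import AggregationResult

DEFAULT_VIF_THRESHOLD = 5.0


@dataclass
class ModelResult:
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    included: list[str]
    excluded: list[tuple[str, float]]
    converged: bool
    n_obs: int
    llf: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.params, "se": self.bse, "z": self.zvalues, "p": self.pvalues}
        )


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1 / (1 - R^2) of column j regressed on the others."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        return float("inf")  # constant column: perfectly explained by the intercept
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def vif_filter(
    design: pd.DataFrame, threshold: float = DEFAULT_VIF_THRESHOLD
) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Iteratively drop the worst-VIF column until all VIFs <= threshold.

    Ties on the maximum VIF are resolved by column order.  Perfectly
    collinear (or constant) columns get infinite VIF and are removed first.
    Returns the retained design and a removal log of (column, VIF at
    removal).  Idempotent: filtering a filtered design is a no-op.
    """
    if threshold <= 1:
        raise ValueError("vif threshold must exceed 1")
    kept = list(design.columns)
    removed: list[tuple[str, float]] = []
    while len(kept) >= 2:
        X = design[kept].to_numpy(dtype=float)
        vifs = np.array([_vif_one(X, j) for j in range(len(kept))])
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        removed.append((kept[worst], float(vifs[worst])))
        kept.pop(worst)
    return design[kept], removed


def response_from_aggregation(
    aggregation: AggregationResult,
) -> pd.DataFrame:
    """Per-aggregate binomial response (successes, trials) for decided clusters.

    Successes are the votes for the consensus class; trials the cluster's
    total votes.  No-consensus aggregates are excluded (there is no defined
    agreeing class).  Row order follows ``aggregation.aggregates``.
    """
    rows = []
    for idx, agg in enumerate(aggregation.aggregates):
        if not agg.has_consensus:
            continue
        trials = sum(agg.vote_tally.values())
        rows.append(
            {
                "aggregate_index": idx,
                "successes": agg.vote_tally[agg.consensus_class],
                "trials": trials,
            }
        )
    return pd.DataFrame(rows)


def fit_binomial_logit(
    design: pd.DataFrame,
    successes: Sequence[int],
    trials: Sequence[int],
    add_intercept: bool = True,
) -> ModelResult:
    """Maximum-likelihood binomial logit fit via IRLS.

    ``design`` holds the covariate columns (already VIF-screened); the
    response is (successes, trials) per row.  Zero-variance covariates are
    rejected before fitting.  Non-convergence (e.g. separation) is surfaced
    through the ``converged`` flag rather than an exception.
    """
    successes = np.asarray(successes, dtype=float)
    trials = np.asarray(trials, dtype=float)
    if successes.shape != trials.shape or len(successes) != len(design):
        raise ValueError("response length must match the design")
    if np.any(successes > trials) or np.any(trials < 1):
        raise ValueError("need 0 <= successes <= trials and trials >= 1")
    if design.isna().any().any():
        raise ValueError("design contains missing values")
    degenerate = [c for c in design.columns if design[c].nunique() <= 1]
    if degenerate:
        raise ValueError(f"zero-variance covariates: {degenerate}")
    X = design.astype(float)
    if add_intercept:
        X = sm.add_constant(X, prepend=True, has_constant="add")
    endog = np.column_stack([successes, trials - successes])
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    try:
        fit = model.fit(maxiter=100, tol=1e-10)
        converged = bool(fit.converged)
    except Exception:
        # refit with heavy regularization off the table: flag and return NaNs
        idx = list(X.columns)
        nan = pd.Series(np.nan, index=idx)
        return ModelResult(nan, nan, nan, nan, list(design.columns), [], False,
                           len(design), float("nan"))
    return ModelResult(
        params=fit.params,
        bse=fit.bse,
        zvalues=fit.tvalues,
        pvalues=fit.pvalues,
        included=list(design.columns),
        excluded=[],
        converged=converged,
        n_obs=len(design),
        llf=float(fit.llf),
    )


def fit_agreement_model(
    aggregation: AggregationResult,
    covariates: pd.DataFrame,
    vif_threshold: float = DEFAULT_VIF_THRESHOLD,
) -> ModelResult:
    """VIF-screen covariates then fit the agreement logit model.

    ``covariates`` must have one row per aggregate (same order as
    ``aggregation.aggregates``); rows for no-consensus aggregates are
    dropped along with their responses.
    """
    if len(covariates) != len(aggregation.aggregates):
        raise ValueError("covariates must have one row per aggregate")
    resp = response_from_aggregation(aggregation)
    if resp.empty:
        raise ValueError("no decided aggregates to model")
    design = covariates.iloc[resp["aggregate_index"].to_numpy()].reset_index(drop=True)
    design = design.loc[:, design.nunique() > 1]
    kept, removed = vif_filter(design, vif_threshold)
    result = fit_binomial_logit(kept, resp["successes"], resp["trials"])
    result.excluded = removed
    return result


def odds_change(beta: float, delta: float = 1.0) -> float:
    """Multiplicative change in odds for a ``delta`` increase in a covariate.

    exp(beta * delta); e.g. beta = 0.144 per neighbor gives a factor of
    1.155 per additional neighbor (+15.5%).
    """
    if not (math.isfinite(beta) and math.isfinite(delta)):
        raise ValueError("beta and delta must be finite")
    return math.exp(beta * delta)


def percent_odds_change(beta: float, delta: float = 1.0) -> float:
    """Percent change in odds: 100 * (exp(beta * delta) - 1)."""
    return 100.0 * (odds_change(beta, delta) - 1.0)
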