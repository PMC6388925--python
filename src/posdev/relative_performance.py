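"""Relative household performance via median-regression residuals.

Absolute indicator scores confound household behaviour with endowments: a
large farm near a market earns more cash regardless of management quality.
Deviance is therefore defined on *relative* performance — the residual of
each indicator over a median (tau = 0.5 quantile) regression on external
determinants: land endowment, livestock endowment, household size, region,
and market access (proxied by mean village market orientation).

Per indicator, all subsets of the five candidate covariate groups are fit
and the model minimising an AIC for quantile regression is selected. The
AIC follows the asymmetric-Laplace profile likelihood,

    AIC = 2k + 2n ln( (1/n) sum_i rho_0.5(e_i) ),    rho_0.5(e) = |e| / 2,

with k the number of estimated coefficients including the intercept;
additive constants are dropped. Region dummies enter and leave the model as
one group, counted as (levels - 1) parameters.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_config import PipelineConfig

__all__ = [
    "CANDIDATE_COVARIATES",
    "MedianFit",
    "market_access_proxy",
    "check_loss",
    "fit_median_regression",
    "quantreg_aic",
    "select_model",
    "relative_performance",
]

CANDIDATE_COVARIATES = ["land_ha", "livestock_tlu", "mae", "region", "market_access"]

NEG_INF_AIC = float("-inf")


@dataclasses.dataclass
class MedianFit:
    """A fitted median regression of one performance dimension."""

    covariates: tuple[str, ...]  # selected covariate groups
    columns: tuple[str, ...]  # design columns incl. dummies, excl. intercept
    intercept: float
    coefficients: np.ndarray  # aligned with `columns`
    tau: float
    n: int
    k: int  # estimated parameters incl. intercept
    check_loss_sum: float
    aic: float
    fitted: np.ndarray
    residuals: np.ndarray

    def describe(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "columns": list(self.columns),
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "n": self.n,
            "k": self.k,
            "check_loss_sum": self.check_loss_sum,
            "aic": self.aic,
        }


def market_access_proxy(records: pd.DataFrame) -> pd.Series:
    """Mean market orientation of each household's village (self included).

    Intra-village differences in observed market utilisation are evened out,
    leaving a village-level proxy for potential market access.
    """
    mo = records["market_orientation"]
    if mo.isna().all() or records.groupby("village_id")["market_orientation"].count().eq(0).any():
        bad = records.groupby("village_id")["market_orientation"].count()
        raise ValueError(
            f"village(s) without any valid market_orientation value: "
            f"{sorted(bad[bad == 0].index.tolist())}"
        )
    out = records.groupby("village_id")["market_orientation"].transform("mean")
    out.name = "market_access"
    return out


def check_loss(residuals, tau: float = 0.5) -> float:
    """Sum of the quantile check loss rho_tau over residuals (0.5|e| at the median)."""
    e = np.asarray(residuals, dtype=float)
    return float(np.sum(e * (tau - (e < 0))))


def _design_matrix(
    records: pd.DataFrame, covariates: Sequence[str], market_access: pd.Series | None
) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov == "region":
            dummies = pd.get_dummies(records["region"], prefix="region", drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float).to_numpy()
        elif cov == "market_access":
            ma = market_access if market_access is not None else market_access_proxy(records)
            cols["market_access"] = np.asarray(ma, dtype=float)
        else:
            cols[cov] = records[cov].astype(float).to_numpy()
    return pd.DataFrame(cols, index=records.index)


def fit_median_regression(y, X: pd.DataFrame, covariates: Sequence[str] = ()) -> MedianFit:
    """Fit a tau = 0.5 quantile regression of y on X (intercept added).

    Coefficients minimise the summed check loss; a rank-deficient design
    raises with the offending columns named.
    """
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    design = sm.add_constant(X.astype(float), has_constant="add")
    k = design.shape[1]
    if n <= k:
        raise ValueError(f"need n > p + 1 (n={n}, parameters={k})")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < k:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {k}); "
            f"collinear among columns {list(design.columns)}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.QuantReg(yv, design).fit(q=0.5, p_tol=1e-9, max_iter=5000)
    params = pd.Series(res.params, index=design.columns)
    fitted = design.to_numpy() @ params.to_numpy()
    residuals = yv - fitted
    loss = check_loss(residuals)
    fit = MedianFit(
        covariates=tuple(covariates),
        columns=tuple(c for c in design.columns if c != "const"),
        intercept=float(params["const"]),
        coefficients=params.drop("const").to_numpy(),
        tau=0.5,
        n=n,
        k=k,
        check_loss_sum=loss,
        aic=np.nan,
        fitted=fitted,
        residuals=residuals,
    )
    fit.aic = quantreg_aic(fit)
    return fit


def quantreg_aic(fit: MedianFit) -> float:
    """AIC of a median fit under the asymmetric-Laplace profile likelihood."""
    if fit.check_loss_sum <= 1e-9 * max(1, fit.n):
        warnings.warn("perfect median fit (zero check loss); AIC set to -inf", stacklevel=2)
        return NEG_INF_AIC
    return 2.0 * fit.k + 2.0 * fit.n * float(np.log(fit.check_loss_sum / fit.n))


def select_model(
    y,
    records: pd.DataFrame,
    candidates: Sequence[str] | None = None,
    market_access: pd.Series | None = None,
    return_table: bool = False,
):
    """Exhaustive best-subset search over candidate covariate groups by AIC.

    All 2^g subsets (region as one dummy group) are fit; the minimum-AIC fit
    is returned. Ties break toward fewer parameters, then toward the earlier
    subset in lexicographic enumeration order. An empty candidate list gives
    the intercept-only fit.
    """
    cands = list(candidates) if candidates is not None else list(CANDIDATE_COVARIATES)
    if len(cands) > 5:
        raise ValueError("at most 5 candidate covariate groups supported")
    if market_access is None and "market_access" in cands:
        market_access = market_access_proxy(records)

    best: MedianFit | None = None
    best_key: tuple | None = None
    table = []
    errors = []
    for idx, subset in enumerate(
        itertools.chain.from_iterable(
            itertools.combinations(range(len(cands)), r) for r in range(len(cands) + 1)
        )
    ):
        names = tuple(cands[i] for i in subset)
        X = _design_matrix(records, names, market_access)
        try:
            fit = fit_median_regression(y, X, covariates=names)
        except Exception as exc:
            errors.append((names, str(exc)))
            continue
        table.append({"covariates": list(names), "k": fit.k, "aic": fit.aic})
        key = (fit.aic, fit.k, idx)
        if best_key is None or key < best_key:
            best, best_key = fit, key
    if best is None:
        raise RuntimeError(f"all candidate model fits failed: {errors}")
    if return_table:
        return best, table
    return best


def relative_performance(
    perf: pd.DataFrame, records: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, dict]:
    """Residual matrix of the five indicators over selected median-regression models.

    For each performance column independently, the best covariate subset is
    selected by AIC and the household's residual (observed minus fitted)
    retained as its relative performance in that dimension.
    """
    if len(perf) != len(records):
        raise ValueError("performance matrix and records are misaligned")
    ma = (
        market_access_proxy(records)
        if "market_access" in config.candidate_covariates
        else None
    )
    residuals = {}
    models = {}
    for col in perf.columns:
        fit, table = select_model(
            perf[col].to_numpy(),
            records,
            candidates=config.candidate_covariates,
            market_access=ma,
            return_table=True,
        )
        residuals[col] = fit.residuals
        models[col] = {"selected": fit.describe(), "aic_table": table}
    out = pd.DataFrame(residuals, index=perf.index)[list(perf.columns)]
    return out, models
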