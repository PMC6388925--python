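"""The five household performance indicators.

Each household is scored on five development dimensions:

* **caloric food security** — first principal component of (i) the caloric
  sufficiency ratio, food availability over the household requirement
  (MAE x 2,550 kcal/day), capped at 100%, and (ii) the number of food-secure
  months in the year;
* **dietary diversity** — harmonic mean of the good-season and lean-season
  Household Dietary Diversity Scores, which penalises a weak season more
  than the arithmetic mean would;
* **cash income** — farm-gate sales plus off-farm income, US$/yr;
* **GHG score** — total on-farm greenhouse-gas emissions multiplied by -1,
  so that lower emissions score higher;
* **gender equity** — 1 at an equal decision-making split (women's share
  0.5), discounted linearly for deviations with a household-type-specific
  weight.

After computation, each indicator column is winsorised against implausible
outliers: values beyond a validity bound are replaced by the maximum
observed in-range value.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io_config import PipelineConfig

__all__ = [
    "INDICATOR_ORDER",
    "PcaFit",
    "caloric_sufficiency",
    "food_secure_months",
    "caloric_food_security",
    "dietary_diversity",
    "cash_income",
    "ghg_score",
    "gender_equity",
    "cap_outliers",
    "performance_matrix",
]

#: Fixed column order of the performance matrix.
INDICATOR_ORDER = [
    "food_security",
    "dietary_diversity",
    "cash_income",
    "ghg_score",
    "gender_equity",
]


@dataclasses.dataclass(frozen=True)
class PcaFit:
    """Fitted two-variable PCA behind the food-security composite."""

    loadings: np.ndarray  # (2,) weights on (sufficiency, secure months), PC-1
    variance_fractions: np.ndarray  # (2,) explained-variance ratio of both PCs
    means: np.ndarray  # standardization means of the two inputs
    scales: np.ndarray  # standardization sds of the two inputs
    sign: float  # orientation applied to the raw component (+1/-1)

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "sign": self.sign,
        }


def caloric_sufficiency(food_availability, kcal_requirement: float = 2550.0):
    """Ratio of per-MAE daily food availability to the requirement, capped at 1.

    ``food_availability`` is already per MAE per day, so it is divided by the
    per-MAE requirement directly.
    """
    avail = np.asarray(food_availability, dtype=float)
    if kcal_requirement <= 0:
        raise ValueError("kcal_requirement must be positive")
    if np.any(avail < 0):
        raise ValueError("food availability must be non-negative")
    out = np.minimum(avail / kcal_requirement, 1.0)
    return out if out.ndim else float(out)


def food_secure_months(food_insecure_months):
    """Months of the year with secure food access: 12 minus insecure months."""
    m = np.asarray(food_insecure_months, dtype=float)
    if np.any((m < 0) | (m > 12)):
        raise ValueError("food_insecure_months must lie in [0, 12]")
    out = 12.0 - m
    return out if out.ndim else float(out)


def caloric_food_security(sufficiency, secure_months) -> tuple[np.ndarray, PcaFit]:
    """Composite food-security score: PC-1 of the two standardized measures.

    Both measures are standardized to mean 0 / sd 1 (they have
    incommensurable units), then the first principal component score is
    taken per household, sign-oriented so that higher means more food
    secure.
    """
    x = np.column_stack([np.asarray(sufficiency, float), np.asarray(secure_months, float)])
    if len(x) < 3:
        raise ValueError("need at least 3 households for the PCA composite")
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=1)
    if np.any(scales == 0):
        which = ["sufficiency", "secure months"][int(np.argmax(scales == 0))]
        raise ValueError(f"constant input measure ({which}): PCA direction undefined")
    z = (x - means) / scales

    pca = PCA(n_components=2)
    scores = pca.fit_transform(z)
    loadings = pca.components_[0]
    pc1 = scores[:, 0]

    # orient so the composite increases with both inputs (for positively
    # correlated measures both loadings then share a sign)
    sign = 1.0 if loadings.sum() >= 0 else -1.0
    pc1 = sign * pc1
    loadings = sign * loadings
    if np.any(loadings < 0):
        warnings.warn(
            "food-security measures are negatively correlated; PC-1 cannot "
            "increase with both inputs",
            stacklevel=2,
        )
    fit = PcaFit(
        loadings=loadings,
        variance_fractions=pca.explained_variance_ratio_.copy(),
        means=means,
        scales=scales,
        sign=sign,
    )
    return pc1, fit


def dietary_diversity(hdds_good, hdds_lean):
    """Harmonic mean of good- and lean-season dietary diversity scores.

    Defined as 0 when either season is 0 (the harmonic mean's limiting
    infimum); always at most the arithmetic mean.
    """
    g = np.asarray(hdds_good, dtype=float)
    l = np.asarray(hdds_lean, dtype=float)
    if np.any((g < 0) | (g > 12)) or np.any((l < 0) | (l > 12)):
        raise ValueError("HDDS values must lie in [0, 12]")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((g > 0) & (l > 0), 2.0 * g * l / (g + l), 0.0)
    return out if out.ndim else float(out)


def cash_income(farm_income, offfarm_income):
    """Disposable cash: farm-gate sales plus off-farm income (US$/yr)."""
    f = np.asarray(farm_income, dtype=float)
    o = np.asarray(offfarm_income, dtype=float)
    if np.any(f < 0) or np.any(o < 0):
        raise ValueError("incomes must be non-negative")
    out = f + o
    return out if out.ndim else float(out)


def ghg_score(ghg_emissions):
    """Sign-flipped emissions so that lower emissions score higher."""
    e = np.asarray(ghg_emissions, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("ghg_emissions must be finite")
    if np.any(e < 0):
        warnings.warn("negative GHG emissions encountered (unusual)", stacklevel=2)
    out = -e
    return out if out.ndim else float(out)


def gender_equity(
    female_share,
    household_type,
    weight_table: Mapping[str, float],
):
    """Gender-equity score in [0, 1], maximal at an equal split.

    score = 1 - w(type) * 2 * |female_share - 0.5|, clipped to [0, 1].
    The weight discounts deviations differently by household type (single
    heads cannot fully share decisions with an absent partner, so their
    deviation is discounted at half weight by default).
    """
    share = np.asarray(female_share, dtype=float)
    if np.any((share < 0) | (share > 1)):
        raise ValueError("female_share must lie in [0, 1]")
    types = np.atleast_1d(np.asarray(household_type, dtype=object))
    unknown = sorted({t for t in types if t not in weight_table})
    if unknown:
        raise ValueError(f"household type(s) not in weight table: {unknown}")
    w = np.array([weight_table[t] for t in types], dtype=float)
    out = np.clip(1.0 - w * 2.0 * np.abs(np.atleast_1d(share) - 0.5), 0.0, 1.0)
    return out if np.asarray(female_share).ndim else float(out[0])


def cap_outliers(
    values,
    percentile: float = 99.0,
    bounds: tuple[float | None, float | None] | None = None,
    cap_low: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace out-of-range values by the extreme observed in-range value.

    The validity bound is either absolute (``bounds=(low, high)``) or the
    observed value at the given percentile (and its mirror when ``cap_low``).
    Percentile bounds use the lower observed order statistic, so re-applying
    the rule is a no-op (idempotence).

    Returns the capped vector and a boolean mask of capped positions.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("cap_outliers expects a 1-D vector")

    if bounds is not None:
        low, high = bounds
    else:
        high = float(np.percentile(v, percentile, method="lower"))
        low = float(np.percentile(v, 100 - percentile, method="higher")) if cap_low else None

    in_range = np.ones(len(v), dtype=bool)
    if high is not None:
        in_range &= v <= high
    if low is not None:
        in_range &= v >= low
    if not in_range.any():
        raise ValueError("no value inside the validity range; cannot cap")

    out = v.copy()
    capped = ~in_range
    if high is not None:
        over = v > high
        out[over] = v[in_range].max()
    if low is not None:
        under = v < low
        out[under] = v[in_range].min()
    return out, capped


def performance_matrix(
    records: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, PcaFit, pd.DataFrame]:
    """Assemble the n x 5 performance matrix from a clean household table.

    Applies the five indicator computations, then outlier capping per column.
    Returns (matrix indexed by household_id, PCA fit, capping-flag frame).
    """
    suff = caloric_sufficiency(records["food_availability"], config.kcal_requirement)
    months = food_secure_months(records["food_insecure_months"])
    fs, pca_fit = caloric_food_security(suff, months)

    raw = pd.DataFrame(
        {
            "food_security": fs,
            "dietary_diversity": dietary_diversity(records["hdds_good"], records["hdds_lean"]),
            "cash_income": cash_income(records["farm_income"], records["offfarm_income"]),
            "ghg_score": ghg_score(records["ghg_emissions"]),
            "gender_equity": gender_equity(
                records["female_share"].to_numpy(),
                records["household_type"].to_numpy(),
                config.gender_weights,
            ),
        },
        index=records["household_id"].to_numpy(),
    )
    raw.index.name = "household_id"

    flags = pd.DataFrame(False, index=raw.index, columns=raw.columns)
    for col in INDICATOR_ORDER:
        capped, mask = cap_outliers(
            raw[col].to_numpy(),
            percentile=config.cap_percentile,
            bounds=config.cap_bounds.get(col),
            cap_low=config.cap_low,
        )
        raw[col] = capped
        flags[col] = mask
    return raw[INDICATOR_ORDER], pca_fit, flags
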