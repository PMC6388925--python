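"""Where positive deviance concentrates: strata, profiles, correlations.

Households are stratified into 20 resource strata — deciles of land
holdings crossed with a median split of livestock holdings (with a median
of 0 TLU the split reads as presence/absence of livestock). Residuals are
z-standardized over the full sample so that mean deviance is comparable
across the five dimensions, and the deviant group is profiled per stratum,
per aggregated stratum, and overall. Pearson correlations between the
deviance magnitudes of positive deviants expose trade-offs between
dimensions, and a group-comparison table contrasts deviants with all other
households on socio-economic characteristics and median performance.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratumAssignment",
    "z_transform",
    "assign_strata",
    "stratum_mean_deviance",
    "deviance_correlations",
    "compare_groups",
]


@dataclasses.dataclass
class StratumAssignment:
    """Per-household land decile (1..10) and livestock class (low/high)."""

    land_decile: np.ndarray
    livestock_class: np.ndarray  # "low" / "high"
    livestock_median: float
    n_deciles: int = 10

    @property
    def stratum_id(self) -> np.ndarray:
        return np.array(
            [f"D{d}-{c}" for d, c in zip(self.land_decile, self.livestock_class)],
            dtype=object,
        )

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "land_decile": self.land_decile,
                "livestock_class": self.livestock_class,
                "stratum_id": self.stratum_id,
            },
            index=index,
        )


def z_transform(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize each column to mean 0 / sd 1 over all households.

    Uses the sample standard deviation (ddof = 1), consistent with the
    correlation conventions used downstream. Returns the scaled matrix and a
    (mean, sd) constants frame.
    """
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    constant = sds[sds == 0]
    if len(constant):
        raise ValueError(f"constant column(s), z-transform undefined: {list(constant.index)}")
    scaled = (matrix - means) / sds
    constants = pd.DataFrame({"mean": means, "sd": sds})
    return scaled, constants


def assign_strata(land, livestock, n_deciles: int = 10) -> StratumAssignment:
    """Assign land deciles (rank-based, ties share the lower decile) and a
    livestock median split (low iff TLU <= median)."""
    land_v = np.asarray(land, dtype=float)
    lv = np.asarray(livestock, dtype=float)
    n = len(land_v)
    if n < n_deciles:
        raise ValueError(f"need at least {n_deciles} households for {n_deciles} deciles")
    ranks = stats.rankdata(land_v, method="min")  # ties get the lowest rank
    deciles = ((ranks - 1) * n_deciles // n + 1).astype(int)
    if np.all(deciles == 1) and n > 1:
        warnings.warn("all land values tied: every household in decile 1", stacklevel=2)
    med = float(np.median(lv))
    classes = np.where(lv <= med, "low", "high").astype(object)
    return StratumAssignment(
        land_decile=deciles, livestock_class=classes, livestock_median=med, n_deciles=n_deciles
    )


def _mean_rows(
    residuals: pd.DataFrame,
    scaled: pd.DataFrame,
    mask: np.ndarray,
    label: str,
    group: str,
) -> list[dict]:
    count = int(mask.sum())
    row = {"group": group, "stratum": label, "n": count}
    if count == 0:
        for col in residuals.columns:
            row[col] = np.nan
            row[f"{col}_z"] = np.nan
    else:
        for col in residuals.columns:
            row[col] = float(residuals.loc[mask, col].mean())
            row[f"{col}_z"] = float(scaled.loc[mask, col].mean())
    return [row]


def stratum_mean_deviance(
    residuals: pd.DataFrame,
    assignment: StratumAssignment,
    deviant_mask,
    decile_pairs: bool = True,
) -> pd.DataFrame:
    """Mean deviance of positive deviants per resource stratum.

    Emits rows for aggregated land-size strata (deciles paired 1+2, 3+4, ...
    when ``decile_pairs``), the livestock classes, the overall deviant mean,
    and every individual (decile, class) stratum — each in raw units and
    z-scaled (full-sample standardization). Empty strata yield NaN rows with
    count 0.
    """
    deviant_mask = np.asarray(deviant_mask, dtype=bool)
    if not deviant_mask.any():
        raise ValueError("deviant set is empty")
    scaled, _ = z_transform(residuals)
    deciles = assignment.land_decile
    classes = assignment.livestock_class

    rows: list[dict] = []
    if decile_pairs:
        for lo in range(1, assignment.n_deciles + 1, 2):
            pair = deviant_mask & ((deciles == lo) | (deciles == lo + 1))
            rows += _mean_rows(residuals, scaled, pair, f"{lo}+{lo + 1}", "land_pair")
    for cls in ("low", "high"):
        m = deviant_mask & (classes == cls)
        rows += _mean_rows(residuals, scaled, m, cls, "livestock")
    rows += _mean_rows(residuals, scaled, deviant_mask, "overall", "overall")
    for d in range(1, assignment.n_deciles + 1):
        for cls in ("low", "high"):
            m = deviant_mask & (deciles == d) & (classes == cls)
            rows += _mean_rows(residuals, scaled, m, f"D{d}-{cls}", "stratum")
    return pd.DataFrame(rows)


def deviance_correlations(
    residuals: pd.DataFrame, deviant_mask
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between deviance magnitudes among positive deviants.

    Returns the 5 x 5 correlation matrix and two-sided p-values. Dimensions
    that are constant within the deviant group get NaN entries with a
    warning.
    """
    deviant_mask = np.asarray(deviant_mask, dtype=bool)
    if deviant_mask.sum() < 3:
        raise ValueError("need at least 3 positive deviants for correlations")
    sub = residuals.loc[deviant_mask]
    cols = list(residuals.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            x, y = sub[a].to_numpy(), sub[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"constant column among deviants: {a if np.std(x) == 0 else b}")
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p


_NUMERIC_CHARACTERISTICS = [
    "mae",
    "land_ha",
    "livestock_tlu",
    "crop_diversity",
    "livestock_diversity",
]
_CATEGORICAL_CHARACTERISTICS = ["region", "household_type"]


def compare_groups(
    records: pd.DataFrame,
    performance: pd.DataFrame,
    deviant_mask,
    numeric: Sequence[str] | None = None,
    categorical: Sequence[str] | None = None,
    test: str = "welch",
) -> pd.DataFrame:
    """Contrast positive deviants against all other households.

    Numeric characteristics: group means with a two-sample t-test (Welch by
    default, classical Student optional). Categorical characteristics:
    per-level proportions with a chi-square test of independence. The five
    performance indicators are summarised by group medians (no test, the
    deviant set is defined on them). Significance flag at p < .05.
    """
    deviant_mask = np.asarray(deviant_mask, dtype=bool)
    other = ~deviant_mask
    if not deviant_mask.any() or not other.any():
        raise ValueError("both groups must be non-empty")
    equal_var = test == "student"

    rows = []
    for col in numeric if numeric is not None else _NUMERIC_CHARACTERISTICS:
        a = records.loc[deviant_mask, col].astype(float)
        b = records.loc[other, col].astype(float)
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            pval = 1.0
        elif len(a) < 2 or len(b) < 2:
            warnings.warn(f"degenerate group for t-test on {col}")
            pval = np.nan
        else:
            pval = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        rows.append(
            {
                "characteristic": col,
                "kind": "numeric_mean",
                "deviants": float(a.mean()),
                "others": float(b.mean()),
                "p_value": pval,
                "significant": bool(pval < 0.05) if np.isfinite(pval) else False,
            }
        )
    for col in categorical if categorical is not None else _CATEGORICAL_CHARACTERISTICS:
        ct = pd.crosstab(records[col], deviant_mask)
        if ct.shape[0] < 2 or ct.shape[1] < 2:
            warnings.warn(f"degenerate contingency table for {col}")
            pval = np.nan
        else:
            pval = float(stats.chi2_contingency(ct.to_numpy()).pvalue)
        dev_prop = records.loc[deviant_mask, col].value_counts(normalize=True)
        oth_prop = records.loc[other, col].value_counts(normalize=True)
        for level in sorted(set(dev_prop.index) | set(oth_prop.index)):
            rows.append(
                {
                    "characteristic": f"{col}={level}",
                    "kind": "categorical_share",
                    "deviants": float(dev_prop.get(level, 0.0)),
                    "others": float(oth_prop.get(level, 0.0)),
                    "p_value": pval,
                    "significant": bool(pval < 0.05) if np.isfinite(pval) else False,
                }
            )
    for col in performance.columns:
        rows.append(
            {
                "characteristic": col,
                "kind": "performance_median",
                "deviants": float(performance.loc[deviant_mask, col].median()),
                "others": float(performance.loc[other, col].median()),
                "p_value": np.nan,
                "significant": False,
            }
        )
    return pd.DataFrame(rows)
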