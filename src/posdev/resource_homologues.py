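"""Resource homologues: nearest visited positive deviants per household.

Every surveyed household is matched to its k most similar visited positive
deviants — its "resource homologues" — by Euclidean distance on six
standardized resource endowments: agro-ecological ability, labor,
financial capital, land holdings, livestock holdings, and social capital.
Each resource is a configurable proxy expression over survey fields (the
defaults use crop diversity, MAE, total income, land, TLU, and the village
market-access proxy respectively). The practices observed with a
household's homologues form its household-specific practice menu, and
counting menus across the sample gives per-practice target-household
numbers.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .relative_performance import market_access_proxy

__all__ = [
    "RESOURCES",
    "resource_profile",
    "nearest_homologues",
    "practice_menu",
]

RESOURCES = [
    "agro_ecological_ability",
    "labor",
    "financial_capital",
    "land_holdings",
    "livestock_holdings",
    "social_capital",
]


def resource_profile(
    records: pd.DataFrame, proxy_config: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate the six resource proxies and standardize them.

    ``proxy_config`` maps each resource to an expression over the survey
    columns (pandas ``eval`` syntax); ``market_access`` is available as a
    derived column. Returns (raw, standardized) frames indexed by
    household_id, the standardized copy having mean 0 / sd 1 per column
    across the full household set.
    """
    missing = [r for r in RESOURCES if r not in proxy_config]
    if missing:
        raise ValueError(f"proxy_config missing resources: {missing}")
    env = records.copy()
    env["market_access"] = market_access_proxy(records).to_numpy()
    raw = {}
    for resource in RESOURCES:
        expr = proxy_config[resource]
        try:
            raw[resource] = np.asarray(
                pd.to_numeric(env.eval(expr), errors="raise"), dtype=float
            )
        except Exception as exc:
            raise ValueError(f"invalid proxy expression for {resource!r}: {expr!r} ({exc})") from exc
    profile = pd.DataFrame(raw, index=records["household_id"].to_numpy())
    profile.index.name = "household_id"
    if not np.all(np.isfinite(profile.to_numpy())):
        raise ValueError("resource profiles contain non-finite values")
    sds = profile.std(axis=0, ddof=1)
    if (sds == 0).any():
        raise ValueError(f"constant resource column(s): {list(sds[sds == 0].index)}")
    standardized = (profile - profile.mean(axis=0)) / sds
    return profile, standardized


def nearest_homologues(
    profiles: pd.DataFrame,
    visited_deviants,
    k: int = 3,
    include_self: bool = True,
    targets=None,
) -> pd.DataFrame:
    """Per target household, the k nearest visited deviants in resource space.

    Distances are Euclidean on (standardized) profiles; ties break by
    ascending household id. A target that is itself a visited deviant
    matches itself at distance 0 unless ``include_self`` is False.
    """
    visited = sorted(visited_deviants)
    if targets is None:
        targets = list(profiles.index)
    n_pool = len(visited) - (0 if include_self else 1)
    if len(visited) < k or (not include_self and any(t in set(visited) for t in targets) and n_pool < k):
        raise ValueError(f"need at least {k} available visited deviants (have {len(visited)})")

    dev_matrix = profiles.loc[visited].to_numpy(dtype=float)
    tgt_matrix = profiles.loc[targets].to_numpy(dtype=float)
    dmat = cdist(tgt_matrix, dev_matrix)

    rows = []
    for i, t in enumerate(targets):
        pairs = [
            (dmat[i, j], visited[j])
            for j in range(len(visited))
            if include_self or visited[j] != t
        ]
        pairs.sort(key=lambda p: (p[0], p[1]))
        row: dict = {"household_id": t}
        for rank_, (dist, dev) in enumerate(pairs[:k], start=1):
            row[f"homologue_{rank_}"] = dev
            row[f"distance_{rank_}"] = dist
        rows.append(row)
    return pd.DataFrame(rows).set_index("household_id")


def practice_menu(
    homologues: pd.DataFrame, catalog: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Household practice menus and per-practice target counts.

    The menu of a household is the union of practices held by its
    homologues (a deviant with no recorded practice contributes nothing).
    The targeting table counts, for every catalog practice, the households
    whose menu contains it, with the share of all target households.
    """
    holder_practices: dict[str, set] = {}
    for _, row in catalog.iterrows():
        holder_practices.setdefault(row["positive_deviant_id"], set()).add(row["practice_code"])

    hom_cols = [c for c in homologues.columns if c.startswith("homologue_")]
    menus = {}
    for hid, row in homologues.iterrows():
        menu: set = set()
        for c in hom_cols:
            menu |= holder_practices.get(row[c], set())
        menus[hid] = frozenset(menu)
    menus = pd.Series(menus, name="practice_menu")

    n_targets = len(menus)
    codes = sorted(catalog["practice_code"].unique())
    counts = pd.DataFrame(
        {
            "practice_code": codes,
            "n_target_households": [
                sum(1 for m in menus if code in m) for code in codes
            ],
        }
    )
    counts["share"] = counts["n_target_households"] / n_targets if n_targets else np.nan
    return menus, counts
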