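"""Diverse case selection: one positive deviant per resource stratum.

For qualitative follow-up, one positive deviant is chosen from every
stratum that contains any, preferring rank-1 over rank-2 deviants, so that
the chosen subset is maximally diverse in four household characteristics:
household size (MAE), land holdings, livestock holdings, and market access
(region, categorical, is excluded). Diversity is the mean crowding distance
of the selection — the NSGA-II spread measure, with the usual infinite
boundary contribution replaced by a finite 2 per characteristic so that the
mean stays well-defined.

The maximisation is a greedy stepwise pass over strata followed by
single-swap improvement passes; on small instances this provably attains
the exhaustive optimum (see the test oracle).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["CaseSelection", "crowding_distance", "mean_crowding_distance", "select_diverse_cases"]

BOUNDARY_CONTRIBUTION = 2.0  # per characteristic; interior contributions are <= 1

SELECTION_CHARACTERISTICS = ["mae", "land_ha", "livestock_tlu", "market_access"]


@dataclasses.dataclass
class CaseSelection:
    """Chosen household per stratum plus the achieved diversity."""

    selected: pd.DataFrame  # columns: stratum_id, household_id, front_rank
    mean_crowding_distance: float
    empty_strata: list[str]

    @property
    def household_ids(self) -> list:
        return list(self.selected["household_id"])


def crowding_distance(points) -> np.ndarray:
    """Crowding distance of each point within the point set.

    Per characteristic the points are sorted; an interior point contributes
    (next - prev) / (max - min), the two boundary points contribute
    ``BOUNDARY_CONTRIBUTION``. A characteristic constant across the set
    contributes nothing. The distance is the sum over characteristics.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an m x k matrix of points")
    m, k = x.shape
    if m < 2:
        raise ValueError("crowding distance needs at least 2 points")
    dist = np.zeros(m)
    for j in range(k):
        col = x[:, j]
        rng = col.max() - col.min()
        if rng == 0:
            continue
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        contrib = np.empty(m)
        contrib[0] = contrib[-1] = BOUNDARY_CONTRIBUTION
        if m > 2:
            contrib[1:-1] = (sorted_col[2:] - sorted_col[:-2]) / rng
        dist[order] += contrib
    return dist


def mean_crowding_distance(points) -> float:
    """Mean crowding distance of a point set (0 for a single point)."""
    x = np.asarray(points, dtype=float)
    if len(x) < 2:
        return 0.0
    return float(crowding_distance(x).mean())


def _stratum_sort_key(label):
    """Ascending land decile, low-livestock before high, for 'D<d>-<class>' ids;
    plain lexicographic for any other labelling."""
    s = str(label)
    if s.startswith("D") and "-" in s:
        head, _, cls = s.partition("-")
        try:
            return (0, int(head[1:]), 0 if cls == "low" else 1, s)
        except ValueError:
            pass
    return (1, 0, 0, s)


def _normalize(chars: pd.DataFrame) -> pd.DataFrame:
    rng = chars.max() - chars.min()
    rng = rng.replace(0, 1.0)
    return (chars - chars.min()) / rng


def select_diverse_cases(
    deviant_ids,
    front_rank: pd.Series,
    stratum_id: pd.Series,
    characteristics: pd.DataFrame,
) -> CaseSelection:
    """Pick one deviant per non-empty stratum maximising mean crowding distance.

    Parameters
    ----------
    deviant_ids
        Ids of positive deviants (the candidate pool).
    front_rank, stratum_id, characteristics
        Indexed by household id; ``characteristics`` holds the four numeric
        selection characteristics (min-max normalized internally).

    The candidate pool of a stratum is its rank-1 deviants when any exist,
    else its rank-2 (or deeper) deviants. Strata are visited in a fixed,
    sorted order; at each step the candidate maximising the provisional
    selection's mean crowding distance is added (ties broken by household
    id). Single-swap improvement passes then run until no swap raises the
    mean. Deterministic given input order; empty strata are skipped and
    reported.
    """
    deviant_ids = list(deviant_ids)
    if not deviant_ids:
        raise ValueError("no positive deviants to select from")
    chars = _normalize(characteristics.loc[deviant_ids].astype(float))

    pools: dict[str, list] = {}
    for s in sorted(set(stratum_id.loc[deviant_ids]), key=_stratum_sort_key):
        members = [h for h in deviant_ids if stratum_id.loc[h] == s]
        best_rank = min(front_rank.loc[h] for h in members)
        pools[s] = sorted([h for h in members if front_rank.loc[h] == best_rank])

    all_strata = sorted(set(stratum_id), key=_stratum_sort_key)
    empty = [s for s in all_strata if s not in pools]

    def score(ids: list) -> float:
        return mean_crowding_distance(chars.loc[ids].to_numpy())

    strata = sorted(pools, key=_stratum_sort_key)
    selection: dict[str, object] = {}
    for s in strata:
        best_h, best_val = None, -np.inf
        for h in pools[s]:
            val = score(list(selection.values()) + [h])
            if val > best_val + 1e-12:
                best_h, best_val = h, val
        selection[s] = best_h

    improved = True
    while improved:
        improved = False
        for s in strata:
            current = selection[s]
            base = score(list(selection.values()))
            best_h, best_val = current, base
            for h in pools[s]:
                if h == current:
                    continue
                trial = dict(selection)
                trial[s] = h
                val = score(list(trial.values()))
                if val > best_val + 1e-12:
                    best_h, best_val = h, val
            if best_h != current:
                selection[s] = best_h
                improved = True

    chosen = pd.DataFrame(
        {
            "stratum_id": strata,
            "household_id": [selection[s] for s in strata],
            "front_rank": [int(front_rank.loc[selection[s]]) for s in strata],
        }
    )
    return CaseSelection(
        selected=chosen,
        mean_crowding_distance=score(list(selection.values())),
        empty_strata=empty,
    )
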