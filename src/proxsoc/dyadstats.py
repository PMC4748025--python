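"""Dyad-level statistics: Hinde index, Friedman average-rank test, Nemenyi.

The Hinde index for a female-male dyad is HI = A_f - R_f, where A_f is the
proportion of the dyad's approaches performed by the female and R_f the
proportion of its retreats performed by the female; supplants are excluded
throughout, and dyads with fewer than 10 approach-retreat interactions are
excluded rather than scored.

The Friedman test ranks treatments within each block (midranks for ties)
and applies the standard tie correction.  For small tables the p-value is
computed exactly over the within-block permutation distribution via dynamic
programming; otherwise the chi-squared approximation with k-1 df is used.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError
from .records import BehaviourEvent, BehaviourType
from .status import StatusAssignment, status_of

__all__ = [
    "HindeInput",
    "HindeResult",
    "hinde_counts",
    "hinde_index",
    "FriedmanResult",
    "friedman_test",
    "NemenyiResult",
    "nemenyi",
    "approach_proportions",
]


# ---------------------------------------------------------------------------
# Hinde index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HindeInput:
    dyad: tuple[str, str]  # (female, male)
    approaches_by_female: int
    approaches_total: int
    retreats_by_female: int
    retreats_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.approaches_by_female <= self.approaches_total:
            raise ConfigurationError("approach counts inconsistent")
        if not 0 <= self.retreats_by_female <= self.retreats_total:
            raise ConfigurationError("retreat counts inconsistent")

    @property
    def n_interactions(self) -> int:
        return self.approaches_total + self.retreats_total


@dataclass(frozen=True)
class HindeResult:
    dyad: tuple[str, str]
    value: float | None
    excluded: bool
    reason: str | None
    counts: HindeInput


def hinde_counts(
    events: Sequence[BehaviourEvent], dyad: tuple[str, str]
) -> HindeInput:
    """Tally the dyad's approaches and retreats; supplants are dropped."""
    female, male = dyad
    pair = frozenset(dyad)
    a_f = a_tot = r_f = r_tot = 0
    for ev in events:
        if ev.participants() != pair:
            continue
        if ev.type is BehaviourType.APPROACH:
            a_tot += 1
            if ev.actor == female:
                a_f += 1
        elif ev.type is BehaviourType.RETREAT:
            r_tot += 1
            if ev.actor == female:
                r_f += 1
        # SUPPLANT and all other types excluded by definition
    return HindeInput(
        dyad=dyad,
        approaches_by_female=a_f,
        approaches_total=a_tot,
        retreats_by_female=r_f,
        retreats_total=r_tot,
    )


def hinde_index(
    events: Sequence[BehaviourEvent],
    dyad: tuple[str, str],
    min_interactions: int = 10,
) -> HindeResult:
    """HI = A_f - R_f in [-1, 1], or an exclusion.

    Dyads with fewer than ``min_interactions`` approach-retreat interactions
    are excluded; so are dyads where either proportion has a zero
    denominator (no approaches at all, or no retreats at all), since the
    index is then undefined.
    """
    counts = hinde_counts(events, dyad)
    if counts.n_interactions < min_interactions:
        return HindeResult(
            dyad=dyad, value=None, excluded=True,
            reason=f"only {counts.n_interactions} approach-retreat interactions "
                   f"(< {min_interactions})",
            counts=counts,
        )
    if counts.approaches_total == 0 or counts.retreats_total == 0:
        which = "approaches" if counts.approaches_total == 0 else "retreats"
        return HindeResult(
            dyad=dyad, value=None, excluded=True,
            reason=f"no {which} observed; proportion undefined",
            counts=counts,
        )
    a_f = counts.approaches_by_female / counts.approaches_total
    r_f = counts.retreats_by_female / counts.retreats_total
    return HindeResult(dyad=dyad, value=a_f - r_f, excluded=False,
                       reason=None, counts=counts)


# ---------------------------------------------------------------------------
# Friedman average-rank test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p_value: float
    mean_ranks: tuple[float, ...]
    n_blocks: int
    k: int
    tie_correction: float
    method: str  # "exact" or "chi2"


def _block_ranks(data: np.ndarray) -> np.ndarray:
    """Within-block midranks, blocks x treatments."""
    return np.vstack([sps.rankdata(row) for row in data])


def _tie_correction(data: np.ndarray) -> float:
    """C = 1 - sum(t^3 - t) / (N k (k^2 - 1)) over all tie groups."""
    n, k = data.shape
    tie_sum = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    return 1.0 - tie_sum / (n * k * (k * k - 1))


def _statistic_from_ranks(ranks: np.ndarray, correction: float) -> float:
    n, k = ranks.shape
    mean_ranks = ranks.mean(axis=0)
    ss = float(np.sum((mean_ranks - (k + 1) / 2.0) ** 2))
    raw = 12.0 * n / (k * (k + 1)) * ss
    if correction <= 0.0:
        return 0.0  # every block fully tied; no information
    return raw / correction


def _exact_p_value(ranks: np.ndarray, ss_obs: float) -> float:
    """P(SS >= ss_obs) under independent within-block permutations.

    The statistic is monotone in SS = sum_j (Rbar_j - (k+1)/2)^2, so the
    permutation p-value can be computed on SS alone.  Distributions of
    column rank-sum vectors are convolved block by block (the tie pattern
    of each block is preserved, as in the permutation null).
    """
    n, k = ranks.shape
    dist: dict[tuple[float, ...], float] = {tuple([0.0] * k): 1.0}
    for row in ranks:
        row_t = tuple(row)
        perms: dict[tuple[float, ...], int] = {}
        for perm in itertools.permutations(row_t):
            perms[perm] = perms.get(perm, 0) + 1
        total = sum(perms.values())
        new: dict[tuple[float, ...], float] = {}
        for sums, p in dist.items():
            for perm, cnt in perms.items():
                key = tuple(s + v for s, v in zip(sums, perm))
                new[key] = new.get(key, 0.0) + p * cnt / total
        dist = new
    centre = n * (k + 1) / 2.0
    p = 0.0
    for sums, prob in dist.items():
        ss = sum((s - centre) ** 2 for s in sums) / (n * n)
        if ss >= ss_obs - 1e-12:
            p += prob
    return min(p, 1.0)


def friedman_test(
    counts: np.ndarray | Sequence[Sequence[float]], method: str = "auto"
) -> FriedmanResult:
    """Friedman average-rank test on an N blocks x k treatments table.

    ``method``: "exact" (full within-block permutation null), "chi2"
    (asymptotic), or "auto" (exact when (k!)^N <= 200000).
    """
    data = np.asarray(counts, dtype=float)
    if data.ndim != 2:
        raise ConfigurationError("counts must be a 2-D blocks x treatments table")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ConfigurationError(f"need N >= 2 blocks and k >= 2 treatments, got {n}x{k}")
    if np.isnan(data).any(axis=1).any():
        bad = int(np.where(np.isnan(data).any(axis=1))[0][0])
        raise ConfigurationError(f"block {bad} contains missing values")

    ranks = _block_ranks(data)
    correction = _tie_correction(data)
    statistic = _statistic_from_ranks(ranks, correction)
    mean_ranks = tuple(float(x) for x in ranks.mean(axis=0))
    df = k - 1

    if method == "auto":
        method = "exact" if math.factorial(k) ** n <= 200_000 else "chi2"
    if method == "exact":
        ss_obs = float(np.sum((np.asarray(mean_ranks) - (k + 1) / 2.0) ** 2))
        p = _exact_p_value(ranks, ss_obs)
    elif method == "chi2":
        p = float(sps.chi2.sf(statistic, df)) if correction > 0 else 1.0
    else:
        raise ConfigurationError(f"unknown method {method!r}")

    return FriedmanResult(
        statistic=statistic, df=df, p_value=p, mean_ranks=mean_ranks,
        n_blocks=n, k=k, tie_correction=correction, method=method,
    )


# ---------------------------------------------------------------------------
# Nemenyi post hoc test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NemenyiResult:
    critical_difference: float
    significant: np.ndarray  # k x k boolean, symmetric, False diagonal
    mean_rank_diff: np.ndarray
    alpha: float


def nemenyi(result: FriedmanResult, alpha: float = 0.05) -> NemenyiResult:
    """All-pairs rank comparison with the studentized-range critical value.

    Pair (i, j) is significant iff |Rbar_i - Rbar_j| > CD, with
    CD = q_{alpha,k} * sqrt(k (k+1) / (6 N)) and q the upper-alpha quantile
    of the studentized range (infinite df) divided by sqrt(2).
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    k, n = result.k, result.n_blocks
    q = float(sps.studentized_range.ppf(1.0 - alpha, k, np.inf))
    if not np.isfinite(q):  # some scipy versions dislike df=inf
        q = float(sps.studentized_range.ppf(1.0 - alpha, k, 1e7))
    cd = q / math.sqrt(2.0) * math.sqrt(k * (k + 1) / (6.0 * n))
    ranks = np.asarray(result.mean_ranks)
    diff = np.abs(ranks[:, None] - ranks[None, :])
    sig = diff > cd
    np.fill_diagonal(sig, False)
    return NemenyiResult(critical_difference=cd, significant=sig,
                         mean_rank_diff=diff, alpha=alpha)


# ---------------------------------------------------------------------------
# Approach initiation by male status class
# ---------------------------------------------------------------------------


def approach_proportions(
    events: Sequence[BehaviourEvent],
    statuses: Sequence[StatusAssignment],
    female_ids: set[str] | None = None,
) -> dict[str, dict[str, float | int | None]]:
    """Share of approaches initiated by the male, per male status class.

    Returns {status: {"male_initiated": int, "total": int, "proportion":
    float | None}}; a class with no approaches reports proportion None.
    """
    if female_ids is None:
        female_ids = set()
        for st in statuses:
            female_ids |= set(st.primary_of)
    tallies: dict[str, list[int]] = {}
    for ev in events:
        if ev.type is not BehaviourType.APPROACH:
            continue
        parts = ev.participants()
        females = parts & female_ids
        if len(females) != 1:
            continue  # not an intersexual dyad we can classify
        female = next(iter(females))
        male = next(iter(parts - {female}))
        st = status_of(statuses, female, male, ev.time.day)
        bucket = tallies.setdefault(st, [0, 0])
        bucket[1] += 1
        if ev.actor == male:
            bucket[0] += 1
    out: dict[str, dict[str, float | int | None]] = {}
    for st, (male_init, total) in tallies.items():
        out[st] = {
            "male_initiated": male_init,
            "total": total,
            "proportion": male_init / total if total else None,
        }
    return out
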