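"""Per-window classification of males as primary / secondary / unaffiliated.

Scan data are pooled into non-overlapping fortnights anchored at study day
1.  Within a window, each female's "primary male" is the male recorded most
often in her 2-m ring; other males seen in her 2-m ring are "secondary";
males never seen within 2 m of any female in the window are "unaffiliated"
(a global, not per-female, set).

Tie-breaking cascade for the primary (logged whenever used): higher 5-m
count, then carry-over of the previous window's primary, then the
lexicographically smallest id.  A female with zero 2-m scans in a window
carries over her previous primary, flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .records import (
    AgeClass,
    BehaviourType,
    FocalSample,
    Individual,
    ScanRecord,
    Sex,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StatusAssignment",
    "fortnight_windows",
    "assign_status",
    "status_of",
    "preference_test",
    "PreferenceResult",
    "behaviour_occurrence_table",
    "scan_count_blocks",
]

#: Behaviours scored in the occurrence table.
OCCURRENCE_BEHAVIOURS = (
    BehaviourType.GROOM,
    BehaviourType.GREET,
    BehaviourType.AGGRESSION,
    BehaviourType.INFANT_HANDLING,
)


@dataclass(frozen=True)
class StatusAssignment:
    window: int  # 1-based fortnight index
    window_days: tuple[int, int]
    primary_of: Mapping[str, str]
    secondary_of: Mapping[str, frozenset[str]]
    unaffiliated: frozenset[str]
    carried_over: frozenset[str] = frozenset()
    tie_log: tuple[str, ...] = ()


def fortnight_windows(
    first_day: int, last_day: int, length: int = 14
) -> list[tuple[int, int]]:
    """Non-overlapping full-length windows anchored at ``first_day``.

    The final window is not clamped to ``last_day``, so every study day up
    to the end of the last fortnight maps to exactly one window."""
    if length < 1:
        raise ConfigurationError("window length must be >= 1")
    out = []
    start = first_day
    while start <= last_day:
        out.append((start, start + length - 1))
        start += length
    return out


def assign_status(
    scans: Sequence[ScanRecord],
    roster: Sequence[Individual],
    windows: Sequence[tuple[int, int]] | None = None,
    window_length: int = 14,
) -> list[StatusAssignment]:
    if not scans:
        raise ConfigurationError("no scans to assign status from")
    males = sorted(ind.id for ind in roster if ind.sex is Sex.MALE)
    females = sorted(
        ind.id
        for ind in roster
        if ind.sex is Sex.FEMALE and ind.age_class is AgeClass.ADULT
    )
    days = [s.time.day for s in scans]
    if windows is None:
        windows = fortnight_windows(min(days), max(days), window_length)

    scanned_females = {s.focal_female for s in scans}
    for female in females:
        if female not in scanned_females:
            logger.warning("female %s has no scans in any window; excluded", female)
    females = [f for f in females if f in scanned_females]

    out: list[StatusAssignment] = []
    prev_primary: dict[str, str] = {}
    for w_idx, (d0, d1) in enumerate(windows, start=1):
        counts2: dict[str, dict[str, int]] = {f: {} for f in females}
        counts5: dict[str, dict[str, int]] = {f: {} for f in females}
        seen2_any: set[str] = set()
        has_scan: set[str] = set()
        for scan in scans:
            if not d0 <= scan.time.day <= d1:
                continue
            f = scan.focal_female
            if f not in counts2:
                continue
            has_scan.add(f)
            for m in scan.males_2m:
                counts2[f][m] = counts2[f].get(m, 0) + 1
                seen2_any.add(m)
            for m in scan.males_5m:
                counts5[f][m] = counts5[f].get(m, 0) + 1

        primary_of: dict[str, str] = {}
        secondary_of: dict[str, frozenset[str]] = {}
        carried: set[str] = set()
        ties: list[str] = []
        for female in females:
            c2 = counts2[female]
            if not c2:
                if female in prev_primary:
                    primary_of[female] = prev_primary[female]
                    carried.add(female)
                    logger.info(
                        "window %d: %s has no 2-m scans; carrying over primary %s",
                        w_idx, female, prev_primary[female],
                    )
                secondary_of[female] = frozenset()
                continue
            top = max(c2.values())
            leaders = sorted(m for m, c in c2.items() if c == top)
            if len(leaders) > 1:
                c5 = counts5[female]
                top5 = max(c5.get(m, 0) for m in leaders)
                leaders5 = [m for m in leaders if c5.get(m, 0) == top5]
                if len(leaders5) == 1:
                    choice = leaders5[0]
                    ties.append(f"w{w_idx}:{female}: 2-m tie {leaders} broken by 5-m count -> {choice}")
                elif prev_primary.get(female) in leaders5:
                    choice = prev_primary[female]
                    ties.append(f"w{w_idx}:{female}: tie {leaders5} broken by carry-over -> {choice}")
                else:
                    choice = leaders5[0]
                    ties.append(f"w{w_idx}:{female}: tie {leaders5} broken lexicographically -> {choice}")
            else:
                choice = leaders[0]
            primary_of[female] = choice
            secondary_of[female] = frozenset(m for m in c2 if m != choice)

        for line in ties:
            logger.info("tie-break %s", line)
        out.append(
            StatusAssignment(
                window=w_idx,
                window_days=(d0, d1),
                primary_of=primary_of,
                secondary_of=secondary_of,
                unaffiliated=frozenset(m for m in males if m not in seen2_any),
                carried_over=frozenset(carried),
                tie_log=tuple(ties),
            )
        )
        prev_primary.update(primary_of)
    return out


def status_of(
    statuses: Sequence[StatusAssignment], female: str, male: str, day: int
) -> str:
    """Male's category relative to a female on a given day.

    Returns ``primary`` / ``secondary`` / ``unaffiliated`` / ``other``;
    ``unwindowed`` when the day falls outside every status window.
    """
    for st in statuses:
        if st.window_days[0] <= day <= st.window_days[1]:
            if st.primary_of.get(female) == male:
                return "primary"
            if male in st.secondary_of.get(female, frozenset()):
                return "secondary"
            if male in st.unaffiliated:
                return "unaffiliated"
            return "other"
    return "unwindowed"


@dataclass(frozen=True)
class PreferenceResult:
    friedman: "FriedmanResult"  # noqa: F821 - imported lazily to avoid cycle
    nemenyi: "NemenyiResult"  # noqa: F821
    preferred: str | None
    males: tuple[str, ...]


def preference_test(
    scan_counts: pd.DataFrame, alpha: float = 0.05
) -> PreferenceResult:
    """Friedman + Nemenyi preferred-associate test for one female.

    ``scan_counts``: blocks x males matrix of per-block scan counts.  A
    "preferred associate" is declared when the top-ranked male differs
    significantly from every other male at level ``alpha``.  An all-zero
    matrix yields a no-preference result rather than an error.
    """
    from .dyadstats import friedman_test, nemenyi

    males = tuple(str(c) for c in scan_counts.columns)
    data = scan_counts.to_numpy(dtype=float)
    if np.all(data == data[0, 0]):
        result = friedman_test(data)
        nres = nemenyi(result, alpha=alpha)
        return PreferenceResult(friedman=result, nemenyi=nres, preferred=None, males=males)
    result = friedman_test(data)
    nres = nemenyi(result, alpha=alpha)
    top = int(np.argmax(result.mean_ranks))
    others = [j for j in range(len(males)) if j != top]
    preferred = males[top] if all(nres.significant[top, j] for j in others) else None
    return PreferenceResult(friedman=result, nemenyi=nres, preferred=preferred, males=males)


def scan_count_blocks(
    scans: Sequence[ScanRecord],
    female: str,
    males: Sequence[str],
    windows: Sequence[tuple[int, int]],
    ring: str = "2m",
) -> pd.DataFrame:
    """Per-window scan-count matrix (blocks x males) for one female."""
    if ring not in ("2m", "5m"):
        raise ConfigurationError("ring must be '2m' or '5m'")
    rows = []
    for d0, d1 in windows:
        counts = {m: 0 for m in males}
        for scan in scans:
            if scan.focal_female != female or not d0 <= scan.time.day <= d1:
                continue
            in_ring = scan.males_2m if ring == "2m" else scan.males_2m | scan.males_5m
            for m in in_ring:
                if m in counts:
                    counts[m] += 1
        rows.append(counts)
    return pd.DataFrame(rows, columns=list(males))


def behaviour_occurrence_table(
    focals: Sequence[FocalSample],
    statuses: Sequence[StatusAssignment],
    roster: Sequence[Individual],
) -> pd.DataFrame:
    """Model-ready long-format yes/no occurrence table.

    One row per (focal sample, male, behaviour class): columns focal_id,
    female, male, male_status, behaviour, occurred, state, in_window.  No
    model fitting is performed here; the table is the hand-off artifact for
    external mixed-model software.
    """
    males = sorted(ind.id for ind in roster if ind.sex is Sex.MALE)
    rows = []
    for focal in focals:
        day = focal.start_time.day
        occurred: dict[tuple[str, BehaviourType], int] = {}
        for ev in focal.events:
            if ev.type in OCCURRENCE_BEHAVIOURS:
                male = ev.actor if ev.actor != focal.focal_female else ev.recipient
                occurred[(male, ev.type)] = 1
        for male in males:
            st = status_of(statuses, focal.focal_female, male, day)
            if st == "unwindowed":
                logger.warning("focal %s on day %d falls outside all status windows",
                               focal.focal_id, day)
            for behaviour in OCCURRENCE_BEHAVIOURS:
                rows.append(
                    {
                        "focal_id": focal.focal_id,
                        "female": focal.focal_female,
                        "male": male,
                        "male_status": st,
                        "behaviour": behaviour.value,
                        "occurred": occurred.get((male, behaviour), 0),
                        "state": focal.state.value,
                        "in_window": st != "unwindowed",
                    }
                )
    return pd.DataFrame(rows)
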