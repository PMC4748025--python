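"""Transfer detection from the ad libitum stream and tenure computation.

A female is recorded as changing primary male only when a non-surreptitious
affiliative interaction (groom / greet / copulation) with a different male
is followed by sustained affiliation with that same male (a configurable
number of confirming affiliative events, default 1).  Surreptitious
interactions never trigger a change.  The transfer is dated at the
triggering event's study day.
"""

from __future__ import annotations

import enum
import logging
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ConfigurationError
from .records import AFFILIATIVE_TYPES, BehaviourEvent

logger = logging.getLogger(__name__)

__all__ = [
    "TransferType",
    "Transfer",
    "Tenure",
    "detect_transfers",
    "tenures",
]


class TransferType(enum.Enum):
    INTRA_PARTY = "INTRA_PARTY"
    INTER_PARTY = "INTER_PARTY"
    INTER_GANG = "INTER_GANG"


@dataclass(frozen=True)
class Transfer:
    female: str
    day: int
    old_male: str
    new_male: str
    type: TransferType
    evidence: str  # id of the triggering event

    def __post_init__(self) -> None:
        if self.old_male == self.new_male:
            raise ConfigurationError("old and new male must differ")


@dataclass(frozen=True)
class Tenure:
    female: str
    male: str | None
    start_day: int
    end_day: int
    truncated: bool

    @property
    def length_days(self) -> int:
        return self.end_day - self.start_day + 1


def _transfer_type(
    old_male: str,
    new_male: str,
    party_map: Mapping[str, str],
    gang_map: Mapping[str, str] | None,
) -> TransferType:
    p_old, p_new = party_map.get(old_male), party_map.get(new_male)
    if p_old == p_new:
        return TransferType.INTRA_PARTY
    if gang_map is not None and gang_map.get(p_old) != gang_map.get(p_new):
        return TransferType.INTER_GANG
    return TransferType.INTER_PARTY


def detect_transfers(
    adlib_events: Sequence[BehaviourEvent],
    statuses,
    party_map: Mapping[str, str],
    gang_map: Mapping[str, str] | None = None,
    confirmations: int = 1,
    initial_primary: Mapping[str, str] | None = None,
) -> list[Transfer]:
    """Walk the affiliative event stream and apply the transfer rule.

    ``statuses`` (per-window status assignments) provide each female's
    starting primary male; ``initial_primary`` overrides them.  Males are
    recognised as the participant present in ``party_map``.  A pending
    candidate is voided by any affiliative interaction with a different
    male (including the current primary); surreptitious events are ignored
    entirely.  Raising ``confirmations`` can only reduce the number of
    transfers detected.
    """
    if confirmations < 0:
        raise ConfigurationError("confirmations must be >= 0")
    current: dict[str, str] = {}
    if statuses:
        current.update(statuses[0].primary_of)
    if initial_primary:
        current.update(initial_primary)

    events = sorted(adlib_events, key=lambda e: (e.time, e.event_id))
    # pending[female] = (candidate male, confirmations seen, trigger event)
    pending: dict[str, tuple[str, int, BehaviourEvent]] = {}
    transfers: list[Transfer] = []
    seen_affiliative: set[str] = set()

    for ev in events:
        if ev.type not in AFFILIATIVE_TYPES:
            continue
        parts = ev.participants()
        males = parts & set(party_map)
        females = parts - males
        if len(males) != 1 or len(females) != 1:
            continue
        male = next(iter(males))
        female = next(iter(females))
        seen_affiliative.add(female)
        if ev.surreptitious:
            continue  # never triggers, confirms, nor voids
        if female not in current:
            current[female] = male  # first observed affiliation defines baseline
            continue
        if male == current[female]:
            pending.pop(female, None)
            continue
        cand = pending.get(female)
        if cand is not None and cand[0] == male:
            male_cand, n_conf, trigger = cand
            n_conf += 1
            if n_conf >= confirmations:
                transfers.append(
                    Transfer(
                        female=female,
                        day=trigger.time.day,
                        old_male=current[female],
                        new_male=male,
                        type=_transfer_type(current[female], male, party_map, gang_map),
                        evidence=trigger.event_id,
                    )
                )
                current[female] = male
                pending.pop(female, None)
            else:
                pending[female] = (male, n_conf, trigger)
        else:
            # new candidate (voids any previous one)
            if confirmations == 0:
                transfers.append(
                    Transfer(
                        female=female, day=ev.time.day, old_male=current[female],
                        new_male=male,
                        type=_transfer_type(current[female], male, party_map, gang_map),
                        evidence=ev.event_id,
                    )
                )
                current[female] = male
                pending.pop(female, None)
            else:
                pending[female] = (male, 0, ev)

    for female in current:
        if female not in seen_affiliative:
            logger.info("female %s had no affiliative events; no transfers detectable", female)
    return transfers


def tenures(
    transfers: Sequence[Transfer],
    study_span: int = 507,
    primary_map: Mapping[str, str] | None = None,
    females: Sequence[str] | None = None,
) -> tuple[list[Tenure], float | None]:
    """Maximal constant-primary intervals per female, plus the median length.

    A transfer at day d ends the old tenure at day d (inclusive) and starts
    the new one at day d+1.  The first and last tenure of each female touch
    a study boundary and are flagged truncated; interior tenures are not.
    The median is computed over all tenures, truncated included.
    """
    by_female: dict[str, list[Transfer]] = {}
    for tr in transfers:
        by_female.setdefault(tr.female, []).append(tr)
    all_females = list(females) if females is not None else sorted(by_female)
    primary_map = primary_map or {}

    out: list[Tenure] = []
    for female in all_females:
        trs = sorted(by_female.get(female, []), key=lambda t: t.day)
        if not trs:
            out.append(
                Tenure(female=female, male=primary_map.get(female),
                       start_day=1, end_day=study_span, truncated=True)
            )
            continue
        start = 1
        for tr in trs:
            out.append(
                Tenure(female=female, male=tr.old_male,
                       start_day=start, end_day=tr.day,
                       truncated=start == 1)
            )
            start = tr.day + 1
        out.append(
            Tenure(female=female, male=trs[-1].new_male,
                   start_day=start, end_day=study_span, truncated=True)
        )
    median = float(statistics.median(t.length_days for t in out)) if out else None
    return out, median
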