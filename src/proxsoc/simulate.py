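"""Synthetic multilevel society and its observation process.

The simulator produces a gang of parties, each party containing one-male
units (one primary male, 0-2 secondary males, 1-4 adult females, plus
bachelor males), then generates daily reproductive states, focal follows
with proximity scans, focal behaviour events, and an ad libitum event
stream — all with known ground truth so the analysis modules can be
validated by parameter recovery.

Randomness is split into named substreams (society / states / observation)
derived from a single user seed, so changing one stage's parameters does
not perturb another stage's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .records import (
    CYCLE_STAGES,
    AgeClass,
    BehaviourEvent,
    BehaviourType,
    FocalSample,
    Individual,
    Protocol,
    ReproductiveState,
    ScanRecord,
    Sex,
    Timestamp,
)

__all__ = [
    "SocietyConfig",
    "SocietyTruth",
    "ScheduledTransfer",
    "simulate_society",
    "simulate_states",
    "simulate_observation",
    "simulate_study",
]


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named simulation stage."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


_DEFAULT_GREET_LOGITS = {
    # Log-odds that a 30-min focal contains >= 1 greeting, by state.
    # Baseline is lactating; other states add their contrast.
    ReproductiveState.L: -1.442,
    ReproductiveState.P: -1.442 + 0.641,
    ReproductiveState.C0: -1.442 + 0.770,
    ReproductiveState.C1: -1.442 + 0.941,
    ReproductiveState.C2: -1.442 + 1.034,
    ReproductiveState.C3: -1.442 + 1.209,
}

_DEFAULT_STATE_MEAN_DAYS = {
    # Assumed semi-Markov block means (days); not field estimates.
    ReproductiveState.L: 110.0,
    ReproductiveState.P: 170.0,
    ReproductiveState.C0: 10.0,
    ReproductiveState.C1: 6.0,
    ReproductiveState.C2: 6.0,
    ReproductiveState.C3: 8.0,
}


@dataclass(frozen=True)
class SocietyConfig:
    """Generative parameters for the society and its observation process."""

    n_parties: int = 3
    units_per_party: tuple[int, int] = (2, 3)
    females_per_unit: tuple[int, int] = (1, 4)
    secondary_males_per_unit: tuple[int, int] = (0, 2)
    n_bachelors: int = 4
    study_days: int = 507
    focals_per_female_per_week: tuple[int, int] = (1, 3)

    # Per-scan probability that a male of the given relation to the focal
    # female is recorded in her 2-m ring / in the (2,5]-m annulus.
    p2m_primary: float = 0.30
    p2m_secondary: float = 0.04
    p2m_other: float = 0.005
    p5m_primary: float = 0.25
    p5m_secondary: float = 0.12
    p5m_other: float = 0.03

    greet_logit_by_state: Mapping[ReproductiveState, float] = field(
        default_factory=lambda: dict(_DEFAULT_GREET_LOGITS)
    )

    # Behaviour rates (focal protocol), per observation hour.
    groom_rate_primary: float = 1.26  # grooming min per focal hour
    groom_rate_secondary: float = 0.16
    groom_bout_mean_primary: float = 3.52  # mean bout length, min
    groom_bout_mean_secondary: float = 2.85
    aggression_rate_per_h: float = 0.10
    greet_rate_per_h: float = 0.85
    copulation_rate_per_h: float = 0.69  # while tumescent only
    infant_handling_rate_per_h: float = 0.10  # while lactating only
    approach_rate_per_h: float = 2.0
    retreat_rate_per_h: float = 2.0

    copulation_fidelity: float = 0.986
    p_greet_primary: float = 0.90
    p_aggression_primary: float = 0.80
    p_infant_handling_primary: float = 0.59
    p_approach_by_male_primary: float = 0.60
    p_approach_by_male_secondary: float = 0.76
    p_retreat_by_female_primary: float = 0.57
    p_retreat_by_female_secondary: float = 0.60
    p_surreptitious_secondary: float = 0.85

    # Ad libitum stream intensities (events per female-day).
    adlib_primary_events_per_day: float = 1.00
    adlib_secondary_events_per_day: float = 0.03
    adlib_copulations_per_tumescent_day: float = 0.30

    # Female transfers between primary males.
    transfer_hazard_per_fortnight: float = 0.033
    tenure_target_days: float = 200.0  # documentation of the calibration aim

    # Reproductive-state chain.
    state_mean_days: Mapping[ReproductiveState, float] = field(
        default_factory=lambda: dict(_DEFAULT_STATE_MEAN_DAYS)
    )
    p_conceive_per_cycle: float = 0.30

    seed: int = 0

    def validate(self) -> None:
        def _range_ok(r: tuple[int, int]) -> bool:
            return len(r) == 2 and 0 <= r[0] <= r[1]

        for name in ("units_per_party", "females_per_unit",
                     "secondary_males_per_unit", "focals_per_female_per_week"):
            if not _range_ok(tuple(getattr(self, name))):
                raise ConfigurationError(f"{name} must be a non-empty (lo, hi) range")
        if self.females_per_unit[0] < 1:
            raise ConfigurationError("each unit needs at least one female")
        if self.units_per_party[0] < 1:
            raise ConfigurationError("each party needs at least one unit")
        if self.n_parties < 1:
            raise ConfigurationError("n_parties must be >= 1")
        if self.n_bachelors < 0:
            raise ConfigurationError("n_bachelors must be >= 0")
        if self.study_days < 1:
            raise ConfigurationError("study_days must be >= 1")
        probs = [
            self.p2m_primary, self.p2m_secondary, self.p2m_other,
            self.p5m_primary, self.p5m_secondary, self.p5m_other,
            self.copulation_fidelity, self.p_greet_primary,
            self.p_aggression_primary, self.p_infant_handling_primary,
            self.p_approach_by_male_primary, self.p_approach_by_male_secondary,
            self.p_retreat_by_female_primary, self.p_retreat_by_female_secondary,
            self.p_surreptitious_secondary, self.transfer_hazard_per_fortnight,
            self.p_conceive_per_cycle,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        for rel in ("primary", "secondary", "other"):
            if getattr(self, f"p2m_{rel}") + getattr(self, f"p5m_{rel}") > 1.0:
                raise ConfigurationError(f"p2m_{rel} + p5m_{rel} must be <= 1")
        rates = [
            self.groom_rate_primary, self.groom_rate_secondary,
            self.aggression_rate_per_h, self.greet_rate_per_h,
            self.copulation_rate_per_h, self.infant_handling_rate_per_h,
            self.approach_rate_per_h, self.retreat_rate_per_h,
            self.adlib_primary_events_per_day, self.adlib_secondary_events_per_day,
            self.adlib_copulations_per_tumescent_day,
        ]
        if any(r < 0 for r in rates):
            raise ConfigurationError("rates must be non-negative")
        if self.groom_bout_mean_primary <= 0 or self.groom_bout_mean_secondary <= 0:
            raise ConfigurationError("grooming bout means must be positive")
        if set(self.greet_logit_by_state) != set(ReproductiveState):
            raise ConfigurationError("greet_logit_by_state must cover all six states")
        if set(self.state_mean_days) != set(ReproductiveState):
            raise ConfigurationError("state_mean_days must cover all six states")
        if any(m < 1.0 for m in self.state_mean_days.values()):
            raise ConfigurationError("state block means must be >= 1 day")


@dataclass(frozen=True)
class ScheduledTransfer:
    female: str
    day: int
    old_male: str
    new_male: str
    transfer_type: str  # INTRA_PARTY / INTER_PARTY / INTER_GANG


@dataclass
class SocietyTruth:
    """Ground truth emitted by :func:`simulate_society`."""

    roster: list[Individual]
    unit_of: dict[str, str]  # female -> initial unit id
    party_of_unit: dict[str, str]
    party_of_male: dict[str, str]
    primary_male_of_unit: dict[str, str]
    secondary_males_of_unit: dict[str, frozenset[str]]
    transfer_schedule: list[ScheduledTransfer]
    config: SocietyConfig

    # female -> sorted list of (start_day, unit id); built in __post_init__
    _segments: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self._segments:
            unit_by_primary = {m: u for u, m in self.primary_male_of_unit.items()}
            segs: dict[str, list[tuple[int, str]]] = {
                f: [(1, u)] for f, u in self.unit_of.items()
            }
            for tr in sorted(self.transfer_schedule, key=lambda t: t.day):
                segs[tr.female].append((tr.day, unit_by_primary[tr.new_male]))
            self._segments = segs

    @property
    def females(self) -> list[str]:
        return sorted(self.unit_of)

    def unit_on(self, female: str, day: int) -> str:
        unit = None
        for start, u in self._segments[female]:
            if start <= day:
                unit = u
            else:
                break
        assert unit is not None
        return unit

    def primary_on(self, female: str, day: int) -> str:
        return self.primary_male_of_unit[self.unit_on(female, day)]

    def secondaries_on(self, female: str, day: int) -> frozenset[str]:
        return self.secondary_males_of_unit[self.unit_on(female, day)]


def simulate_society(config: SocietyConfig) -> SocietyTruth:
    """Draw a society layout and a transfer schedule.

    Deterministic given ``config.seed``.  Transfers happen only at fortnight
    boundaries and move a female to a bachelor (who thereby founds a new
    unit) or to another unit's primary male — never to one of her own
    secondary males.
    """
    config.validate()
    rng = _substream(config.seed, "society")

    roster: list[Individual] = []
    party_of_unit: dict[str, str] = {}
    primary_male_of_unit: dict[str, str] = {}
    secondary_males_of_unit: dict[str, frozenset[str]] = {}
    unit_of: dict[str, str] = {}
    party_of_male: dict[str, str] = {}

    male_counter = 0
    female_counter = 0

    def next_male(age: AgeClass) -> str:
        nonlocal male_counter
        male_counter += 1
        mid = f"M{male_counter:02d}"
        roster.append(Individual(id=mid, sex=Sex.MALE, age_class=age))
        return mid

    def next_female() -> str:
        nonlocal female_counter
        female_counter += 1
        fid = f"F{female_counter:02d}"
        roster.append(Individual(id=fid, sex=Sex.FEMALE, age_class=AgeClass.ADULT))
        return fid

    unit_idx = 0
    for p in range(1, config.n_parties + 1):
        party = f"P{p}"
        n_units = int(rng.integers(config.units_per_party[0], config.units_per_party[1] + 1))
        for _ in range(n_units):
            unit_idx += 1
            unit = f"U{unit_idx:02d}"
            party_of_unit[unit] = party
            primary = next_male(AgeClass.ADULT)
            primary_male_of_unit[unit] = primary
            party_of_male[primary] = party
            n_sec = int(rng.integers(
                config.secondary_males_per_unit[0], config.secondary_males_per_unit[1] + 1
            ))
            secondaries = []
            for _ in range(n_sec):
                age = AgeClass.SUBADULT if rng.random() < 0.5 else AgeClass.ADULT
                sec = next_male(age)
                secondaries.append(sec)
                party_of_male[sec] = party
            secondary_males_of_unit[unit] = frozenset(secondaries)
            n_fem = int(rng.integers(config.females_per_unit[0], config.females_per_unit[1] + 1))
            for _ in range(n_fem):
                unit_of[next_female()] = unit

    parties = [f"P{p}" for p in range(1, config.n_parties + 1)]
    bachelors: list[str] = []
    for _ in range(config.n_bachelors):
        b = next_male(AgeClass.ADULT)
        bachelors.append(b)
        party_of_male[b] = parties[int(rng.integers(len(parties)))]

    # Transfer schedule: per fortnight boundary, each female moves with the
    # configured hazard, to a bachelor or another unit's primary male.
    unit_by_primary = {m: u for u, m in primary_male_of_unit.items()}
    current_unit = dict(unit_of)
    avail_bachelors = list(bachelors)
    transfers: list[ScheduledTransfer] = []
    # No transfers in the final fortnight: a switch with < 2 weeks of
    # remaining observation is undetectable by construction.
    day = 15
    while day <= config.study_days - 13:
        for female in sorted(unit_of):
            if rng.random() >= config.transfer_hazard_per_fortnight:
                continue
            old_unit = current_unit[female]
            old_male = primary_male_of_unit[old_unit]
            candidates = sorted(
                m for m in primary_male_of_unit.values() if m != old_male
            ) + sorted(avail_bachelors)
            if not candidates:
                continue
            new_male = candidates[int(rng.integers(len(candidates)))]
            if new_male in avail_bachelors:
                # Bachelor founds a new unit (no secondary males) in his party.
                unit_idx += 1
                new_unit = f"U{unit_idx:02d}"
                party_of_unit[new_unit] = party_of_male[new_male]
                primary_male_of_unit[new_unit] = new_male
                secondary_males_of_unit[new_unit] = frozenset()
                unit_by_primary[new_male] = new_unit
                avail_bachelors.remove(new_male)
            new_unit = unit_by_primary[new_male]
            ttype = (
                "INTRA_PARTY"
                if party_of_unit[new_unit] == party_of_unit[old_unit]
                else "INTER_PARTY"
            )
            transfers.append(
                ScheduledTransfer(
                    female=female, day=day, old_male=old_male,
                    new_male=new_male, transfer_type=ttype,
                )
            )
            current_unit[female] = new_unit
        day += 14

    return SocietyTruth(
        roster=roster,
        unit_of=unit_of,
        party_of_unit=party_of_unit,
        party_of_male=party_of_male,
        primary_male_of_unit=primary_male_of_unit,
        secondary_males_of_unit=secondary_males_of_unit,
        transfer_schedule=transfers,
        config=config,
    )


def _draw_block_days(rng: np.random.Generator, mean: float) -> int:
    # >= 1 day; Poisson jitter around the configured mean.
    return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))


def simulate_states(
    truth: SocietyTruth, config: SocietyConfig | None = None
) -> dict[str, dict[int, ReproductiveState]]:
    """Daily reproductive states as a semi-Markov block chain.

    Chain: L -> C0 -> C1 -> C2 -> C3 -> (conceive? P : C0); P -> L.
    Each female starts in a random state with a fresh block.
    """
    config = config or truth.config
    config.validate()
    rng = _substream(config.seed, "states")
    out: dict[str, dict[int, ReproductiveState]] = {}
    order = [ReproductiveState.L, *CYCLE_STAGES, ReproductiveState.P]
    for female in truth.females:
        state = order[int(rng.integers(len(order)))]
        series: dict[int, ReproductiveState] = {}
        day = 1
        while day <= config.study_days:
            length = _draw_block_days(rng, config.state_mean_days[state])
            for d in range(day, min(day + length, config.study_days + 1)):
                series[d] = state
            day += length
            if state is ReproductiveState.L:
                state = ReproductiveState.C0
            elif state is ReproductiveState.P:
                state = ReproductiveState.L
            elif state is ReproductiveState.C3:
                state = (
                    ReproductiveState.P
                    if rng.random() < config.p_conceive_per_cycle
                    else ReproductiveState.C0
                )
            else:
                state = CYCLE_STAGES[CYCLE_STAGES.index(state) + 1]
        out[female] = series
    return out


_MORNING_SLOTS = [6 * 60 + 30 * k for k in range(13)]  # 06:00 .. 12:00
_AFTERNOON_SLOTS = [15 * 60 + 30 * k for k in range(8)]  # 15:00 .. 18:30
_FOCAL_SLOTS = _MORNING_SLOTS + _AFTERNOON_SLOTS


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _positive_poisson(rng: np.random.Generator, lam: float) -> int:
    """Poisson draw conditioned on being >= 1 (inverse-CDF on the tail)."""
    lam = max(lam, 1e-9)
    u = rng.random()
    # P(X >= 1) = 1 - exp(-lam); invert within the positive tail.
    target = np.exp(-lam) + u * (1.0 - np.exp(-lam))
    k, cdf, term = 0, np.exp(-lam), np.exp(-lam)
    while cdf < target and k < 1000:
        k += 1
        term *= lam / k
        cdf += term
    return max(k, 1)


class _EventFactory:
    def __init__(self) -> None:
        self.counter = 0

    def make(self, **kwargs) -> BehaviourEvent:
        self.counter += 1
        return BehaviourEvent(event_id=f"E{self.counter:06d}", **kwargs)


def simulate_observation(
    truth: SocietyTruth,
    states: Mapping[str, Mapping[int, ReproductiveState]],
    config: SocietyConfig | None = None,
) -> tuple[list[FocalSample], list[BehaviourEvent]]:
    """Generate focal samples (scans + events) and the ad libitum stream."""
    config = config or truth.config
    config.validate()
    rng = _substream(config.seed, "observation")
    factory = _EventFactory()

    males = sorted(
        ind.id for ind in truth.roster if ind.sex is Sex.MALE
    )
    focals: list[FocalSample] = []
    adlib: list[BehaviourEvent] = []

    def relation(female: str, male: str, day: int) -> str:
        if male == truth.primary_on(female, day):
            return "primary"
        if male in truth.secondaries_on(female, day):
            return "secondary"
        return "other"

    def maybe_surreptitious(female: str, male: str, day: int) -> bool:
        if relation(female, male, day) == "secondary":
            return bool(rng.random() < config.p_surreptitious_secondary)
        return False

    def pick_secondary(female: str, day: int) -> str | None:
        secs = sorted(truth.secondaries_on(female, day))
        if not secs:
            return None
        return secs[int(rng.integers(len(secs)))]

    def pick_non_primary(female: str, day: int) -> str | None:
        primary = truth.primary_on(female, day)
        pool = [m for m in males if m != primary]
        if not pool:
            return None
        return pool[int(rng.integers(len(pool)))]

    half_hour = 0.5  # focal duration in hours

    # ---- focal follows -------------------------------------------------
    for female in truth.females:
        week_starts = range(1, config.study_days + 1, 7)
        for week_start in week_starts:
            week_days = [d for d in range(week_start, min(week_start + 7, config.study_days + 1))]
            lo, hi = config.focals_per_female_per_week
            k = min(int(rng.integers(lo, hi + 1)), len(week_days))
            if k <= 0:
                continue
            days = sorted(rng.choice(week_days, size=k, replace=False).tolist())
            for day in days:
                start_minute = _FOCAL_SLOTS[int(rng.integers(len(_FOCAL_SLOTS)))]
                start = Timestamp(day=day, minute=start_minute)
                focal_id = f"{female}-d{day:03d}-{start.clock.replace(':', '')}"
                state = states[female][day]

                scans = []
                for i in range(4):
                    t = start.shifted(10 * i)
                    ring2, ring5 = set(), set()
                    for male in males:
                        rel = relation(female, male, day)
                        p2 = getattr(config, f"p2m_{rel}")
                        p5 = getattr(config, f"p5m_{rel}")
                        u = rng.random()
                        if u < p2:
                            ring2.add(male)
                        elif u < p2 + p5:
                            ring5.add(male)
                    scans.append(
                        ScanRecord(
                            focal_female=female, time=t,
                            males_2m=frozenset(ring2), males_5m=frozenset(ring5),
                            focal_id=focal_id,
                        )
                    )

                primary = truth.primary_on(female, day)
                events: list[BehaviourEvent] = []

                def ev_time() -> Timestamp:
                    return start.shifted(int(rng.integers(0, 31)))

                def add(etype: BehaviourType, male: str, *,
                        actor_is_male: bool, duration_s: float | None = None) -> None:
                    events.append(
                        factory.make(
                            type=etype,
                            actor=male if actor_is_male else female,
                            recipient=female if actor_is_male else male,
                            time=ev_time(),
                            duration_s=duration_s,
                            surreptitious=maybe_surreptitious(female, male, day),
                            protocol=Protocol.FOCAL,
                            focal_id=focal_id,
                        )
                    )

                # Greeting: occurrence from the state's logit, intensity
                # Poisson conditioned on occurrence.
                if rng.random() < _logistic(config.greet_logit_by_state[state]):
                    n_greet = _positive_poisson(rng, config.greet_rate_per_h * half_hour)
                    for _ in range(n_greet):
                        partner = primary
                        if rng.random() >= config.p_greet_primary:
                            partner = pick_secondary(female, day) or primary
                        add(BehaviourType.GREET, partner, actor_is_male=rng.random() < 0.5)

                # Grooming bouts per partner class; bout rate = min/h over
                # mean bout length.
                for rel, rate, mean_bout in (
                    ("primary", config.groom_rate_primary, config.groom_bout_mean_primary),
                    ("secondary", config.groom_rate_secondary, config.groom_bout_mean_secondary),
                ):
                    bout_rate = rate / mean_bout
                    for _ in range(int(rng.poisson(bout_rate * half_hour))):
                        partner = primary if rel == "primary" else pick_secondary(female, day)
                        if partner is None:
                            continue
                        duration = float(round(rng.exponential(mean_bout) * 60.0, 0)) + 1.0
                        add(BehaviourType.GROOM, partner,
                            actor_is_male=rng.random() < 0.24, duration_s=duration)

                for _ in range(int(rng.poisson(config.aggression_rate_per_h * half_hour))):
                    partner = primary
                    if rng.random() >= config.p_aggression_primary:
                        partner = pick_secondary(female, day) or primary
                    add(BehaviourType.AGGRESSION, partner, actor_is_male=rng.random() < 0.8)

                if state.tumescent:
                    for _ in range(int(rng.poisson(config.copulation_rate_per_h * half_hour))):
                        partner = primary
                        if rng.random() >= config.copulation_fidelity:
                            partner = pick_non_primary(female, day) or primary
                        add(BehaviourType.COPULATION, partner, actor_is_male=True)

                if state is ReproductiveState.L:
                    for _ in range(int(rng.poisson(config.infant_handling_rate_per_h * half_hour))):
                        partner = primary
                        if rng.random() >= config.p_infant_handling_primary:
                            partner = pick_secondary(female, day) or pick_non_primary(female, day) or primary
                        add(BehaviourType.INFANT_HANDLING, partner, actor_is_male=True)

                # Approach / retreat streams per affiliated partner.
                partners = [("primary", primary)] + [
                    ("secondary", s) for s in sorted(truth.secondaries_on(female, day))
                ]
                for rel, partner in partners:
                    p_app_male = getattr(config, f"p_approach_by_male_{rel}")
                    p_ret_female = getattr(config, f"p_retreat_by_female_{rel}")
                    for _ in range(int(rng.poisson(config.approach_rate_per_h * half_hour))):
                        add(BehaviourType.APPROACH, partner,
                            actor_is_male=rng.random() < p_app_male)
                    for _ in range(int(rng.poisson(config.retreat_rate_per_h * half_hour))):
                        add(BehaviourType.RETREAT, partner,
                            actor_is_male=rng.random() >= p_ret_female)

                events.sort(key=lambda e: (e.time, e.event_id))
                focals.append(
                    FocalSample(
                        focal_id=focal_id, focal_female=female, start_time=start,
                        state=state, scans=tuple(scans), events=tuple(events),
                    )
                )

    # ---- ad libitum stream (covers all days) ---------------------------
    adlib_types = [BehaviourType.GROOM, BehaviourType.GREET, BehaviourType.AGGRESSION]
    for day in range(1, config.study_days + 1):
        for female in truth.females:
            primary = truth.primary_on(female, day)
            state = states[female][day]

            def adlib_event(etype: BehaviourType, partner: str) -> BehaviourEvent:
                minute = int(rng.integers(6 * 60, 19 * 60))
                duration = None
                if etype is BehaviourType.GROOM:
                    duration = float(round(rng.exponential(config.groom_bout_mean_primary) * 60.0, 0)) + 1.0
                actor_is_male = rng.random() < 0.5
                return factory.make(
                    type=etype,
                    actor=partner if actor_is_male else female,
                    recipient=female if actor_is_male else partner,
                    time=Timestamp(day=day, minute=minute),
                    duration_s=duration,
                    surreptitious=maybe_surreptitious(female, partner, day),
                    protocol=Protocol.AD_LIBITUM,
                )

            for _ in range(int(rng.poisson(config.adlib_primary_events_per_day))):
                etype = adlib_types[int(rng.integers(len(adlib_types)))]
                adlib.append(adlib_event(etype, primary))
            for _ in range(int(rng.poisson(config.adlib_secondary_events_per_day))):
                partner = pick_secondary(female, day)
                if partner is None:
                    continue
                etype = adlib_types[int(rng.integers(len(adlib_types)))]
                adlib.append(adlib_event(etype, partner))
            if state.tumescent:
                for _ in range(int(rng.poisson(config.adlib_copulations_per_tumescent_day))):
                    partner = primary
                    if rng.random() >= config.copulation_fidelity:
                        partner = pick_non_primary(female, day) or primary
                    adlib.append(adlib_event(BehaviourType.COPULATION, partner))

    adlib.sort(key=lambda e: (e.time, e.event_id))
    return focals, adlib


def simulate_study(
    config: SocietyConfig,
) -> tuple[SocietyTruth, dict[str, dict[int, ReproductiveState]], list[FocalSample], list[BehaviourEvent]]:
    """Convenience wrapper chaining the three simulation stages."""
    truth = simulate_society(config)
    states = simulate_states(truth, config)
    focals, adlib = simulate_observation(truth, states, config)
    return truth, states, focals, adlib
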