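import math
from dataclasses import replace

import numpy as np
import pytest

from proxsoc.errors import ConfigurationError
from proxsoc.records import BehaviourType, ReproductiveState, Sex
from proxsoc.simulate import (
    SocietyConfig,
    simulate_observation,
    simulate_society,
    simulate_states,
    simulate_study,
)

L, P = ReproductiveState.L, ReproductiveState.P
C0, C1, C2, C3 = (ReproductiveState.C0, ReproductiveState.C1,
                  ReproductiveState.C2, ReproductiveState.C3)

ALLOWED_TRANSITIONS = {
    L: {C0}, C0: {C1}, C1: {C2}, C2: {C3}, C3: {C0, P}, P: {L},
}


class TestConfig:
    def test_default_config_valid(self):
        SocietyConfig().validate()

    @pytest.mark.parametrize("kwargs", [
        {"p2m_primary": 1.2},
        {"copulation_fidelity": -0.1},
        {"females_per_unit": (3, 1)},
        {"females_per_unit": (0, 2)},
        {"study_days": 0},
        {"groom_rate_primary": -1.0},
        {"p2m_primary": 0.7, "p5m_primary": 0.5},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SocietyConfig(**kwargs).validate()


class TestSociety:
    def test_structure_within_ranges(self):
        config = SocietyConfig(seed=1)
        truth = simulate_society(config)
        parties = set(truth.party_of_unit.values())
        assert len(parties) == 3
        # initial units respect the configured composition ranges
        females_per_unit = {}
        for female, unit in truth.unit_of.items():
            females_per_unit[unit] = females_per_unit.get(unit, 0) + 1
        for unit, n in females_per_unit.items():
            assert 1 <= n <= 4
        for unit, secs in truth.secondary_males_of_unit.items():
            assert 0 <= len(secs) <= 2

    def test_one_primary_male_per_unit_at_all_times(self):
        config = SocietyConfig(seed=3)
        truth = simulate_society(config)
        for female in truth.females:
            for day in (1, 100, 300, 507):
                primary = truth.primary_on(female, day)
                unit = truth.unit_on(female, day)
                assert truth.primary_male_of_unit[unit] == primary

    def test_zero_hazard_means_constant_primary(self):
        config = SocietyConfig(seed=2, transfer_hazard_per_fortnight=0.0)
        truth = simulate_society(config)
        assert truth.transfer_schedule == []
        for female in truth.females:
            primaries = {truth.primary_on(female, d) for d in range(1, 508, 20)}
            assert len(primaries) == 1

    def test_deterministic(self):
        config = SocietyConfig(seed=9)
        a, b = simulate_society(config), simulate_society(config)
        assert a.roster == b.roster
        assert a.unit_of == b.unit_of
        assert a.transfer_schedule == b.transfer_schedule

    def test_transfers_never_to_own_secondary(self):
        config = SocietyConfig(seed=5, transfer_hazard_per_fortnight=0.2)
        truth = simulate_society(config)
        assert truth.transfer_schedule  # hazard high enough to see some
        for tr in truth.transfer_schedule:
            secs_before = truth.secondary_males_of_unit[
                [u for u, m in truth.primary_male_of_unit.items() if m == tr.old_male][0]
            ]
            assert tr.new_male not in secs_before
            assert tr.old_male != tr.new_male

    def test_infeasible_range_raises(self):
        with pytest.raises(ConfigurationError):
            simulate_society(SocietyConfig(units_per_party=(0, 0)))


class TestStates:
    def test_chain_never_skips_stages(self):
        config = SocietyConfig(seed=4)
        truth = simulate_society(config)
        states = simulate_states(truth, config)
        for female, series in states.items():
            for day in range(1, config.study_days):
                cur, nxt = series[day], series[day + 1]
                if cur != nxt:
                    assert nxt in ALLOWED_TRANSITIONS[cur], (female, day, cur, nxt)

    def test_covers_every_study_day(self):
        config = SocietyConfig(seed=4, study_days=123)
        truth = simulate_society(config)
        states = simulate_states(truth, config)
        for series in states.values():
            assert set(series) == set(range(1, 124))

    def test_equal_block_lengths_give_uniform_frequencies(self):
        # one female, 10^5 days, all means equal, conception certain:
        # every macro-cycle visits each state once -> ~1/6 each
        mean_days = {s: 5.0 for s in ReproductiveState}
        config = SocietyConfig(
            seed=6, n_parties=1, units_per_party=(1, 1), females_per_unit=(1, 1),
            secondary_males_per_unit=(0, 0), n_bachelors=0,
            study_days=100_000, state_mean_days=mean_days, p_conceive_per_cycle=1.0,
            transfer_hazard_per_fortnight=0.0,
        )
        truth = simulate_society(config)
        states = simulate_states(truth, config)
        series = next(iter(states.values()))
        counts = {s: 0 for s in ReproductiveState}
        for state in series.values():
            counts[state] += 1
        total = sum(counts.values())
        for s, c in counts.items():
            # Monte-Carlo tolerance: block bootstrap scale ~ sqrt(blocks)
            assert abs(c / total - 1 / 6) < 0.02, (s, c / total)

    def test_seed_reproducible(self):
        config = SocietyConfig(seed=8)
        truth = simulate_society(config)
        assert simulate_states(truth, config) == simulate_states(truth, config)


class TestObservation:
    def test_degenerate_probabilities_pin_primary(self):
        config = SocietyConfig(
            seed=2, study_days=28,
            p2m_primary=1.0, p2m_secondary=0.0, p2m_other=0.0,
            p5m_primary=0.0, p5m_secondary=0.0, p5m_other=0.0,
            transfer_hazard_per_fortnight=0.0,
        )
        truth = simulate_society(config)
        states = simulate_states(truth, config)
        focals, _ = simulate_observation(truth, states, config)
        assert focals
        for f in focals:
            primary = truth.primary_on(f.focal_female, f.start_time.day)
            for scan in f.scans:
                assert scan.males_2m == frozenset({primary})
                assert scan.males_5m == frozenset()

    def test_full_fidelity_copulations_only_with_primary(self):
        config = SocietyConfig(seed=3, study_days=120, copulation_fidelity=1.0,
                               transfer_hazard_per_fortnight=0.0)
        truth = simulate_society(config)
        states = simulate_states(truth, config)
        focals, adlib = simulate_observation(truth, states, config)
        cops = [e for f in focals for e in f.events
                if e.type is BehaviourType.COPULATION]
        cops += [e for e in adlib if e.type is BehaviourType.COPULATION]
        assert cops
        females = set(truth.females)
        for ev in cops:
            female = next(iter(ev.participants() & females))
            male = next(iter(ev.participants() - {female}))
            assert male == truth.primary_on(female, ev.time.day)

    def test_copulations_only_while_tumescent(self, default_sim):
        config, truth, states, focals, adlib = default_sim
        for f in focals:
            if any(e.type is BehaviourType.COPULATION for e in f.events):
                assert f.state.tumescent
        females = set(truth.females)
        for ev in adlib:
            if ev.type is BehaviourType.COPULATION:
                female = next(iter(ev.participants() & females))
                assert states[female][ev.time.day].tumescent

    def test_four_scans_at_ten_minute_spacing(self, default_sim):
        config, truth, states, focals, adlib = default_sim
        for f in focals[:200]:
            assert len(f.scans) == 4
            for i, scan in enumerate(f.scans):
                assert scan.time == f.start_time.shifted(10 * i)

    def test_greeting_occurrence_matches_logistic_for_lactating(self):
        # Monte-Carlo vs closed form: logistic(-1.442) ~ 0.1911
        config = SocietyConfig(seed=12, study_days=507,
                               focals_per_female_per_week=(3, 3),
                               transfer_hazard_per_fortnight=0.0)
        truth = simulate_society(config)
        states = simulate_states(truth, config)
        focals, _ = simulate_observation(truth, states, config)
        lact = [f for f in focals if f.state is ReproductiveState.L]
        occ = [any(e.type is BehaviourType.GREET for e in f.events) for f in lact]
        n = len(occ)
        assert n > 500
        p_hat = sum(occ) / n
        p_true = 1 / (1 + math.exp(1.442))
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_hat - p_true) < 3 * se, (p_hat, p_true, n)

    def test_primary_2m_frequency_converges(self, default_sim):
        # law of large numbers at >= 10^4 scans
        config, truth, states, focals, adlib = default_sim
        scans = [s for f in focals for s in f.scans]
        hits = total = 0
        for f in focals:
            primary = truth.primary_on(f.focal_female, f.start_time.day)
            for scan in f.scans:
                total += 1
                hits += primary in scan.males_2m
        assert total >= 8000
        se = math.sqrt(config.p2m_primary * (1 - config.p2m_primary) / total)
        assert abs(hits / total - config.p2m_primary) < 4 * se

    def test_deterministic(self):
        config = SocietyConfig(seed=21, study_days=42)
        a = simulate_study(config)
        b = simulate_study(config)
        assert a[2] == b[2]  # focal samples identical
        assert a[3] == b[3]  # ad libitum stream identical

    def test_surreptitious_only_for_secondary_partners(self, default_sim):
        config, truth, states, focals, adlib = default_sim
        females = set(truth.females)
        for ev in list(adlib)[:2000]:
            if ev.surreptitious:
                female = next(iter(ev.participants() & females))
                male = next(iter(ev.participants() - {female}))
                assert male in truth.secondaries_on(female, ev.time.day)
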