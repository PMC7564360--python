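import numpy as np
import pytest

from spovsim import load_config
from spovsim.micro import (
    RefFemale,
    RefMale,
    make_micro_fixture,
    population_from_individuals,
    reference_run_season,
)
from spovsim.population import initialize_generation
from spovsim.season import (
    attack_decision,
    daily_intake,
    escape_probability,
    resolve_attack,
    run_season,
)


class TestEscapeProbability:
    def test_zero_size_always_escapes(self):
        assert escape_probability(0.0) == 1.0

    def test_printed_value(self):
        assert escape_probability(6.408) == pytest.approx(0.527, abs=0.001)

    def test_monotone_decreasing(self):
        grid = np.linspace(0, 12, 30)
        values = [escape_probability(c) for c in grid]
        assert np.all(np.diff(values) < 0)


class TestAttackDecision:
    def test_spillover_attacks_regardless_of_state(self, rng):
        draws = [
            attack_decision(
                spillover_rule=True, mated=True, satiated=True, pspov=0.9, rng=rng
            )
            for _ in range(2000)
        ]
        assert 0.85 < np.mean(draws) < 0.95

    def test_mfcl_satiated_virgin_never_attacks(self, rng):
        assert not attack_decision(
            spillover_rule=False, mated=False, satiated=True, pspov=0.9, rng=rng
        )

    def test_mfcl_mated_always_attacks(self, rng):
        assert attack_decision(
            spillover_rule=False, mated=True, satiated=True, pspov=0.9, rng=rng
        )

    def test_mfcl_hungry_virgin_attacks(self, rng):
        assert attack_decision(
            spillover_rule=False, mated=False, satiated=False, pspov=0.9, rng=rng
        )

    def test_mated_only_rule_drops_satiation_clause(self, rng):
        assert not attack_decision(
            spillover_rule=False, mated=False, satiated=False, pspov=0.9, rng=rng,
            mfcl_attack_rule="mated_only",
        )


class TestResolveAttack:
    def _tiny_population(self, condition, maxcond, satiated=False):
        f = RefFemale(
            allele_1=1, allele_2=1, phenotype=1, mat_day=1, cw=6.0,
            condition=condition, maxcond=maxcond, mort=0.0, intake=0.0,
            attack_spillover=True, satiated=satiated,
        )
        return population_from_individuals([f], [RefMale(allele=0, mat_day=1)])

    def test_meal_gain_capped_at_threshold(self):
        cfg = load_config({})
        pop = self._tiny_population(condition=7.5, maxcond=8.7)
        rng = np.random.default_rng(0)
        while True:  # find a kill draw
            pop2 = self._tiny_population(condition=7.5, maxcond=8.7)
            if resolve_attack(0, 0, pop2, cfg, rng) == "male_eaten":
                pop = pop2
                break
        assert pop.females.condition[0] == pytest.approx(8.7)  # capped, not 9.89
        assert pop.females.satiated[0]
        assert pop.females.kills[0] == 1
        assert not pop.males.alive[0]

    def test_uncapped_gain_is_2_39(self):
        cfg = load_config({})
        rng = np.random.default_rng(0)
        while True:
            pop = self._tiny_population(condition=3.0, maxcond=8.7)
            if resolve_attack(0, 0, pop, cfg, rng) == "male_eaten":
                break
        assert pop.females.condition[0] == pytest.approx(3.0 + 2.39)

    def test_satiated_female_gains_nothing(self):
        cfg = load_config({})
        rng = np.random.default_rng(0)
        while True:
            pop = self._tiny_population(condition=8.7, maxcond=8.7, satiated=True)
            if resolve_attack(0, 0, pop, cfg, rng) == "male_eaten":
                break
        assert pop.females.condition[0] == pytest.approx(8.7)
        assert not pop.males.alive[0]


class TestDailyIntake:
    def test_mean_scales_with_multiplier_and_environment(self, rng):
        draws = np.array([daily_intake(1.5, 0.0741, rng) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(1.5 * 0.0741 * 0.5, rel=0.05)
        assert draws.max() <= 1.5 * 0.0741


class TestSeasonInvariants:
    def _run(self, config, seed=5):
        rng = np.random.default_rng(seed)
        pop = initialize_generation(config, rng)
        start_cond = pop.females.condition.copy()
        out = run_season(pop, config, rng)
        return pop, out, start_cond

    def test_male_bookkeeping_conserves(self, small_config):
        pop, out, _ = self._run(small_config)
        assert (
            pop.males.n
            == pop.males.alive.sum() + out.male_background_deaths + out.males_cannibalized
        )
        assert out.males_cannibalized == pop.females.kills.sum()

    def test_condition_nondecreasing_and_capped(self, small_config):
        pop, out, start = self._run(small_config)
        assert np.all(pop.females.condition >= start - 1e-12)
        # the cap applies to every female except those born above their own
        # threshold (degenerate draws, marked satiated at entry)
        regular = start <= pop.females.maxcond
        assert np.all(pop.females.condition[regular] <= pop.females.maxcond[regular] + 1e-9)
        # degenerate females never feed, so their condition is unchanged
        assert np.allclose(pop.females.condition[~regular], start[~regular])

    def test_satiation_is_absorbing_at_threshold(self, small_config):
        pop, out, start = self._run(small_config)
        regular = start <= pop.females.maxcond
        sat = pop.females.satiated & regular
        assert np.all(pop.females.condition[sat] <= pop.females.maxcond[sat] + 1e-9)
        # any female at her threshold is flagged satiated
        at_threshold = np.isclose(pop.females.condition, pop.females.maxcond)
        assert np.all(pop.females.satiated[at_threshold])

    def test_every_mated_female_has_father_allele(self, small_config):
        pop, out, _ = self._run(small_config)
        mated = pop.females.mated
        assert np.all(pop.females.father_allele[mated] >= 0)
        assert np.all(pop.females.father_allele[~mated] == -1)

    def test_no_cannibalism_when_no_attack_rules_fire(self):
        # spillover rule disabled via pspov=0 and the MFCL rule neutralized by
        # the mated_only alternative (no female is mated at season start)
        cfg = load_config(
            {
                "environment": {"richness": "rich", "pspov": 0.0},
                "mfcl_attack_rule": "mated_only",
                "n_females": 60,
                "n_males": 60,
            }
        )
        # no remating: females mate once, and mated females under mated_only
        # do attack -- but each female mates before ever attacking, so the
        # only cannibalism path is a mated female's later attack; count only
        # pre-mating deaths by asserting kills happen only for mated females
        rng = np.random.default_rng(11)
        pop = initialize_generation(cfg, rng)
        out = run_season(pop, cfg, rng)
        killers = pop.females.kills > 0
        assert np.all(pop.females.mated[killers])

    def test_male_background_mortality_closed_form(self):
        # males only: deaths over 79 days follow 1 - (1 - 0.0045)^79 ~ 0.30
        cfg = load_config({"n_females": 1, "n_males": 400})
        males = [RefMale(allele=0, mat_day=0) for _ in range(400)]
        pop = population_from_individuals([], males)
        rng = np.random.default_rng(17)
        out = run_season(pop, cfg, rng)
        expected = 1 - (1 - 0.0045) ** 79
        dead_frac = out.male_background_deaths / 400
        se = np.sqrt(expected * (1 - expected) / 400)
        assert abs(dead_frac - expected) < 4 * se
        assert out.males_cannibalized == 0


class TestMicroOracle:
    @pytest.mark.parametrize("n_males, n_females, days, seed", [
        (2, 2, 3, 7),
        (3, 3, 5, 123),
        (5, 4, 4, 2024),
        (1, 5, 5, 99),
    ])
    def test_engine_trace_equals_reference(self, n_males, n_females, days, seed):
        """The compiled engine and the per-individual reference implementation
        consume one RNG stream identically, so their event traces match."""
        cfg, females, males, expected = make_micro_fixture(n_males, n_females, days, seed)
        pop = population_from_individuals(females, males)
        out = run_season(pop, cfg, np.random.default_rng(seed), log_events=True)
        assert out.events.equals(expected)

    def test_trace_equality_with_alternative_rules(self):
        cfg, females, males, _ = make_micro_fixture(4, 4, 5, 31)
        cfg = cfg.replace(
            cohab_order="mate_first", withdrawal="gravid",
            satiated_attacks_lethal=True, encounter_model="thinned",
        )
        expected = reference_run_season(
            [RefFemale(**f.__dict__) for f in females],
            [RefMale(**m.__dict__) for m in males],
            cfg,
            np.random.default_rng(31),
        )
        pop = population_from_individuals(females, males)
        out = run_season(pop, cfg, np.random.default_rng(31), log_events=True)
        got = list(out.events.itertuples(index=False, name=None))
        assert got == expected

    def test_no_males_no_encounters(self):
        cfg, females, males, expected = make_micro_fixture(0, 2, 3, 5)
        assert males == []
        assert set(expected.event) <= {"female_background_death"}

    def test_full_season_end_state_matches_reference(self, small_config):
        """Beyond event traces: end-of-season state agrees on a larger cohort."""
        rng = np.random.default_rng(77)
        pop = initialize_generation(small_config, rng)
        f, m = pop.females, pop.males
        ref_females = [
            RefFemale(
                allele_1=int(f.allele_1[i]), allele_2=int(f.allele_2[i]),
                phenotype=int(f.phenotype[i]), mat_day=int(f.mat_day[i]),
                cw=float(f.cw[i]), condition=float(f.condition[i]),
                maxcond=float(f.maxcond[i]), mort=float(f.mort[i]),
                intake=float(f.intake[i]), attack_spillover=bool(f.attack_spillover[i]),
                satiated=bool(f.satiated[i]),
            )
            for i in range(f.n)
        ]
        ref_males = [RefMale(allele=int(m.allele[j]), mat_day=int(m.mat_day[j])) for j in range(m.n)]
        seed = np.random.default_rng(123)
        run_season(pop, small_config, seed)
        reference_run_season(ref_females, ref_males, small_config, np.random.default_rng(123))
        assert np.array_equal(pop.females.mated, [rf.mated for rf in ref_females])
        assert np.array_equal(pop.females.alive, [rf.alive for rf in ref_females])
        assert np.array_equal(pop.males.alive, [rm.alive for rm in ref_males])
        assert np.allclose(pop.females.condition, [rf.condition for rf in ref_females])
        assert np.array_equal(pop.females.kills, [rf.kills for rf in ref_females])
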