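"""Straightforward per-individual reference implementation of the daily
season rules, plus a generator for tiny deterministic test scenarios.

This module re-implements the season loop of :mod:`spovsim.season` in the
most literal way possible: one Python object per spider, explicit daily
steps, no arrays and no compilation.  It consumes scalar RNG draws in the
documented protocol order, so running it and the compiled engine from the
same seed must produce identical event traces — which the test suite uses
as an exhaustive cross-check on small scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import SimulationConfig, load_config
from .population import Females, Males, Population

__all__ = ["RefFemale", "RefMale", "reference_run_season", "make_micro_fixture",
           "population_from_individuals"]


@dataclass
class RefFemale:
    allele_1: int
    allele_2: int
    phenotype: int  # 1 spillover, 0 mfcl
    mat_day: int
    cw: float
    condition: float
    maxcond: float
    mort: float
    intake: float
    attack_spillover: bool
    satiated: bool = False
    mated: bool = False
    father_allele: int = -1
    resident: int = -1
    alive: bool = True
    kills: int = 0


@dataclass
class RefMale:
    allele: int
    mat_day: int
    alive: bool = True
    cohabiting_with: int = -1
    matings: int = 0


def _attacks(female: RefFemale, pspov: float, mated_only: bool, rng) -> bool:
    if female.attack_spillover:
        return rng.random() < pspov
    if mated_only:
        return female.mated
    return female.mated or not female.satiated


def _feed_on_male(female: RefFemale, meal_gain: float) -> None:
    female.kills += 1
    if not female.satiated:
        female.condition = min(female.condition + meal_gain, female.maxcond)
        if female.condition >= female.maxcond:
            female.satiated = True


def reference_run_season(
    females: list[RefFemale],
    males: list[RefMale],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[int, str, int, int]]:
    """Run the daily rules step by step; return the event trace.

    Events are ``(day, name, male_id, female_id)`` tuples with -1 for a
    missing side, matching the compiled engine's optional event log.
    """
    env = config.environment
    mated_only = config.mfcl_attack_rule == "mated_only"
    mate_first = config.cohab_order == "mate_first"
    events: list[tuple[int, str, int, int]] = []

    def eligible_now(f: RefFemale, day: int) -> bool:
        if not (f.alive and f.mat_day <= day):
            return False
        if config.withdrawal == "gravid":
            return not (f.mated and f.satiated)
        if config.withdrawal == "satiated":
            return not f.satiated
        return True

    for day in range(config.season_length):
        # background mortality: females then males, by index
        for i, f in enumerate(females):
            if f.alive and f.mat_day <= day and rng.random() < f.mort:
                f.alive = False
                if f.resident >= 0:
                    males[f.resident].cohabiting_with = -1
                    f.resident = -1
                events.append((day, "female_background_death", -1, i))
        for j, m in enumerate(males):
            if m.alive and m.mat_day <= day and rng.random() < config.male_mortality_rate:
                m.alive = False
                if m.cohabiting_with >= 0:
                    females[m.cohabiting_with].resident = -1
                    m.cohabiting_with = -1
                events.append((day, "male_background_death", j, -1))

        # feeding
        for f in females:
            if f.alive and f.mat_day <= day and not f.satiated:
                f.condition += rng.random() * f.intake
                if f.condition >= f.maxcond:
                    f.condition = f.maxcond
                    f.satiated = True

        # eligibility is frozen at this point of the day, matching the
        # compiled engine (a mid-search satiation does not remove a female
        # from the day's encounter pool)
        eligible = [i for i, f in enumerate(females) if eligible_now(f, day)]
        eligible_set = set(eligible)

        # male search
        if eligible:
            for j, m in enumerate(males):
                if not m.alive or m.mat_day > day or m.cohabiting_with >= 0:
                    continue
                n_enc = env.maxenc
                if config.encounter_model == "poisson":
                    limit = math.exp(-env.maxenc)
                    n_enc, prod = 0, rng.random()
                    while prod > limit:
                        prod *= rng.random()
                        n_enc += 1
                elif config.encounter_model == "thinned":
                    frac = len(eligible) / len(females)
                    n_enc = sum(rng.random() < frac for _ in range(env.maxenc))
                n_enc = min(n_enc, len(eligible))
                visited: list[int] = []
                for _ in range(n_enc):
                    while True:
                        i = int(rng.integers(0, len(females)))
                        f = females[i]
                        if i in eligible_set and i not in visited:
                            break
                    visited.append(i)
                    if f.resident >= 0:
                        events.append((day, "male_turned_away", j, i))
                        continue
                    if not f.mated and not config.approach_attack_virgins:
                        f.resident = j
                        m.cohabiting_with = i
                        events.append((day, "residency_start", j, i))
                        break
                    if _attacks(f, env.pspov, mated_only, rng):
                        if f.satiated and not config.satiated_attacks_lethal:
                            events.append((day, "male_escaped_attack", j, i))
                            break
                        if rng.random() < math.exp(-config.escape_coeff * f.cw):
                            events.append((day, "male_escaped_attack", j, i))
                            break
                        m.alive = False
                        _feed_on_male(f, config.male_meal_gain)
                        events.append((day, "male_cannibalized", j, i))
                        break
                    if not f.mated:
                        f.resident = j
                        m.cohabiting_with = i
                        events.append((day, "residency_start", j, i))
                        break
                    # rebuffed by a mated, non-attacking female: keep searching

        # cohabitation, by female index (pairs formed today included)
        for i, f in enumerate(females):
            j = f.resident
            if j < 0:
                continue
            m = males[j]
            if mate_first and rng.random() < config.pmate:
                f.mated = True
                f.father_allele = m.allele
                m.matings += 1
                f.resident = -1
                m.cohabiting_with = -1
                events.append((day, "mating", j, i))
                continue
            if _attacks(f, env.pspov, mated_only, rng):
                if f.satiated and not config.satiated_attacks_lethal:
                    f.resident = -1
                    m.cohabiting_with = -1
                    events.append((day, "male_escaped_cohabitation_attack", j, i))
                elif rng.random() < math.exp(-config.escape_coeff * f.cw):
                    f.resident = -1
                    m.cohabiting_with = -1
                    events.append((day, "male_escaped_cohabitation_attack", j, i))
                else:
                    m.alive = False
                    _feed_on_male(f, config.male_meal_gain)
                    f.resident = -1
                    m.cohabiting_with = -1
                    events.append((day, "male_cannibalized_in_cohabitation", j, i))
            elif not mate_first:
                if rng.random() < config.pmate:
                    f.mated = True
                    f.father_allele = m.allele
                    m.matings += 1
                    f.resident = -1
                    m.cohabiting_with = -1
                    events.append((day, "mating", j, i))
    return events


def population_from_individuals(
    females: list[RefFemale], males: list[RefMale]
) -> Population:
    """Pack per-individual states into the array cohort the engine runs on."""
    fem = Females(
        allele_1=np.array([f.allele_1 for f in females], np.int8),
        allele_2=np.array([f.allele_2 for f in females], np.int8),
        phenotype=np.array([f.phenotype for f in females], np.int8),
        mat_day=np.array([f.mat_day for f in females], np.int64),
        cw=np.array([f.cw for f in females], float),
        condition=np.array([f.condition for f in females], float),
        maxcond=np.array([f.maxcond for f in females], float),
        satiated=np.array([f.satiated for f in females], bool),
        mated=np.array([f.mated for f in females], bool),
        father_allele=np.array([f.father_allele for f in females], np.int8),
        resident=np.array([f.resident for f in females], np.int64),
        alive=np.array([f.alive for f in females], bool),
        kills=np.array([f.kills for f in females], np.int64),
        mort=np.array([f.mort for f in females], float),
        intake=np.array([f.intake for f in females], float),
        attack_spillover=np.array([int(f.attack_spillover) for f in females], np.int8),
    )
    mal = Males(
        allele=np.array([m.allele for m in males], np.int8),
        mat_day=np.array([m.mat_day for m in males], np.int64),
        alive=np.array([m.alive for m in males], bool),
        cohabiting_with=np.array([m.cohabiting_with for m in males], np.int64),
        matings=np.array([m.matings for m in males], np.int64),
    )
    return Population(females=fem, males=mal)


def make_micro_fixture(
    n_males: int,
    n_females: int,
    days: int,
    seed: int,
    environment: str = "rich",
) -> tuple[SimulationConfig, list[RefFemale], list[RefMale], pd.DataFrame]:
    """Build a tiny deterministic scenario and its expected event trace.

    Returns ``(config, females, males, expected_events)`` where the
    individuals have hand-chosen attributes (all mature from day 1, fixed
    CW of 6.0 mm, alternating MFCL / spillover phenotypes, alternating
    alleles) and ``expected_events`` is the trace of the reference
    implementation run from ``seed``.  The compiled engine run on the same
    cohort and seed must reproduce the trace exactly.
    """
    if n_males > 5 or n_females > 5 or days > 5:
        raise ValueError("micro fixtures are capped at 5 individuals per sex and 5 days")
    cfg = load_config(
        {
            "environment": environment,
            "strategy_pair": ["EARLY-SPOV", "MFCL"],
            "n_females": max(n_females, 1),
            "n_males": max(n_males, 1),
            "season_length": days,
            "seed": seed,
        }
    )
    cw = 6.0
    maxcond = -38.98 + 11.73 * cw - 0.63 * cw * cw
    females = [
        RefFemale(
            allele_1=i % 2,
            allele_2=(i + 1) % 2 if i % 3 == 0 else i % 2,
            phenotype=i % 2,
            mat_day=1,
            cw=cw,
            condition=5.0,
            maxcond=maxcond,
            mort=cfg.female_mortality(bool(i % 2)),
            intake=cfg.environment.intake_scale
            * (cfg.spillover_strategy if i % 2 else cfg.mfcl_strategy).intake_multiplier,
            attack_spillover=bool(i % 2),
        )
        for i in range(n_females)
    ]
    males = [RefMale(allele=j % 2, mat_day=1) for j in range(n_males)]

    trace = reference_run_season(
        [replace(f) for f in females],
        [replace(m) for m in males],
        cfg,
        np.random.default_rng(seed),
    )
    expected = pd.DataFrame(trace, columns=["day", "event", "male_id", "female_id"])
    return cfg, females, males, expected
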