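"""The 79-day within-season daily loop: maturation, mortality, feeding,
male search, cohabitation, attack/escape/cannibalism and mating.

Each season day ``d`` (0-based; an individual is mature once
``maturation_day <= d``) proceeds in a fixed order:

1. **Maturation entry** — implicit via the maturity test.
2. **Background mortality** — every mature, living female (by index order),
   then every mature, living male, dies with its daily rate; a dying partner
   releases any cohabitation pair.
3. **Feeding** — each mature, living, unsatiated female gains
   U(0,1) * intake (mm); condition is capped at maxCOND_f, where satiation
   becomes absorbing.
4. **Male search** — each mature, living, non-cohabiting male (by index
   order) approaches up to ``maxenc`` distinct living mature females drawn
   uniformly at random (rejection sampling).  A female with a resident male
   turns the newcomer away.  Otherwise the female decides whether to attack:
   spillover females attack with probability ``pspov`` regardless of state;
   MFCL females attack (probability 1) iff mated or not satiated.  An attack
   by an *unsatiated* female is lethal unless the male escapes (probability
   exp(-escape_coeff * CW)); a kill raises her condition by
   ``male_meal_gain`` (capped at the satiation threshold).  A satiated
   female no longer feeds, so by default her attack drives the male off
   unharmed (``satiated_attacks_lethal`` restores the lethal reading).
   Either way an attacked male is done searching for the day.  If the female
   does not attack and is unmated, the male takes residency and stops
   searching.
5. **Cohabitation** — every resident pair (by female index, including pairs
   formed earlier the same day): the attack decision is taken first
   (``cohab_order="mate_first"`` swaps the order); if no attack, mating
   occurs with probability ``pmate`` — the female records the male's allele,
   the male departs alive and may search again the next day.

RNG draw protocol
-----------------
All stochastic decisions consume scalar draws from a single
``numpy.random.Generator`` in exactly the order the steps above are listed
(within a step, index order; within an encounter: target index via rejected
``integers(0, n_females)`` draws, then the attack draw if the rule is
probabilistic, then the escape draw if the attack is lethal, then the mating
draw during cohabitation).  Day-start encounter eligibility is frozen before
the search step.  The pure-Python reference engine in :mod:`spovsim.micro`
follows the same protocol, which makes engine-vs-oracle traces comparable
draw for draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._core import run_season_core
from .config import SimulationConfig
from .population import Population

__all__ = ["EVENT_CODES", "EVENT_NAMES", "SeasonOutcome", "attack_decision",
           "escape_probability", "resolve_attack", "daily_intake", "run_season"]

#: event codes written to the optional per-day event log
EVENT_CODES = {
    "female_background_death": 1,
    "male_background_death": 2,
    "male_turned_away": 3,  # approached female already has a resident
    "male_escaped_attack": 4,
    "male_cannibalized": 5,
    "residency_start": 6,
    "male_escaped_cohabitation_attack": 7,
    "male_cannibalized_in_cohabitation": 8,
    "mating": 9,
}
EVENT_NAMES = {v: k for k, v in EVENT_CODES.items()}


def escape_probability(cw: float, escape_coeff: float = 0.1) -> float:
    """P(male escapes an attack) = exp(-escape_coeff * CW); decreasing in CW."""
    if cw < 0:
        raise ValueError(f"CW must be >= 0, got {cw}")
    return float(np.exp(-escape_coeff * cw))


def attack_decision(
    *,
    spillover_rule: bool,
    mated: bool,
    satiated: bool,
    pspov: float,
    rng: np.random.Generator,
    mfcl_attack_rule: str = "literal",
) -> bool:
    """Whether a female attacks an approaching (or cohabiting) male.

    Spillover-family females attack with probability ``pspov`` regardless of
    mating or satiation status (one RNG draw).  MFCL females attack
    deterministically iff mated or not satiated (``"literal"`` rule; the
    ``"mated_only"`` alternative drops the satiation clause).
    """
    if spillover_rule:
        return rng.random() < pspov
    if mfcl_attack_rule == "mated_only":
        return bool(mated)
    return bool(mated or not satiated)


def resolve_attack(
    female_idx: int,
    male_idx: int,
    population: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> str:
    """Resolve a single attack: ``"male_escaped"`` or ``"male_eaten"``.

    On a kill the female's condition rises by ``male_meal_gain`` mm, capped at
    her satiation threshold (no gain if already satiated), and any
    cohabitation with that male ends.  Scalar companion to the compiled
    season loop, used for unit-level checks.
    """
    f, m = population.females, population.males
    if rng.random() < escape_probability(f.cw[female_idx], config.escape_coeff):
        return "male_escaped"
    m.alive[male_idx] = False
    f.kills[female_idx] += 1
    if not f.satiated[female_idx]:
        f.condition[female_idx] = min(
            f.condition[female_idx] + config.male_meal_gain, f.maxcond[female_idx]
        )
        if f.condition[female_idx] >= f.maxcond[female_idx]:
            f.satiated[female_idx] = True
    if m.cohabiting_with[male_idx] == female_idx:
        m.cohabiting_with[male_idx] = -1
        f.resident[female_idx] = -1
    return "male_eaten"


def daily_intake(
    intake_multiplier: float,
    intake_scale: float,
    rng: np.random.Generator,
) -> float:
    """One day's condition increment: U(0,1) * intake_scale * intake_multiplier (mm)."""
    return rng.random() * intake_scale * intake_multiplier


@dataclass
class SeasonOutcome:
    """End-of-season tallies; individual end states live in the mutated cohort."""

    female_background_deaths: int
    male_background_deaths: int
    males_cannibalized: int
    matings_by_phenotype: dict[str, int]  # {"spillover": n, "mfcl": n}
    events: pd.DataFrame | None = None  # columns: day, event, male_id, female_id

    @property
    def male_deaths(self) -> int:
        return self.male_background_deaths + self.males_cannibalized


def run_season(
    population: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
    log_events: bool = False,
) -> SeasonOutcome:
    """Run one full mating season in place and return end-of-season tallies.

    The cohort arrays are mutated: deaths, matings, condition trajectories
    and cohabitation bookkeeping all end up in ``population``.
    """
    f, m = population.females, population.males
    if log_events:
        cap = config.season_length * (f.n + m.n + m.n * max(config.environment.maxenc, 8) + 2 * f.n) + 16
        events = np.empty((cap, 4), np.int64)
    else:
        events = np.empty((1, 4), np.int64)

    encounter_mode = {"fixed": 0, "poisson": 1, "thinned": 2}[config.encounter_model]
    withdrawal_mode = {"none": 0, "gravid": 1, "satiated": 2}[config.withdrawal]
    f_bg, m_bg, m_can, n_ev = run_season_core(
        rng,
        config.season_length,
        config.environment.maxenc,
        encounter_mode,
        config.environment.pspov,
        config.pmate,
        config.escape_coeff,
        config.male_meal_gain,
        config.male_mortality_rate,
        config.mfcl_attack_rule == "mated_only",
        config.satiated_attacks_lethal,
        config.approach_attack_virgins,
        config.cohab_order == "mate_first",
        withdrawal_mode,
        f.mat_day,
        f.cw,
        f.condition,
        f.maxcond,
        f.satiated,
        f.mated,
        f.father_allele,
        f.resident,
        f.alive,
        f.kills,
        f.mort,
        f.intake,
        f.attack_spillover,
        m.allele,
        m.mat_day,
        m.alive,
        m.cohabiting_with,
        m.matings,
        log_events,
        events,
    )

    matings = {
        "spillover": int(np.sum(f.mated & (f.phenotype == 1))),
        "mfcl": int(np.sum(f.mated & (f.phenotype == 0))),
    }
    log = None
    if log_events:
        ev = events[:n_ev]
        log = pd.DataFrame(
            {
                "day": ev[:, 0],
                "event": [EVENT_NAMES[c] for c in ev[:, 1]],
                "male_id": ev[:, 2],
                "female_id": ev[:, 3],
            }
        )
    return SeasonOutcome(
        female_background_deaths=int(f_bg),
        male_background_deaths=int(m_bg),
        males_cannibalized=int(m_can),
        matings_by_phenotype=matings,
        events=log,
    )
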