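"""Build a generation of adults with field-calibrated life-history attributes.

A generation is a fixed cohort of ``n_females`` + ``n_males`` adults (500 each
by default, the observed 1:1 sex ratio at maturation).  Per female the module
draws: maturation day, adult carapace width CW from the size-maturation
regression, initial condition (abdomen width) from the condition-size
regression, and the satiation threshold maxCOND_f from its quadratic in CW.
The cohort is stored as a struct-of-arrays so the daily season engine can be
compiled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import SimulationConfig, StrategySpec
from .genetics import ALLELE_M, ALLELE_S, phenotype_codes

__all__ = [
    "Females",
    "Males",
    "Population",
    "satiation_threshold",
    "adult_size",
    "initial_condition",
    "draw_female_genotypes",
    "draw_male_alleles",
    "initialize_generation",
    "build_generation_from_genotypes",
]

logger = logging.getLogger(__name__)


def satiation_threshold(cw: float) -> float:
    """Satiation threshold maxCOND_f (mm) as a quadratic in carapace width.

    maxCOND_f = -38.98 + 11.73 * CW - 0.63 * CW**2; increasing up to its
    vertex at CW ~ 9.31 mm.  Raises for degenerate (non-positive) values,
    which occur for implausibly small CW; cohort initialization instead marks
    such females satiated at entry (see :func:`build_generation_from_genotypes`).
    """
    if cw <= 0:
        raise ValueError(f"CW must be > 0, got {cw}")
    value = -38.98 + 11.73 * cw - 0.63 * cw * cw
    if value <= 0.0:
        raise ValueError(
            f"satiation threshold {value:.3f} mm is non-positive at CW={cw:.3f} mm "
            "(degenerate female)"
        )
    return value


def _satiation_threshold_vec(cw: np.ndarray) -> np.ndarray:
    return -38.98 + 11.73 * cw - 0.63 * cw * cw


def adult_size(
    fem_mat: np.ndarray | float,
    cl: float,
    strategy: StrategySpec,
    rng: np.random.Generator,
) -> np.ndarray | float:
    """Draw adult carapace width CW (mm) from the strategy's size regression.

    mean = cw_intercept + cw_mat_slope * fem_mat + cw_cl_slope * CL with the
    strategy's residual sd (steeper maturation slope and larger sd for the
    early-maturing spillover variants).  Draws are truncated below at a small
    positive floor; with the default coefficients the floor is never reached.
    """
    mean = strategy.cw_intercept + strategy.cw_mat_slope * np.asarray(fem_mat, float) + strategy.cw_cl_slope * cl
    draw = rng.normal(mean, strategy.cw_sd) if strategy.cw_sd > 0 else mean
    return np.maximum(draw, 1e-3)


def initial_condition(cw: np.ndarray | float, rng: np.random.Generator, sd: float = 0.2671) -> np.ndarray | float:
    """Draw initial condition COND_o (mm): N(3.54 + 0.49 * CW, 0.2671), floored at 0."""
    mean = 3.54 + 0.49 * np.asarray(cw, float)
    draw = rng.normal(mean, sd) if sd > 0 else mean
    return np.maximum(draw, 0.0)


@dataclass
class Females:
    """Struct-of-arrays state for the female cohort (one slot per individual)."""

    allele_1: np.ndarray  # int8 allele codes
    allele_2: np.ndarray
    phenotype: np.ndarray  # int8: 1 = spillover family, 0 = MFCL
    mat_day: np.ndarray  # int64 maturation day, 1..season_length
    cw: np.ndarray  # carapace width (mm)
    condition: np.ndarray  # abdomen width (mm), current
    maxcond: np.ndarray  # satiation threshold (mm)
    satiated: np.ndarray  # bool, absorbing
    mated: np.ndarray  # bool, set at most once
    father_allele: np.ndarray  # int8, -1 until mated
    resident: np.ndarray  # int64 male index or -1
    alive: np.ndarray  # bool
    kills: np.ndarray  # int64 males cannibalized
    mort: np.ndarray  # effective daily background mortality
    intake: np.ndarray  # intake_scale * intake_multiplier (mm/day)
    attack_spillover: np.ndarray  # int8: 1 = spillover attack rule

    @property
    def n(self) -> int:
        return self.allele_1.size


@dataclass
class Males:
    """Struct-of-arrays state for the male cohort."""

    allele: np.ndarray  # int8
    mat_day: np.ndarray  # int64
    alive: np.ndarray  # bool
    cohabiting_with: np.ndarray  # int64 female index or -1
    matings: np.ndarray  # int64

    @property
    def n(self) -> int:
        return self.allele.size


@dataclass
class Population:
    females: Females
    males: Males
    #: count of females marked satiated at entry because maxCOND_f <= COND_o
    degenerate_females: int = 0


def draw_female_genotypes(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Initial female genotypes from ``config.initial_state``.

    ``"maintenance"`` splits the cohort deterministically into thirds of
    heterozygotes (SM), spillover homozygotes (SS) and MFCL homozygotes (MM),
    any remainder going to the earlier classes in that order.  A float p0
    draws each of the two alleles independently Bernoulli(p0), i.e.
    Hardy-Weinberg genotype proportions.
    """
    n = config.n_females
    state = config.initial_state
    if state == "maintenance":
        base, rem = divmod(n, 3)
        counts = {"SM": base + (rem > 0), "SS": base + (rem > 1), "MM": base}
        return _genotypes_from_counts(counts, rng)
    if isinstance(state, Mapping):
        return _genotypes_from_counts(state, rng)
    p0 = float(state)
    a1 = (rng.random(n) < p0).astype(np.int8)
    a2 = (rng.random(n) < p0).astype(np.int8)
    return a1, a2


def _genotypes_from_counts(counts: Mapping[str, int], rng: np.random.Generator):
    a1 = np.concatenate(
        [
            np.full(counts["SM"], ALLELE_S, np.int8),
            np.full(counts["SS"], ALLELE_S, np.int8),
            np.full(counts["MM"], ALLELE_M, np.int8),
        ]
    )
    a2 = np.concatenate(
        [
            np.full(counts["SM"], ALLELE_M, np.int8),
            np.full(counts["SS"], ALLELE_S, np.int8),
            np.full(counts["MM"], ALLELE_M, np.int8),
        ]
    )
    order = rng.permutation(a1.size)
    return a1[order], a2[order]


def draw_male_alleles(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Initial male alleles: 50/50 split for maintenance, Bernoulli(p0) otherwise."""
    n = config.n_males
    state = config.initial_state
    if state == "maintenance":
        alleles = np.concatenate(
            [np.full(n // 2, ALLELE_S, np.int8), np.full(n - n // 2, ALLELE_M, np.int8)]
        )
        return alleles[rng.permutation(n)]
    if isinstance(state, Mapping):
        k = int(state["male_S"])
        alleles = np.concatenate(
            [np.full(k, ALLELE_S, np.int8), np.full(n - k, ALLELE_M, np.int8)]
        )
        return alleles[rng.permutation(n)]
    p0 = float(state)
    return (rng.random(n) < p0).astype(np.int8)


def build_generation_from_genotypes(
    config: SimulationConfig,
    f_allele_1: np.ndarray,
    f_allele_2: np.ndarray,
    m_allele: np.ndarray,
    rng: np.random.Generator,
) -> Population:
    """Assign life-history attributes to a cohort of known genotypes.

    Maturation days are drawn per phenotype's strategy, rounded half-up to an
    integer day on the daily grid and clamped to [1, season_length].  CW,
    COND_o and maxCOND_f follow from the regressions.  Females whose drawn
    threshold does not exceed their initial condition (possible only in the
    far tail of the size distribution) are marked satiated at entry rather
    than redrawn, preserving the fixed cohort size.
    """
    nf, nm = f_allele_1.size, m_allele.size
    pheno = phenotype_codes(f_allele_1, f_allele_2, config.dominance)
    spov, mfcl = config.spillover_strategy, config.mfcl_strategy

    mat_mean = np.where(pheno == 1, spov.fem_mat_mean, mfcl.fem_mat_mean)
    mat_sd = np.where(pheno == 1, spov.fem_mat_sd, mfcl.fem_mat_sd)
    mat = rng.normal(mat_mean, mat_sd)
    mat_day = np.clip(np.floor(mat + 0.5).astype(np.int64), 1, config.season_length)

    cw_mean = (
        np.where(pheno == 1, spov.cw_intercept, mfcl.cw_intercept)
        + np.where(pheno == 1, spov.cw_mat_slope, mfcl.cw_mat_slope) * mat_day
        + np.where(pheno == 1, spov.cw_cl_slope, mfcl.cw_cl_slope) * config.cl_value
    )
    cw_sd = np.where(pheno == 1, spov.cw_sd, mfcl.cw_sd)
    cw = np.maximum(rng.normal(cw_mean, cw_sd), 1e-3)

    cond = np.asarray(initial_condition(cw, rng), float)
    maxcond = _satiation_threshold_vec(cw)

    degenerate = maxcond <= cond
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.debug(
            "%d female(s) initialized with maxCOND_f <= COND_o; marked satiated at entry",
            n_degenerate,
        )

    females = Females(
        allele_1=f_allele_1.astype(np.int8),
        allele_2=f_allele_2.astype(np.int8),
        phenotype=pheno,
        mat_day=mat_day,
        cw=cw,
        condition=cond,
        maxcond=maxcond,
        satiated=degenerate.copy(),
        mated=np.zeros(nf, bool),
        father_allele=np.full(nf, -1, np.int8),
        resident=np.full(nf, -1, np.int64),
        alive=np.ones(nf, bool),
        kills=np.zeros(nf, np.int64),
        mort=np.where(
            pheno == 1,
            config.female_mortality(True),
            config.female_mortality(False),
        ).astype(float),
        intake=np.where(
            pheno == 1,
            config.environment.intake_scale * spov.intake_multiplier,
            config.environment.intake_scale * mfcl.intake_multiplier,
        ).astype(float),
        attack_spillover=np.where(
            pheno == 1,
            np.int8(spov.attack_family == "spillover"),
            np.int8(mfcl.attack_family == "spillover"),
        ).astype(np.int8),
    )

    m_mat = rng.normal(config.male_mat_mean, config.male_mat_sd, nm)
    m_mat_day = np.clip(np.floor(m_mat + 0.5).astype(np.int64), 1, config.season_length)
    males = Males(
        allele=m_allele.astype(np.int8),
        mat_day=m_mat_day,
        alive=np.ones(nm, bool),
        cohabiting_with=np.full(nm, -1, np.int64),
        matings=np.zeros(nm, np.int64),
    )
    return Population(females=females, males=males, degenerate_females=n_degenerate)


def initialize_generation(config: SimulationConfig, rng: np.random.Generator) -> Population:
    """Draw the founding generation specified by ``config.initial_state``."""
    a1, a2 = draw_female_genotypes(config, rng)
    m = draw_male_alleles(config, rng)
    return build_generation_from_genotypes(config, a1, a2, m, rng)
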