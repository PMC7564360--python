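"""End-of-season reproduction: fecundity allometries, differential juvenile
survival, and constant-size next-generation sampling.

Every female alive and mated at the season's end lays one egg sac whose
volume follows her strategy's regression on carapace width (and, for MFCL
and the body-condition-dependent spillover variants, on her realized
end-of-season condition).  Offspring number is linear in volume.  Juvenile
life is collapsed into the single parameter ``different``: the proportion of
spillover-phenotype juveniles surviving to maturation relative to MFCL
juveniles.  Exactly ``n_females`` daughters and ``n_males`` sons are sampled
from the weighted offspring pool, holding the adult population at its
carrying capacity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig, StrategySpec
from .genetics import phenotype_codes
from .population import Population, build_generation_from_genotypes

__all__ = ["Brood", "ExtinctionError", "eggsac_volume", "offspring_number",
           "collect_broods", "build_next_generation"]

logger = logging.getLogger(__name__)


class ExtinctionError(RuntimeError):
    """No offspring of a required sex: the population cannot be renewed."""


@dataclass
class Brood:
    """One mated, surviving female's contribution to the offspring pool."""

    mother_allele_1: int
    mother_allele_2: int
    mother_phenotype: int  # 1 = spillover family, 0 = MFCL
    father_allele: int
    volume: float  # egg-sac volume (mm^3)
    offspring_count: int


def eggsac_volume(
    cw: np.ndarray | float,
    condition: np.ndarray | float,
    strategy: StrategySpec,
    rng: np.random.Generator,
) -> np.ndarray | float:
    """Draw egg-sac volume (mm^3) from the strategy's fecundity regression.

    mean = vol_intercept + vol_cw_slope * CW [+ vol_cond_slope * COND for the
    condition-dependent strategies, COND being the realized end-of-season
    condition, never above the satiation threshold].  Negative draws truncate
    to 0: the regressions extrapolate outside their fitted range for small
    females.
    """
    mean = strategy.vol_intercept + strategy.vol_cw_slope * np.asarray(cw, float)
    if strategy.vol_cond_slope != 0.0:
        mean = mean + strategy.vol_cond_slope * np.asarray(condition, float)
    draw = rng.normal(mean, strategy.vol_sd) if strategy.vol_sd > 0 else mean
    return np.maximum(draw, 0.0)


def offspring_number(vol: np.ndarray | float) -> np.ndarray | int:
    """Offspring per egg sac: round(57.54 + 0.16 * vol), floored at 0."""
    n = np.floor(57.54 + 0.16 * np.asarray(vol, float) + 0.5)
    n = np.maximum(n, 0.0)
    if np.ndim(vol) == 0:
        return int(n)
    return n.astype(np.int64)


def collect_broods(
    population: Population, config: SimulationConfig, rng: np.random.Generator
) -> list[Brood]:
    """Build the brood list from females alive and mated at season end."""
    f = population.females
    mask = f.alive & f.mated
    idx = np.flatnonzero(mask)
    broods: list[Brood] = []
    for phen, strategy in ((1, config.spillover_strategy), (0, config.mfcl_strategy)):
        sel = idx[f.phenotype[idx] == phen]
        if sel.size == 0:
            continue
        vols = np.atleast_1d(eggsac_volume(f.cw[sel], f.condition[sel], strategy, rng))
        counts = np.atleast_1d(offspring_number(vols))
        for i, v, n in zip(sel, vols, counts):
            broods.append(
                Brood(
                    mother_allele_1=int(f.allele_1[i]),
                    mother_allele_2=int(f.allele_2[i]),
                    mother_phenotype=phen,
                    father_allele=int(f.father_allele[i]),
                    volume=float(v),
                    offspring_count=int(n),
                )
            )
    return broods


def _weighted_sample_without_replacement(
    n_pool: int, k: int, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Efraimidis-Spirakis reservoir keys: top-k of u**(1/w) is an exact
    sequential weighted sample without replacement."""
    keys = rng.random(n_pool) ** (1.0 / weights)
    return np.argpartition(keys, n_pool - k)[n_pool - k:]


def build_next_generation(
    broods: list[Brood], config: SimulationConfig, rng: np.random.Generator
) -> Population:
    """Sample the next adult cohort from the pooled offspring of all broods.

    Sexes and segregating maternal alleles are drawn per offspring
    (probability 1/2 each); daughters also inherit the father's X.  Under the
    default ``juvenile_mode="weight"``, each spillover-phenotype daughter
    carries relative sampling weight ``different`` (MFCL weight 1) in an
    exact weighted draw without replacement of ``n_females`` daughters;
    ``"cull"`` instead applies a Bernoulli(different) survival filter before
    a uniform draw.  Sons are sampled uniformly (males are phenotypically
    identical carriers) unless ``apply_different_to_sons`` is set, in which
    case S-carrying sons are weighted too.  If a pool is smaller than the
    required cohort, sampling falls back to with-replacement with a logged
    warning.  Raises :class:`ExtinctionError` if either sex is absent.
    """
    counts = np.array([b.offspring_count for b in broods], np.int64)
    total = int(counts.sum())
    if len(broods) == 0 or total == 0:
        raise ExtinctionError("no brood produced any offspring")

    mother_a1 = np.repeat(np.array([b.mother_allele_1 for b in broods], np.int8), counts)
    mother_a2 = np.repeat(np.array([b.mother_allele_2 for b in broods], np.int8), counts)
    father = np.repeat(np.array([b.father_allele for b in broods], np.int8), counts)

    is_female = rng.random(total) < 0.5
    take_first = rng.random(total) < 0.5
    maternal = np.where(take_first, mother_a1, mother_a2).astype(np.int8)

    d_maternal = maternal[is_female]
    d_paternal = father[is_female]
    s_allele = maternal[~is_female]

    if d_maternal.size == 0:
        raise ExtinctionError("no daughters were produced")
    if s_allele.size == 0:
        raise ExtinctionError("no sons were produced")

    d_pheno = phenotype_codes(d_maternal, d_paternal, config.dominance)

    # daughters: differential juvenile survival
    if config.juvenile_mode == "cull":
        keep = (d_pheno == 0) | (rng.random(d_pheno.size) < config.different)
        d_maternal, d_paternal, d_pheno = d_maternal[keep], d_paternal[keep], d_pheno[keep]
        if d_maternal.size == 0:
            raise ExtinctionError("no daughters survived the juvenile stage")
        d_idx = _uniform_sample(d_maternal.size, config.n_females, rng, "daughters")
    else:
        weights = np.where(d_pheno == 1, config.different, 1.0)
        if d_maternal.size >= config.n_females:
            d_idx = _weighted_sample_without_replacement(
                d_maternal.size, config.n_females, weights, rng
            )
        else:
            logger.debug(
                "daughter pool (%d) smaller than cohort (%d); sampling with replacement",
                d_maternal.size, config.n_females,
            )
            p = weights / weights.sum()
            d_idx = rng.choice(d_maternal.size, config.n_females, replace=True, p=p)

    # sons: uniform, unless the sensitivity toggle weights S carriers
    if config.apply_different_to_sons:
        weights = np.where(s_allele == 1, config.different, 1.0)
        if s_allele.size >= config.n_males:
            s_idx = _weighted_sample_without_replacement(
                s_allele.size, config.n_males, weights, rng
            )
        else:
            logger.debug(
                "son pool (%d) smaller than cohort (%d); sampling with replacement",
                s_allele.size, config.n_males,
            )
            p = weights / weights.sum()
            s_idx = rng.choice(s_allele.size, config.n_males, replace=True, p=p)
    else:
        s_idx = _uniform_sample(s_allele.size, config.n_males, rng, "sons")

    return build_generation_from_genotypes(
        config,
        d_maternal[d_idx],
        d_paternal[d_idx],
        s_allele[s_idx],
        rng,
    )


def _uniform_sample(n_pool: int, k: int, rng: np.random.Generator, what: str) -> np.ndarray:
    if n_pool >= k:
        return rng.choice(n_pool, k, replace=False)
    logger.debug("%s pool (%d) smaller than cohort (%d); sampling with replacement",
                   what, n_pool, k)
    return rng.choice(n_pool, k, replace=True)
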