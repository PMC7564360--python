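"""Multi-generation experiments: maintenance and invasion runs, outcome
classification, and parameter-grid sweeps.

A run iterates initialize -> season -> reproduce until the spillover allele
frequency p hits 0 or 1 (fixation) or the generation cap is reached
(coexistence).  Per generation a :class:`GenerationRecord` captures the
quantities used downstream: p, phenotype counts at maturation and at season
end, matings, cannibalism deaths, the percentage of MFCL females that mated,
and spillover relative fitness (the ratio between the number of spillover
females surviving to maturation and the mean of the two strategies'
survivor counts, a quantity in [0, 2]).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig, load_config
from .genetics import allele_frequency_arrays
from .population import initialize_generation
from .reproduction import ExtinctionError, build_next_generation, collect_broods
from .season import run_season

__all__ = [
    "GenerationRecord",
    "Trajectory",
    "run_generations",
    "run_maintenance",
    "run_invasion",
    "classify_outcome",
    "sweep",
]

logger = logging.getLogger(__name__)

OUTCOME_SPILLOVER_FIXED = "spillover_fixed"
OUTCOME_MFCL_FIXED = "mfcl_fixed"
OUTCOME_COEXISTENCE = "coexistence_at_max_gen"


@dataclass
class GenerationRecord:
    """Per-generation summary statistics."""

    generation: int
    p: float  # spillover allele frequency over all adult X copies
    n_females_spillover: int  # females surviving to maturation, by phenotype
    n_females_mfcl: int
    survivors_spillover: int = 0  # females alive at season end, by phenotype
    survivors_mfcl: int = 0
    matings_spillover: int = 0
    matings_mfcl: int = 0
    males_cannibalized: int = 0
    male_background_deaths: int = 0
    female_background_deaths: int = 0

    @property
    def mfcl_mating_pct(self) -> float:
        """Percentage of MFCL females (at maturation) that mated; NaN if none."""
        if self.n_females_mfcl == 0:
            return math.nan
        return 100.0 * self.matings_mfcl / self.n_females_mfcl

    @property
    def relative_fitness_spillover(self) -> float:
        """N_spov / ((N_spov + N_mfcl) / 2) on maturation counts; in [0, 2]."""
        total = self.n_females_spillover + self.n_females_mfcl
        if total == 0:
            return math.nan
        return self.n_females_spillover / (total / 2.0)


@dataclass
class Trajectory:
    """Ordered generation records plus the terminal outcome of a run."""

    records: list[GenerationRecord]
    outcome: str
    terminal_generation: int
    config: SimulationConfig
    extinct: bool = False  # population failed to renew (no offspring of a sex)
    quasi_equilibrium: bool = False

    @property
    def p_series(self) -> np.ndarray:
        return np.array([r.p for r in self.records])

    @property
    def terminal_p(self) -> float:
        return self.records[-1].p

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "generation": r.generation,
                "p": r.p,
                "n_es_females": r.n_females_spillover,
                "n_mfcl_females": r.n_females_mfcl,
                "survivors_es": r.survivors_spillover,
                "survivors_mfcl": r.survivors_mfcl,
                "matings_es": r.matings_spillover,
                "matings_mfcl": r.matings_mfcl,
                "males_cannibalized": r.males_cannibalized,
                "mfcl_mating_pct": r.mfcl_mating_pct,
                "rel_fitness_es": r.relative_fitness_spillover,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "generation", "p", "n_es_females", "n_mfcl_females",
                "survivors_es", "survivors_mfcl", "matings_es", "matings_mfcl",
                "males_cannibalized", "mfcl_mating_pct", "rel_fitness_es",
            ],
        )


def classify_outcome(trajectory: Trajectory) -> str:
    """Label a completed trajectory and set its quasi-equilibrium flag.

    Fixation labels follow the terminal p; coexistence means both alleles
    were still present at the generation cap.  A fixation occurring after a
    configurable fraction (default one half) of the generation cap is
    flagged as a quasi-equilibrium: the run held a polymorphic balance for
    thousands of generations before one allele was finally lost.
    """
    p = trajectory.terminal_p
    cap = trajectory.config.max_generations
    if p == 1.0:
        label = OUTCOME_SPILLOVER_FIXED
    elif p == 0.0:
        label = OUTCOME_MFCL_FIXED
    else:
        label = OUTCOME_COEXISTENCE
    trajectory.outcome = label
    trajectory.quasi_equilibrium = (
        label != OUTCOME_COEXISTENCE
        and trajectory.terminal_generation
        >= trajectory.config.quasi_equilibrium_fraction * cap
    )
    return label


def run_generations(
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    progress_every: int | None = None,
) -> Trajectory:
    """Run one trajectory until fixation or the generation cap.

    Fixation is declared when p hits 0 or 1 at the start of a generation
    (i.e. after next-generation sampling); the fixation generation gets a
    minimal record (no season is simulated for a monomorphic terminal
    cohort's bookkeeping beyond its counts).  A renewal failure (no
    offspring of a required sex) ends the run with ``extinct=True`` and the
    fixation label of the majority allele at that point.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else config.seed)
    config.validate()

    records: list[GenerationRecord] = []
    population = initialize_generation(config, rng)
    gen = 0
    extinct = False
    while True:
        f, m = population.females, population.males
        p = allele_frequency_arrays(f.allele_1, f.allele_2, m.allele)
        n_spov = int(np.sum(f.phenotype == 1))
        n_mfcl = f.n - n_spov
        rec = GenerationRecord(
            generation=gen, p=p, n_females_spillover=n_spov, n_females_mfcl=n_mfcl
        )
        records.append(rec)
        if p == 0.0 or p == 1.0 or gen >= config.max_generations:
            break
        if progress_every and gen and gen % progress_every == 0:
            logger.info("generation %d: p = %.4f", gen, p)

        outcome = run_season(population, config, rng)
        rec.survivors_spillover = int(np.sum(f.alive & (f.phenotype == 1)))
        rec.survivors_mfcl = int(np.sum(f.alive & (f.phenotype == 0)))
        rec.matings_spillover = outcome.matings_by_phenotype["spillover"]
        rec.matings_mfcl = outcome.matings_by_phenotype["mfcl"]
        rec.males_cannibalized = outcome.males_cannibalized
        rec.male_background_deaths = outcome.male_background_deaths
        rec.female_background_deaths = outcome.female_background_deaths

        try:
            broods = collect_broods(population, config, rng)
            population = build_next_generation(broods, config, rng)
        except ExtinctionError as err:
            logger.warning("generation %d: %s; ending run", gen, err)
            extinct = True
            break
        gen += 1

    terminal = records[-1].generation
    trajectory = Trajectory(
        records=records,
        outcome="",
        terminal_generation=terminal,
        config=config,
        extinct=extinct,
    )
    if extinct and trajectory.terminal_p not in (0.0, 1.0):
        # renewal failure of a polymorphic cohort: label by the majority allele
        trajectory.outcome = (
            OUTCOME_SPILLOVER_FIXED if trajectory.terminal_p >= 0.5 else OUTCOME_MFCL_FIXED
        )
        trajectory.quasi_equilibrium = False
        return trajectory
    classify_outcome(trajectory)
    return trajectory


def run_maintenance(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> Trajectory:
    """Maintenance run: allele frequency 0.5 with female genotype thirds."""
    return run_generations(config.replace(initial_state="maintenance"), rng)


def run_invasion(
    config: SimulationConfig,
    p0: float,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Invasion run from a rare-mutant frequency (0.01 or 0.99 in the study design)."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    return run_generations(config.replace(initial_state=float(p0)), rng)


def sweep(
    base_config: SimulationConfig | dict,
    environments: Sequence[str] = ("poor", "rich"),
    different_values: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    dominance_values: Sequence[str] = ("spillover",),
    replicates: int = 1,
    seed: int | None = None,
    p0: float | str | None = None,
) -> pd.DataFrame:
    """Run the full factorial grid and return one row per cell per replicate.

    Each replicate draws its generator from an independent child of the root
    ``SeedSequence``, so the grid is reproducible from ``seed`` alone and
    cells are statistically independent.  Columns: the cell coordinates, the
    replicate stream id, the outcome label, the terminal generation, and the
    terminal allele frequency.
    """
    if not isinstance(base_config, SimulationConfig):
        base_config = load_config(base_config)
    cells = list(itertools.product(environments, different_values, dominance_values))
    if not cells:
        raise ValueError("sweep grid is empty")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(cells) * replicates)

    rows = []
    k = 0
    for env, diff, dom in cells:
        from .config import default_environment

        cfg = base_config.replace(
            environment=default_environment(env), different=diff, dominance=dom
        )
        if p0 is not None:
            cfg = cfg.replace(initial_state=p0)
        for rep in range(replicates):
            traj = run_generations(cfg, np.random.default_rng(streams[k]))
            rows.append(
                {
                    "environment": env,
                    "different": diff,
                    "dominance": dom,
                    "replicate": rep,
                    "stream": str(streams[k].spawn_key),
                    "outcome": traj.outcome,
                    "terminal_generation": traj.terminal_generation,
                    "terminal_p": traj.terminal_p,
                    "quasi_equilibrium": traj.quasi_equilibrium,
                    "extinct": traj.extinct,
                }
            )
            k += 1
    return pd.DataFrame(rows)
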