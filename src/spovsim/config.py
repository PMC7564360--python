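"""Model parameters: environments, strategies, and full scenario configuration.

All numeric defaults are the field-calibrated values for the Iberian tarantula
(*Lycosa hispanica*), a burrowing wolf spider: regression coefficients relating
maturation time, carapace width (CW, the fixed structural size of the adult),
body condition (abdomen width, mm) and egg-sac volume, together with the daily
rates (mortality, feeding, encounters) that drive the within-season loop.

Five female behavioral strategies are parameterized:

``MFCL``
    "Mate first, cannibalize later" — a plastic strategy that attacks
    approaching males only once mated or while unsatiated.
``SPOV``
    Classic aggressive-spillover — attacks suitors with probability ``pspov``
    regardless of mating or satiation status; forages at 1.5x the MFCL rate
    and pays a higher background mortality.
``BCD-SPOV``
    Spillover whose fecundity also depends on realized adult body condition.
``EARLY-SPOV``
    Spillover that additionally matures ~30% earlier (day 39 vs. 56) and grows
    with a steeper size-maturation slope.
``BCD-EM-SPOV``
    Condition-dependent fecundity combined with early maturation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ConfigError",
    "EnvironmentSpec",
    "StrategySpec",
    "SimulationConfig",
    "STRATEGY_NAMES",
    "SPILLOVER_NAMES",
    "default_strategy",
    "default_environment",
    "load_config",
]

MFCL_NAME = "MFCL"
STRATEGY_NAMES = ("MFCL", "SPOV", "BCD-SPOV", "EARLY-SPOV", "BCD-EM-SPOV")
#: strategies belonging to the aggressive-spillover family
SPILLOVER_NAMES = ("SPOV", "BCD-SPOV", "EARLY-SPOV", "BCD-EM-SPOV")

#: aliases accepted on input (the early variants appear under both names)
_STRATEGY_ALIASES = {
    "EM-SPOV": "EARLY-SPOV",
    "BCD-EARLY-SPOV": "BCD-EM-SPOV",
    "BCD EM-SPOV": "BCD-EM-SPOV",
}


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration values."""


@dataclass(frozen=True)
class EnvironmentSpec:
    """Ecological environment: encounter rate, food availability, risk.

    Poor environments halve the daily condition increment, lower the maximum
    male encounter rate from 3 to 1 female/day, raise adult spillover-female
    predation mortality (multiplier 1.5 instead of 1.2 on the MFCL base rate)
    and raise the spillover attack probability on males (0.9 instead of 0.5).
    """

    richness: str  # {"poor", "rich"}
    maxenc: int  # max daily female encounters per searching male (day^-1)
    intake_scale: float  # daily condition-increment scale (mm/day)
    mort_multiplier: float  # spillover female mortality multiplier ("mort")
    pspov: float  # P(spillover female attacks an approaching male)

    def validate(self) -> None:
        if self.richness not in ("poor", "rich"):
            raise ConfigError(f"richness must be 'poor' or 'rich', got {self.richness!r}")
        if self.maxenc < 1:
            raise ConfigError(f"maxenc must be >= 1, got {self.maxenc}")
        if self.intake_scale <= 0:
            raise ConfigError(f"intake_scale must be > 0, got {self.intake_scale}")
        if self.mort_multiplier <= 0:
            raise ConfigError(f"mort_multiplier must be > 0, got {self.mort_multiplier}")
        if not 0.0 <= self.pspov <= 1.0:
            raise ConfigError(f"pspov must be in [0, 1], got {self.pspov}")


@dataclass(frozen=True)
class StrategySpec:
    """One female strategy's life-history parameterization.

    ``cw_*`` are the coefficients of the adult-size regression
    CW = cw_intercept + cw_mat_slope * fem_mat + cw_cl_slope * CL + N(0, cw_sd),
    ``vol_*`` those of the egg-sac-volume regression
    vol = vol_intercept + vol_cw_slope * CW + vol_cond_slope * COND + N(0, vol_sd).
    ``attack_family`` selects the behavioral attack rule applied in the season
    engine: "spillover" (Bernoulli(pspov), unconditional) or "mfcl"
    (state-dependent: attack iff mated or unsatiated).
    """

    name: str
    fem_mat_mean: float  # maturation day since season onset (days)
    fem_mat_sd: float
    cw_intercept: float
    cw_mat_slope: float
    cw_cl_slope: float
    cw_sd: float
    intake_multiplier: float  # relative daily feeding rate (MFCL = 1)
    mortality_rate: float  # background daily death probability (day^-1)
    vol_intercept: float
    vol_cw_slope: float
    vol_cond_slope: float  # 0 for non-BCD spillover strategies
    vol_sd: float
    bcd: bool  # fecundity uses realized adult condition
    attack_family: str  # {"spillover", "mfcl"}

    def validate(self) -> None:
        if self.fem_mat_sd < 0 or self.cw_sd < 0 or self.vol_sd < 0:
            raise ConfigError(f"{self.name}: standard deviations must be >= 0")
        if not 0.0 <= self.mortality_rate <= 1.0:
            raise ConfigError(
                f"{self.name}: mortality_rate must be in [0, 1], got {self.mortality_rate}"
            )
        if self.intake_multiplier <= 0:
            raise ConfigError(f"{self.name}: intake_multiplier must be > 0")
        if self.attack_family not in ("spillover", "mfcl"):
            raise ConfigError(
                f"{self.name}: attack_family must be 'spillover' or 'mfcl', "
                f"got {self.attack_family!r}"
            )


_MFCL = dict(
    fem_mat_mean=56.0,
    fem_mat_sd=0.5,
    cw_intercept=3.21,
    cw_mat_slope=0.024,
    cw_cl_slope=0.39,
    cw_sd=0.4679,
    intake_multiplier=1.0,
    mortality_rate=0.0030,
    vol_intercept=-2297.64,
    vol_cw_slope=217.88,
    vol_cond_slope=123.44,
    vol_sd=129.59,
    bcd=True,
    attack_family="mfcl",
)
_SPOV_COMMON = dict(
    fem_mat_mean=56.0,
    fem_mat_sd=0.5,
    cw_intercept=3.21,
    cw_mat_slope=0.024,
    cw_cl_slope=0.39,
    cw_sd=0.4679,
    intake_multiplier=1.5,
    mortality_rate=0.0036,
    attack_family="spillover",
)
_EARLY = dict(fem_mat_mean=39.0, cw_mat_slope=0.047, cw_sd=0.5066)
_VOL_PLAIN = dict(vol_intercept=-1156.43, vol_cw_slope=277.21, vol_cond_slope=0.0, vol_sd=140.33, bcd=False)
_VOL_BCD = dict(vol_intercept=-1156.43, vol_cw_slope=277.21, vol_cond_slope=123.44, vol_sd=132.97, bcd=True)

_DEFAULT_STRATEGIES: dict[str, dict[str, Any]] = {
    "MFCL": _MFCL,
    "SPOV": {**_SPOV_COMMON, **_VOL_PLAIN},
    "BCD-SPOV": {**_SPOV_COMMON, **_VOL_BCD},
    "EARLY-SPOV": {**_SPOV_COMMON, **_EARLY, **_VOL_PLAIN},
    "BCD-EM-SPOV": {**_SPOV_COMMON, **_EARLY, **_VOL_BCD},
}

_DEFAULT_ENVIRONMENTS = {
    "poor": dict(richness="poor", maxenc=1, intake_scale=0.0741, mort_multiplier=1.5, pspov=0.9),
    "rich": dict(richness="rich", maxenc=3, intake_scale=0.1482, mort_multiplier=1.2, pspov=0.5),
}


def default_strategy(name: str) -> StrategySpec:
    """Return the default parameterization of one of the five strategies."""
    canonical = _STRATEGY_ALIASES.get(name, name)
    if canonical not in _DEFAULT_STRATEGIES:
        raise ConfigError(
            f"unknown strategy {name!r}; expected one of {STRATEGY_NAMES}"
        )
    return StrategySpec(name=canonical, **_DEFAULT_STRATEGIES[canonical])


def default_environment(richness: str, **overrides: Any) -> EnvironmentSpec:
    """Return the default poor or rich environment, with optional overrides."""
    if richness not in _DEFAULT_ENVIRONMENTS:
        raise ConfigError(f"unknown environment {richness!r}; expected 'poor' or 'rich'")
    params = {**_DEFAULT_ENVIRONMENTS[richness], **overrides}
    env = EnvironmentSpec(**params)
    env.validate()
    return env


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameter set for one simulation scenario.

    ``initial_state`` is either the string ``"maintenance"`` (allele frequency
    0.5 with female genotypes in equal thirds heterozygote / spillover
    homozygote / MFCL homozygote and a 50/50 male allele split), a float p0
    in [0, 1] (Hardy-Weinberg genotype draw, used for invasion runs at 0.01
    and 0.99), or an explicit mapping with keys ``SS``, ``SM``, ``MM``
    (female counts) and ``male_S`` (count of S-carrying males).
    """

    environment: EnvironmentSpec = field(default_factory=lambda: default_environment("rich"))
    spillover_strategy: StrategySpec = field(default_factory=lambda: default_strategy("EARLY-SPOV"))
    mfcl_strategy: StrategySpec = field(default_factory=lambda: default_strategy("MFCL"))
    dominance: str = "spillover"  # which allele is dominant {"spillover", "mfcl"}
    different: float = 0.5  # spillover juvenile survival relative to MFCL
    n_females: int = 500
    n_males: int = 500
    season_length: int = 79  # days
    max_generations: int = 20_000
    initial_state: Any = "maintenance"
    pmate: float = 0.5  # daily mating probability during cohabitation
    cl_value: float = 3.5  # carapace length covariate CL (mm), held constant
    male_meal_gain: float = 2.39  # condition gain from cannibalizing a male (mm)
    male_mortality_rate: float = 0.0045  # day^-1
    escape_coeff: float = 0.1  # pescape = exp(-escape_coeff * CW) (mm^-1)
    male_mat_mean: float = 36.0
    male_mat_sd: float = 0.5
    mfcl_attack_rule: str = "literal"  # {"literal", "mated_only"}
    encounter_model: str = "fixed"  # {"fixed", "poisson", "thinned"}
    cohab_order: str = "attack_first"  # {"attack_first", "mate_first"}
    #: when a male approaches an unoccupied virgin, does her attack decision
    #: fire at the approach itself (True) or only within the daily
    #: cohabitation loop (False)?
    approach_attack_virgins: bool = True
    #: encounter-pool withdrawal: "none", "gravid" (mated AND satiated
    #: females retire to brood), or "satiated" (any satiated female retires)
    withdrawal: str = "none"
    #: do attacks by satiated females kill the male?  By default a satiated
    #: female's attack drives the male off unharmed: above the satiation
    #: threshold females no longer feed, so the aggression is still expressed
    #: (spillover females keep attacking) but the suitor is not consumed
    satiated_attacks_lethal: bool = False
    juvenile_mode: str = "weight"  # {"weight", "cull"}
    apply_different_to_sons: bool = False
    quasi_equilibrium_fraction: float = 0.5
    seed: int | None = None
    replicates: int = 1

    def validate(self) -> None:
        self.environment.validate()
        self.spillover_strategy.validate()
        self.mfcl_strategy.validate()
        if self.dominance not in ("spillover", "mfcl"):
            raise ConfigError(f"dominance must be 'spillover' or 'mfcl', got {self.dominance!r}")
        if not 0.0 < self.different <= 1.0:
            raise ConfigError(f"different must be in (0, 1], got {self.different}")
        if self.n_females < 1 or self.n_males < 1:
            raise ConfigError("n_females and n_males must be >= 1")
        if self.season_length < 1:
            raise ConfigError(f"season_length must be >= 1, got {self.season_length}")
        if self.max_generations < 1:
            raise ConfigError(f"max_generations must be >= 1, got {self.max_generations}")
        for name in ("pmate", "male_mortality_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.male_meal_gain < 0:
            raise ConfigError(f"male_meal_gain must be >= 0, got {self.male_meal_gain}")
        if self.escape_coeff < 0:
            raise ConfigError(f"escape_coeff must be >= 0, got {self.escape_coeff}")
        if self.mfcl_attack_rule not in ("literal", "mated_only"):
            raise ConfigError(
                f"mfcl_attack_rule must be 'literal' or 'mated_only', got {self.mfcl_attack_rule!r}"
            )
        if self.encounter_model not in ("fixed", "poisson", "thinned"):
            raise ConfigError(
                f"encounter_model must be 'fixed', 'poisson' or 'thinned', "
                f"got {self.encounter_model!r}"
            )
        if self.cohab_order not in ("mate_first", "attack_first"):
            raise ConfigError(
                f"cohab_order must be 'mate_first' or 'attack_first', got {self.cohab_order!r}"
            )
        if self.withdrawal not in ("none", "gravid", "satiated"):
            raise ConfigError(
                f"withdrawal must be 'none', 'gravid' or 'satiated', got {self.withdrawal!r}"
            )
        if self.juvenile_mode not in ("weight", "cull"):
            raise ConfigError(
                f"juvenile_mode must be 'weight' or 'cull', got {self.juvenile_mode!r}"
            )
        if not 0.0 < self.quasi_equilibrium_fraction <= 1.0:
            raise ConfigError("quasi_equilibrium_fraction must be in (0, 1]")
        self._validate_initial_state()

    def _validate_initial_state(self) -> None:
        state = self.initial_state
        if state == "maintenance":
            return
        if isinstance(state, (int, float)) and not isinstance(state, bool):
            if not 0.0 <= float(state) <= 1.0:
                raise ConfigError(f"initial_state p0 must be in [0, 1], got {state}")
            return
        if isinstance(state, Mapping):
            required = {"SS", "SM", "MM", "male_S"}
            if set(state) != required:
                raise ConfigError(
                    f"explicit initial_state must have keys {sorted(required)}, got {sorted(state)}"
                )
            if state["SS"] + state["SM"] + state["MM"] != self.n_females:
                raise ConfigError("female genotype counts must sum to n_females")
            if not 0 <= state["male_S"] <= self.n_males:
                raise ConfigError("male_S must be between 0 and n_males")
            return
        raise ConfigError(f"unrecognized initial_state: {state!r}")

    # -- effective per-phenotype rates used by the engine ------------------

    def female_mortality(self, spillover_phenotype: bool) -> float:
        """Effective background daily mortality for a female of either phenotype.

        Spillover-family females pay the environment's predation multiplier on
        the MFCL base rate ("mort" = 1.2 rich, 1.5 poor: 0.0030 -> 0.0036 or
        0.0045); MFCL females use their own base rate.
        """
        if spillover_phenotype:
            return self.mfcl_strategy.mortality_rate * self.environment.mort_multiplier
        return self.mfcl_strategy.mortality_rate

    def strategy_for_phenotype(self, spillover_phenotype: bool) -> StrategySpec:
        return self.spillover_strategy if spillover_phenotype else self.mfcl_strategy

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["environment"] = dataclasses.asdict(self.environment)
        d["spillover_strategy"] = dataclasses.asdict(self.spillover_strategy)
        d["mfcl_strategy"] = dataclasses.asdict(self.mfcl_strategy)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def replace(self, **changes: Any) -> "SimulationConfig":
        cfg = dataclasses.replace(self, **changes)
        cfg.validate()
        return cfg


_TOP_LEVEL_SIMPLE = {
    f.name
    for f in dataclasses.fields(SimulationConfig)
    if f.name not in ("environment", "spillover_strategy", "mfcl_strategy")
}


def _build_strategy(value: Any, role: str) -> StrategySpec:
    if isinstance(value, StrategySpec):
        return value
    if isinstance(value, str):
        return default_strategy(value)
    if isinstance(value, Mapping):
        known = {f.name for f in dataclasses.fields(StrategySpec)}
        base = dict(value)
        name = base.get("name")
        if name is None:
            raise ConfigError(f"{role}: strategy mapping requires a 'name' key")
        defaults = dataclasses.asdict(default_strategy(name))
        unknown = set(base) - known
        if unknown:
            raise ConfigError(f"{role}: unknown strategy keys {sorted(unknown)}")
        defaults.update(base)
        defaults["name"] = _STRATEGY_ALIASES.get(name, name)
        return StrategySpec(**defaults)
    raise ConfigError(f"{role}: cannot build a strategy from {value!r}")


def _build_environment(value: Any) -> EnvironmentSpec:
    if isinstance(value, EnvironmentSpec):
        return value
    if isinstance(value, str):
        return default_environment(value)
    if isinstance(value, Mapping):
        known = {f.name for f in dataclasses.fields(EnvironmentSpec)}
        base = dict(value)
        richness = base.get("richness")
        if richness is None:
            raise ConfigError("environment mapping requires a 'richness' key")
        unknown = set(base) - known
        if unknown:
            raise ConfigError(f"environment: unknown keys {sorted(unknown)}")
        defaults = dict(_DEFAULT_ENVIRONMENTS.get(richness, {}))
        if not defaults:
            raise ConfigError(f"unknown environment richness {richness!r}")
        defaults.update(base)
        return EnvironmentSpec(**defaults)
    raise ConfigError(f"cannot build an environment from {value!r}")


def load_config(source: str | Path | Mapping[str, Any]) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from a mapping or YAML/JSON file.

    Every parameter absent from the input is filled with its default value.
    Unknown keys are rejected with a :class:`ConfigError` naming the key, as
    are out-of-range values.

    The mapping accepts, besides any :class:`SimulationConfig` field name:

    - ``environment``: ``"poor"``/``"rich"`` or a partial mapping,
    - ``strategy_pair``: ``[spillover-variant, "MFCL"]`` (or just the
      spillover variant name) selecting which pair of strategies competes.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        mapping = yaml.safe_load(text) or {}
    else:
        mapping = dict(source)
    if not isinstance(mapping, Mapping):
        raise ConfigError("config file must contain a mapping at top level")
    mapping = dict(mapping)

    kwargs: dict[str, Any] = {}
    if "environment" in mapping:
        kwargs["environment"] = _build_environment(mapping.pop("environment"))
    if "strategy_pair" in mapping:
        pair = mapping.pop("strategy_pair")
        if isinstance(pair, str):
            pair = [pair, "MFCL"]
        if len(pair) != 2:
            raise ConfigError("strategy_pair must be [spillover_variant, MFCL]")
        kwargs["spillover_strategy"] = _build_strategy(pair[0], "strategy_pair[0]")
        kwargs["mfcl_strategy"] = _build_strategy(pair[1], "strategy_pair[1]")
    if "spillover_strategy" in mapping:
        kwargs["spillover_strategy"] = _build_strategy(
            mapping.pop("spillover_strategy"), "spillover_strategy"
        )
    if "mfcl_strategy" in mapping:
        kwargs["mfcl_strategy"] = _build_strategy(mapping.pop("mfcl_strategy"), "mfcl_strategy")

    unknown = set(mapping) - _TOP_LEVEL_SIMPLE
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs.update(mapping)

    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg
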