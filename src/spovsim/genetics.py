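"""Sex-linked single-locus inheritance on an XX (female) / X0 (male) system.

The aggression locus sits on the X chromosome and carries one of two alleles:
``S`` (spillover family) or ``M`` (MFCL).  Females are diploid at the locus,
males hemizygous pure carriers with no phenotype of their own.  Female
phenotype follows configurable dominance; a heterozygote expresses the
dominant allele's strategy.

Alleles are encoded as small integers so that population-scale bookkeeping
can live in numpy arrays: ``M = 0``, ``S = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ALLELE_M",
    "ALLELE_S",
    "FemaleGenotype",
    "MaleGenotype",
    "allele_label",
    "female_phenotype",
    "phenotype_codes",
    "make_offspring",
    "allele_frequency",
    "allele_frequency_arrays",
    "female_allele_frequency",
]

ALLELE_M: int = 0  #: MFCL allele
ALLELE_S: int = 1  #: spillover-family allele

_LABELS = {ALLELE_M: "M", ALLELE_S: "S"}
_CODES = {"M": ALLELE_M, "S": ALLELE_S, ALLELE_M: ALLELE_M, ALLELE_S: ALLELE_S}


def allele_label(code: int) -> str:
    return _LABELS[int(code)]


def _as_code(allele: int | str) -> int:
    try:
        return _CODES[allele]
    except KeyError:
        raise ValueError(f"unknown allele {allele!r}; expected 'S'/'M' or 0/1") from None


@dataclass(frozen=True)
class FemaleGenotype:
    """Unordered diploid genotype at the X-linked aggression locus."""

    allele_1: int
    allele_2: int

    def __post_init__(self):
        object.__setattr__(self, "allele_1", _as_code(self.allele_1))
        object.__setattr__(self, "allele_2", _as_code(self.allele_2))

    def __eq__(self, other):  # order-insensitive: Sm == mS
        if not isinstance(other, FemaleGenotype):
            return NotImplemented
        return frozenset((self.allele_1, self.allele_2)) == frozenset(
            (other.allele_1, other.allele_2)
        ) and (self.allele_1 + self.allele_2) == (other.allele_1 + other.allele_2)

    def __hash__(self):
        return hash((min(self.allele_1, self.allele_2), max(self.allele_1, self.allele_2)))

    @property
    def n_spillover(self) -> int:
        return (self.allele_1 == ALLELE_S) + (self.allele_2 == ALLELE_S)

    def __repr__(self):
        return f"FemaleGenotype({allele_label(self.allele_1)}{allele_label(self.allele_2)})"


@dataclass(frozen=True)
class MaleGenotype:
    """Hemizygous male genotype: a single X-borne allele."""

    allele: int

    def __post_init__(self):
        object.__setattr__(self, "allele", _as_code(self.allele))

    def __repr__(self):
        return f"MaleGenotype({allele_label(self.allele)})"


def female_phenotype(genotype: FemaleGenotype, dominance: str) -> str:
    """Map a female genotype to ``"spillover"`` or ``"mfcl"`` under dominance.

    Homozygotes express their own allele's strategy; the heterozygote
    expresses the strategy of whichever allele is configured dominant.
    """
    if dominance not in ("spillover", "mfcl"):
        raise ValueError(f"dominance must be 'spillover' or 'mfcl', got {dominance!r}")
    n_s = genotype.n_spillover
    if n_s == 2:
        return "spillover"
    if n_s == 0:
        return "mfcl"
    return "spillover" if dominance == "spillover" else "mfcl"


def phenotype_codes(allele_1: np.ndarray, allele_2: np.ndarray, dominance: str) -> np.ndarray:
    """Vectorized phenotype map: 1 = spillover family, 0 = MFCL."""
    n_s = allele_1.astype(np.int64) + allele_2.astype(np.int64)
    if dominance == "spillover":
        return (n_s >= 1).astype(np.int8)
    if dominance == "mfcl":
        return (n_s == 2).astype(np.int8)
    raise ValueError(f"dominance must be 'spillover' or 'mfcl', got {dominance!r}")


def make_offspring(
    mother: FemaleGenotype, father_allele: int | str, rng: np.random.Generator
) -> tuple[str, FemaleGenotype | MaleGenotype]:
    """Draw one offspring: sex with probability 1/2 each, Mendelian segregation.

    A daughter receives one uniformly chosen maternal allele plus the paternal
    allele (the father's only X always goes to daughters under XX/X0); a son
    receives one uniformly chosen maternal allele and nothing paternal.
    """
    father = _as_code(father_allele)
    is_female = rng.random() < 0.5
    maternal = mother.allele_1 if rng.random() < 0.5 else mother.allele_2
    if is_female:
        return "female", FemaleGenotype(maternal, father)
    return "male", MaleGenotype(maternal)


def _copies(females, males) -> tuple[int, int]:
    s_copies = 0
    total = 0
    for f in females:
        g = f.genotype if hasattr(f, "genotype") else f
        s_copies += g.n_spillover
        total += 2
    for m in males:
        g = m.genotype if hasattr(m, "genotype") else m
        s_copies += g.allele == ALLELE_S
        total += 1
    return s_copies, total


def allele_frequency(females: Iterable, males: Iterable) -> float:
    """Frequency p of the spillover allele over all adult X copies.

    Each female contributes two copies and each male one, so the default
    denominator over 500 + 500 adults is 1500 copies.  Accepts either
    genotype objects or individuals exposing a ``genotype`` attribute.
    """
    s_copies, total = _copies(females, males)
    if total == 0:
        raise ValueError("allele frequency undefined for an empty population")
    return s_copies / total


def allele_frequency_arrays(
    f_allele_1: np.ndarray, f_allele_2: np.ndarray, m_allele: np.ndarray
) -> float:
    """Array form of :func:`allele_frequency` used by the generation loop."""
    total = 2 * f_allele_1.size + m_allele.size
    if total == 0:
        raise ValueError("allele frequency undefined for an empty population")
    s = int(f_allele_1.sum()) + int(f_allele_2.sum()) + int(m_allele.sum())
    return s / total


def female_allele_frequency(f_allele_1: np.ndarray, f_allele_2: np.ndarray) -> float:
    """Spillover allele frequency counted over female X copies only."""
    if f_allele_1.size == 0:
        raise ValueError("allele frequency undefined for an empty population")
    return (int(f_allele_1.sum()) + int(f_allele_2.sum())) / (2 * f_allele_1.size)
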