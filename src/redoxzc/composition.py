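"""Elemental and amino-acid composition arithmetic.

The central quantity is the average oxidation state of carbon,

    Z_C = (-h + 3n + 2o + 2s) / c

for a molecule with elemental composition C_c H_h N_n O_o S_s.  Formal
charge does not enter the formula.  For proteins and proteomes, Z_C is
computed from the amino-acid composition as the carbon-weighted mean of
the per-amino-acid Z_C values, which is algebraically identical to
applying the formula to the summed elemental composition: peptide-bond
water carries no carbon and contributes -h + 2o = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "FREE_AA_FORMULAS",
    "AA_ZC",
    "ElementalFormula",
    "AminoAcidTally",
    "zc_from_formula",
    "formula_from_tally",
    "zc_from_tally",
    "normalize_per_residue",
]

#: Canonical one-letter codes, alphabetical; fixed column order everywhere.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residues silently absent from the canonical 20; dropped with a logged count.
AMBIGUOUS_RESIDUES = frozenset("BJZXUO*")


class UndefinedMetricError(ValueError):
    """Raised when Z_C is requested for a carbon-free composition."""


@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition C_c H_h N_n O_o S_s with formal charge ``z``.

    Counts may be fractional (mean compositions).  All counts must be
    non-negative and at least one element must be present.
    """

    c: float = 0.0
    h: float = 0.0
    n: float = 0.0
    o: float = 0.0
    s: float = 0.0
    z: float = 0.0

    def __post_init__(self) -> None:
        counts = (self.c, self.h, self.n, self.o, self.s)
        if any(x < 0 for x in counts):
            raise ValueError(f"negative element count in {self}")
        if not any(x > 0 for x in counts):
            raise ValueError("formula must contain at least one atom")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            self.c + other.c, self.h + other.h, self.n + other.n,
            self.o + other.o, self.s + other.s, self.z + other.z,
        )

    def scaled(self, k: float) -> "ElementalFormula":
        return ElementalFormula(
            self.c * k, self.h * k, self.n * k, self.o * k, self.s * k, self.z * k
        )

    def as_vector(self) -> np.ndarray:
        """(c, h, n, o, s, z) as a float array, the order used in reaction balancing."""
        return np.array([self.c, self.h, self.n, self.o, self.s, self.z], float)


#: Free (neutral, unpolymerized) formulas of the 20 canonical amino acids.
FREE_AA_FORMULAS: dict[str, ElementalFormula] = {
    "A": ElementalFormula(3, 7, 1, 2, 0),
    "C": ElementalFormula(3, 7, 1, 2, 1),
    "D": ElementalFormula(4, 7, 1, 4, 0),
    "E": ElementalFormula(5, 9, 1, 4, 0),
    "F": ElementalFormula(9, 11, 1, 2, 0),
    "G": ElementalFormula(2, 5, 1, 2, 0),
    "H": ElementalFormula(6, 9, 3, 2, 0),
    "I": ElementalFormula(6, 13, 1, 2, 0),
    "K": ElementalFormula(6, 14, 2, 2, 0),
    "L": ElementalFormula(6, 13, 1, 2, 0),
    "M": ElementalFormula(5, 11, 1, 2, 1),
    "N": ElementalFormula(4, 8, 2, 3, 0),
    "P": ElementalFormula(5, 9, 1, 2, 0),
    "Q": ElementalFormula(5, 10, 2, 3, 0),
    "R": ElementalFormula(6, 14, 4, 2, 0),
    "S": ElementalFormula(3, 7, 1, 3, 0),
    "T": ElementalFormula(4, 9, 1, 3, 0),
    "V": ElementalFormula(5, 11, 1, 2, 0),
    "W": ElementalFormula(11, 12, 2, 2, 0),
    "Y": ElementalFormula(9, 11, 1, 3, 0),
}

WATER = ElementalFormula(0, 2, 0, 1, 0)

# Per-amino-acid element matrices in AMINO_ACIDS order, for vectorized sums.
_AA_MATRIX = np.array(
    [FREE_AA_FORMULAS[a].as_vector() for a in AMINO_ACIDS]
)  # shape (20, 6)

#: Carbon atoms per amino acid, AMINO_ACIDS order.
AA_CARBON: np.ndarray = _AA_MATRIX[:, 0].copy()


def zc_from_formula(f: ElementalFormula) -> float:
    """Average oxidation state of carbon of an elemental formula.

    Charge is ignored: the metric is defined from element counts only.
    """
    if f.c <= 0:
        raise UndefinedMetricError("Z_C is undefined for a carbon-free formula")
    return (-f.h + 3.0 * f.n + 2.0 * f.o + 2.0 * f.s) / f.c


#: Z_C of each free amino acid, AMINO_ACIDS order.
AA_ZC: np.ndarray = np.array(
    [zc_from_formula(FREE_AA_FORMULAS[a]) for a in AMINO_ACIDS]
)


@dataclass
class AminoAcidTally:
    """Quantities of the 20 canonical amino acids; fractional values allowed.

    Internally a length-20 vector in ``AMINO_ACIDS`` (alphabetical one-letter)
    order.  Means over proteins or species are naturally fractional.
    """

    counts: np.ndarray = field(default_factory=lambda: np.zeros(20))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (20,):
            raise ValueError("tally must have exactly 20 entries")
        if np.any(self.counts < 0):
            raise ValueError("tally entries must be non-negative")

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "AminoAcidTally":
        vec = np.zeros(20)
        for aa, q in counts.items():
            idx = AMINO_ACIDS.find(aa.upper())
            if idx < 0:
                raise KeyError(f"unknown amino acid code {aa!r}")
            vec[idx] += q
        return cls(vec)

    @classmethod
    def from_sequence(cls, seq: str) -> "AminoAcidTally":
        """Tally a protein sequence; ambiguous codes (B, J, Z, X, U, O) are
        dropped with a logged count."""
        vec = np.zeros(20)
        dropped = 0
        for ch in seq.upper():
            idx = AMINO_ACIDS.find(ch)
            if idx >= 0:
                vec[idx] += 1
            elif ch in AMBIGUOUS_RESIDUES:
                dropped += 1
            elif not ch.isspace():
                raise ValueError(f"unexpected residue code {ch!r}")
        if dropped:
            logger.info("dropped %d ambiguous residues from sequence", dropped)
        return cls(vec)

    @property
    def n_residues(self) -> float:
        return float(self.counts.sum())

    def as_dict(self) -> dict[str, float]:
        return {a: float(q) for a, q in zip(AMINO_ACIDS, self.counts)}

    def __add__(self, other: "AminoAcidTally") -> "AminoAcidTally":
        return AminoAcidTally(self.counts + other.counts)

    def scaled(self, k: float) -> "AminoAcidTally":
        if k < 0:
            raise ValueError("scale factor must be non-negative")
        return AminoAcidTally(self.counts * k)


def mean_tally(tallies: Iterable[AminoAcidTally]) -> AminoAcidTally:
    """Unweighted arithmetic mean of tallies (equal weight per member)."""
    mat = np.array([t.counts for t in tallies])
    if mat.size == 0:
        raise ValueError("cannot average an empty collection of tallies")
    return AminoAcidTally(mat.mean(axis=0))


def formula_from_tally(t: AminoAcidTally, polymerized: bool = False) -> ElementalFormula:
    """Elemental formula of a tally of free amino acids.

    With ``polymerized=True``, (n_residues - 1) waters are removed to account
    for peptide-bond condensation.  Water removal never changes Z_C.
    """
    n = t.n_residues
    if n <= 0:
        raise ValueError("empty tally has no elemental formula")
    vec = t.counts @ _AA_MATRIX
    if polymerized:
        vec = vec - (n - 1.0) * WATER.as_vector()
    return ElementalFormula(*vec)


def zc_from_tally(t: AminoAcidTally) -> float:
    """Carbon-weighted mean of per-amino-acid Z_C values.

    Identical to ``zc_from_formula(formula_from_tally(t))`` for either
    polymerization convention.
    """
    if t.n_residues <= 0:
        raise ValueError("empty tally has no Z_C")
    carbons = t.counts * AA_CARBON
    total_c = carbons.sum()
    if total_c <= 0:
        raise UndefinedMetricError("tally contains no carbon")
    return float((carbons * AA_ZC).sum() / total_c)


def normalize_per_residue(t: AminoAcidTally) -> AminoAcidTally:
    """Rescale so the entries sum to 1 (one formula unit per residue)."""
    n = t.n_residues
    if n <= 0:
        raise ValueError("cannot normalize an empty tally")
    return t.scaled(1.0 / n)
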