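"""Peptide mass arithmetic and isotope envelopes.

Covers elemental composition bookkeeping, monoisotopic masses, protonated
m/z, interpeptide disulfide masses, electron-transfer-dissociation (ETD)
fragment masses of disulfide precursors, and aggregated-isotopologue
envelope prediction for light/heavy carbamidomethylated peptides.

Masses are monoisotopic throughout.  The atomic mass table is fixed here as
module constants so every printed value downstream is reproducible to four
decimals; labeled isotopes (``13C``, ``D``) are distinct symbols in a
composition and are treated as isotopically pure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import (
    ChargeError,
    ModificationError,
    NoCysteineError,
    UnknownElementError,
    UnknownResidueError,
)

__all__ = [
    "ElementalComposition",
    "Modification",
    "Peptide",
    "IsotopeEnvelope",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "HYDROGEN_MASS",
    "ISOTOPE_SPACING",
    "NAMED_MODIFICATIONS",
    "elemental_composition",
    "monoisotopic_mass",
    "peptide_mass",
    "peptide_mz",
    "disulfide_mass",
    "disulfide_mz",
    "etd_disulfide_fragments",
    "isotope_distribution",
]

# Monoisotopic (lightest-isotope) masses, Da.  13C and D are enriched labels
# carried as their own symbols so labeled compositions stay element-wise.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.007825,
    "C": 12.000000,
    "13C": 13.003355,
    "D": 2.014102,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
}

PROTON_MASS = 1.007276
#: Mass of a hydrogen atom as used in disulfide / ETD arithmetic.
HYDROGEN_MASS = 1.00783
#: Mean spacing between adjacent aggregated isotopologue peaks, Da.
ISOTOPE_SPACING = 1.00336

# Natural isotope abundance vectors at unit nominal-mass offsets from the
# lightest isotope.  Enriched labels are pure by construction.
ISOTOPE_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "13C": (1.0,),
    "D": (1.0,),
}


@dataclass(frozen=True)
class ElementalComposition:
    """Multiset of element (or labeled-isotope) counts.

    Addition and subtraction are element-wise; subtraction below zero is a
    bookkeeping bug and raises ``ValueError``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for symbol, n in self.counts.items():
            if symbol not in MONOISOTOPIC_MASS:
                raise UnknownElementError(f"unknown element symbol: {symbol!r}")
            if n < 0:
                raise ValueError(f"negative count for {symbol}: {n}")
            if n > 0:
                clean[symbol] = int(n)
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for symbol, n in other.counts.items():
            merged[symbol] = merged.get(symbol, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for symbol, n in other.counts.items():
            merged[symbol] = merged.get(symbol, 0) - n
            if merged[symbol] < 0:
                raise ValueError(f"subtraction yields negative {symbol} count")
        return ElementalComposition(merged)

    def __getitem__(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)


def _comp(formula: Mapping[str, int]) -> ElementalComposition:
    return ElementalComposition(formula)


WATER = _comp({"H": 2, "O": 1})

# Residue (minus-water) compositions of the 20 standard amino acids.
RESIDUE_COMPOSITION: dict[str, ElementalComposition] = {
    "G": _comp({"C": 2, "H": 3, "N": 1, "O": 1}),
    "A": _comp({"C": 3, "H": 5, "N": 1, "O": 1}),
    "S": _comp({"C": 3, "H": 5, "N": 1, "O": 2}),
    "P": _comp({"C": 5, "H": 7, "N": 1, "O": 1}),
    "V": _comp({"C": 5, "H": 9, "N": 1, "O": 1}),
    "T": _comp({"C": 4, "H": 7, "N": 1, "O": 2}),
    "C": _comp({"C": 3, "H": 5, "N": 1, "O": 1, "S": 1}),
    "L": _comp({"C": 6, "H": 11, "N": 1, "O": 1}),
    "I": _comp({"C": 6, "H": 11, "N": 1, "O": 1}),
    "N": _comp({"C": 4, "H": 6, "N": 2, "O": 2}),
    "D": _comp({"C": 4, "H": 5, "N": 1, "O": 3}),
    "Q": _comp({"C": 5, "H": 8, "N": 2, "O": 2}),
    "K": _comp({"C": 6, "H": 12, "N": 2, "O": 1}),
    "E": _comp({"C": 5, "H": 7, "N": 1, "O": 3}),
    "M": _comp({"C": 5, "H": 9, "N": 1, "O": 1, "S": 1}),
    "H": _comp({"C": 6, "H": 7, "N": 3, "O": 1}),
    "F": _comp({"C": 9, "H": 9, "N": 1, "O": 1}),
    "R": _comp({"C": 6, "H": 12, "N": 4, "O": 1}),
    "Y": _comp({"C": 9, "H": 9, "N": 1, "O": 2}),
    "W": _comp({"C": 11, "H": 10, "N": 2, "O": 1}),
}


@dataclass(frozen=True)
class Modification:
    """A named composition delta attached to one residue position.

    ``target_residue`` restricts placement (e.g. carbamidomethylation sits on
    cysteine); ``None`` allows any position.
    """

    name: str
    composition_delta: ElementalComposition
    target_residue: str | None = None


#: Shipped named modifications.  The heavy carbamidomethyl reagent carries
#: two 13C and two D (iodoacetamide-13C2,2-D2), +4.0193 Da vs the light form.
NAMED_MODIFICATIONS: dict[str, Modification] = {
    "cam": Modification(
        "cam", _comp({"C": 2, "H": 3, "N": 1, "O": 1}), target_residue="C"
    ),
    "heavy-cam": Modification(
        "heavy-cam",
        _comp({"13C": 2, "H": 1, "D": 2, "N": 1, "O": 1}),
        target_residue="C",
    ),
}


@dataclass(frozen=True)
class Peptide:
    """A peptide: one-letter sequence plus positioned modifications.

    ``modifications`` is a tuple of ``(Modification, position)`` with 1-based
    residue positions.
    """

    sequence: str
    modifications: tuple[tuple[Modification, int], ...] = ()

    def __post_init__(self):
        if not self.sequence:
            raise UnknownResidueError("empty sequence")
        for letter in self.sequence:
            if letter not in RESIDUE_COMPOSITION:
                raise UnknownResidueError(f"unknown residue letter: {letter!r}")
        for mod, pos in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ModificationError(
                    f"modification {mod.name} position {pos} outside 1..{len(self.sequence)}"
                )
            residue = self.sequence[pos - 1]
            if mod.target_residue is not None and residue != mod.target_residue:
                raise ModificationError(
                    f"modification {mod.name} targets {mod.target_residue} "
                    f"but position {pos} is {residue}"
                )

    def with_modification(self, name: str, position: int) -> "Peptide":
        """Return a copy with the named modification added at ``position``."""
        if name not in NAMED_MODIFICATIONS:
            raise ModificationError(f"unknown modification: {name!r}")
        mods = self.modifications + ((NAMED_MODIFICATIONS[name], position),)
        return dataclasses.replace(self, modifications=mods)

    def free_cysteines(self) -> list[int]:
        """1-based positions of cysteines not claimed by a cysteine-targeted mod."""
        modified = {
            pos for mod, pos in self.modifications if mod.target_residue == "C"
        }
        return [
            i + 1
            for i, letter in enumerate(self.sequence)
            if letter == "C" and (i + 1) not in modified
        ]

    @classmethod
    def parse(cls, text: str) -> "Peptide":
        """Parse ``"CQPPPPPMK cam@1 heavy-cam@5"`` style strings."""
        parts = text.split()
        if not parts:
            raise UnknownResidueError("empty peptide string")
        peptide = cls(parts[0])
        for token in parts[1:]:
            name, _, pos = token.partition("@")
            if not pos:
                raise ModificationError(f"modification token {token!r} lacks '@position'")
            peptide = peptide.with_modification(name, int(pos))
        return peptide


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Theoretical isotopologue peaks of one charge state.

    ``mz`` is strictly increasing with the monoisotopic peak first;
    ``relative_intensity`` sums to 1 over the retained peaks.
    """

    mz: np.ndarray
    relative_intensity: np.ndarray
    charge: int
    monoisotopic_mz: float

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.relative_intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1 or mz.size == 0:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("envelope m/z values must be strictly increasing")
        if np.any(inten < 0) or abs(inten.sum() - 1.0) > 1e-6:
            raise ValueError("intensities must be non-negative and sum to 1")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "relative_intensity", inten)


def elemental_composition(peptide: Peptide) -> ElementalComposition:
    """Residue compositions + one water + all modification deltas."""
    total = WATER
    for letter in peptide.sequence:
        total = total + RESIDUE_COMPOSITION[letter]
    for mod, _pos in peptide.modifications:
        total = total + mod.composition_delta
    return total


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Sum of count x lightest-isotope (or labeled-isotope) mass, Da."""
    return sum(
        n * MONOISOTOPIC_MASS[symbol] for symbol, n in composition.counts.items()
    )


def peptide_mass(peptide: Peptide) -> float:
    """Monoisotopic neutral mass of a (possibly modified) peptide, Da."""
    return monoisotopic_mass(elemental_composition(peptide))


def _mz(neutral_mass: float, charge: int) -> float:
    if charge < 1:
        raise ChargeError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def peptide_mz(peptide: Peptide, charge: int) -> float:
    """Protonated monoisotopic m/z: (M + z * proton) / z."""
    return _mz(peptide_mass(peptide), charge)


def disulfide_mass(p1: Peptide, p2: Peptide) -> float:
    """Neutral mass of the interpeptide disulfide: M1 + M2 - 2 H.

    Each peptide must carry at least one cysteine not already blocked by a
    cysteine-targeted modification; S-S formation removes one hydrogen from
    each thiol.  Symmetric in its arguments.
    """
    for peptide in (p1, p2):
        if not peptide.free_cysteines():
            raise NoCysteineError(
                f"peptide {peptide.sequence} has no unmodified cysteine"
            )
    return peptide_mass(p1) + peptide_mass(p2) - 2 * HYDROGEN_MASS


def disulfide_mz(p1: Peptide, p2: Peptide, charge: int) -> float:
    """Protonated m/z of the interpeptide disulfide at the given charge."""
    return _mz(disulfide_mass(p1, p2), charge)


@dataclass(frozen=True)
class EtdFragmentAssignment:
    """One of the two ways ETD S-S cleavage partitions H between products.

    The even-electron thiol fragment gains one hydrogen; the radical
    fragment keeps the bare peptide mass.
    """

    thiol_peptide: str
    thiol_neutral_mass: float
    radical_peptide: str
    radical_neutral_mass: float


def etd_disulfide_fragments(
    p1: Peptide, p2: Peptide
) -> tuple[EtdFragmentAssignment, EtdFragmentAssignment]:
    """Both thiol/radical mass assignments for ETD cleavage of a disulfide.

    Electron-transfer dissociation preferentially cleaves the S-S bond,
    producing a thiol fragment (peptide + 1.00783 Da) and a sulfanyl radical
    fragment (bare peptide mass); either peptide can take either role.
    """
    for peptide in (p1, p2):
        if not peptide.free_cysteines():
            raise NoCysteineError(
                f"peptide {peptide.sequence} has no unmodified cysteine"
            )
    m1, m2 = peptide_mass(p1), peptide_mass(p2)
    return (
        EtdFragmentAssignment(p1.sequence, m1 + HYDROGEN_MASS, p2.sequence, m2),
        EtdFragmentAssignment(p2.sequence, m2 + HYDROGEN_MASS, p1.sequence, m1),
    )


def isotope_distribution(
    composition: ElementalComposition, charge: int, max_peaks: int = 6
) -> IsotopeEnvelope:
    """Aggregated isotopologue envelope by per-element convolution.

    Convolves each element's natural-abundance vector ``count`` times at unit
    nominal-mass spacing (no fine structure), truncates to ``max_peaks``,
    renormalizes, and places peak k at ``monoisotopic_mz + k * 1.00336 / z``.
    """
    if charge < 1:
        raise ChargeError(f"charge must be >= 1, got {charge}")
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    dist = np.array([1.0])
    for symbol, count in composition.counts.items():
        if symbol not in ISOTOPE_ABUNDANCE:
            raise UnknownElementError(f"no isotope data for {symbol!r}")
        element_vec = np.asarray(ISOTOPE_ABUNDANCE[symbol], dtype=float)
        for _ in range(count):
            dist = np.convolve(dist, element_vec)
            # drop negligible high-mass tail to keep the convolution short
            if dist.size > max_peaks + 8:
                dist = dist[: max_peaks + 8]
    dist = dist[:max_peaks]
    dist = dist / dist.sum()
    mono_mz = _mz(monoisotopic_mass(composition), charge)
    mz = mono_mz + np.arange(dist.size) * (ISOTOPE_SPACING / charge)
    return IsotopeEnvelope(mz, dist, charge, mono_mz)
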