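"""Elemental-composition arithmetic, monoisotopic masses and ion m/z conventions.

Every mass printed by the rest of the package is derived here from an
:class:`ElementalComposition` and the embedded IUPAC monoisotopic atomic
masses.  Ion m/z values follow standard high-resolution practice: (de)protonation
shifts by the proton mass (1.007276 Da) and intrinsic cations (quaternary
ammonium species that carry their own charge) subtract one electron mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ElementalComposition",
    "Adduct",
    "Polarity",
    "IonDescriptor",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
]

# IUPAC 2021 monoisotopic atomic masses (most abundant isotope), Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "Br": 78.9183371,
}

PROTON_MASS = 1.007276466  # m(H) - m(e-)
ELECTRON_MASS = 0.00054857990

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """A multiset of element counts; the atom-level currency for mass arithmetic.

    Counts are non-negative integers.  Addition and subtraction are
    element-wise; subtraction that would drive any count negative raises
    ``ValueError``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {el} must be a non-negative integer, got {n!r}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise ValueError(
                    f"subtraction would give negative count for {el}: {merged.get(el, 0)} - {n}"
                )
            merged[el] = left
        return ElementalComposition(merged)

    def scaled(self, k: int) -> "ElementalComposition":
        if k < 0:
            raise ValueError("scale factor must be non-negative")
        return ElementalComposition({el: n * k for el, n in self.counts.items()})

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return monoisotopic_mass(self)

    def formula(self) -> str:
        """Hill-order molecular formula (C, H, then alphabetical)."""
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        return "".join(f"{el}{self.counts[el] if self.counts[el] != 1 else ''}" for el in order)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.formula() or "(empty)"


def parse_formula(text: str) -> ElementalComposition:
    """Parse a molecular-formula string such as ``"C16H31N3O2"``.

    The empty string parses to the empty composition (mass 0).  Unknown
    element symbols or malformed text raise ``ValueError`` naming the
    offending token.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r}: unexpected {text[pos:m.start()]!r}")
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"malformed formula {text!r}: unknown element {el!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r}: unexpected {text[pos:]!r}")
    return ElementalComposition(counts)


def monoisotopic_mass(comp: ElementalComposition | Mapping[str, int]) -> float:
    """Monoisotopic mass in Da: sum of count x atomic monoisotopic mass."""
    counts = comp.counts if isinstance(comp, ElementalComposition) else comp
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


class Adduct(Enum):
    """Ionization rule relating a neutral (or pre-charged) species to its ion."""

    PROTONATED = "[M+H]+"
    DEPROTONATED = "[M-H]-"
    INTRINSIC_CATION = "[M]+"


class Polarity(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


_ADDUCT_POLARITY = {
    Adduct.PROTONATED: Polarity.POSITIVE,
    Adduct.DEPROTONATED: Polarity.NEGATIVE,
    Adduct.INTRINSIC_CATION: Polarity.POSITIVE,
}


@dataclass(frozen=True)
class IonDescriptor:
    """A neutral (or intrinsically charged) composition plus its adduct rule."""

    composition: ElementalComposition
    adduct: Adduct
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge <= 0:
            raise ValueError("charge magnitude must be a positive integer")

    @property
    def polarity(self) -> Polarity:
        return _ADDUCT_POLARITY[self.adduct]

    @property
    def mz(self) -> float:
        return ion_mz(self)


def ion_mz(ion: IonDescriptor) -> float:
    """m/z of an ion under the fixed conventions.

    [M+H]+ = M + 1.007276; [M-H]- = M - 1.007276; intrinsic [M]+ subtracts one
    electron mass.  For charge z the shift applies z times and the result is
    divided by z.
    """
    m = monoisotopic_mass(ion.composition)
    z = ion.charge
    if ion.adduct is Adduct.PROTONATED:
        mz = (m + z * PROTON_MASS) / z
    elif ion.adduct is Adduct.DEPROTONATED:
        mz = (m - z * PROTON_MASS) / z
    else:  # intrinsic cation: composition written as the neutral radical formula
        mz = (m - z * ELECTRON_MASS) / z
    if mz <= 0:
        raise ValueError("non-positive m/z")
    return mz
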