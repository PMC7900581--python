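"""Propargyl-lipid species enumeration, clicked-product ions and diagnostic fragments.

The species space covers choline phospholipids whose head group carries a
propargyl (terminal-alkyne) moiety in place of one N-methyl: diacyl pPC, its
ether pendant pPC O, the lyso forms LpPC / LpPC O, and propargyl sphingomyelin
pSM, together with the unlabeled parent classes used for internal standards.
Sum compositions follow backbone arithmetic validated against standard lipid
mass tables: a diacyl PC with C radyl carbons and D double bonds is
C(C+8) H(2C-2D+16) N O8 P; ether classes exchange one ester oxygen for two
hydrogens; lyso classes lack one chain; the propargyl head group adds exactly
C2 (propargyl replaces an N-methyl).

A :class:`ReporterDefinition` describes a click (CuAAC) azide reporter: the
cycloaddition adds the reporter's full composition to the alkyne lipid, and on
collisional activation the clicked product loses a reporter-diagnostic neutral
(the triazole-palmitate neutral C19H33N3O2, 335.2573 Da, for azidopalmitate;
C4H11N, 73.0891 Da, for the quaternary-ammonium C171 reporter).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .chem import (
    Adduct,
    ElementalComposition,
    IonDescriptor,
    Polarity,
    PROTON_MASS,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "LipidClass",
    "FattyAcyl",
    "SumSpecies",
    "Subspecies",
    "ReporterDefinition",
    "InternalStandard",
    "N3PAL",
    "C171",
    "species_composition",
    "clicked_precursor",
    "nl_fragment_mz",
    "fa_fragment_mz",
    "enumerate_species",
    "enumerate_subspecies",
    "export_db",
    "import_db",
    "DEFAULT_SPECIES_C_RANGE",
    "DEFAULT_SPECIES_D_RANGE",
    "DEFAULT_ACYL_C_RANGE",
    "DEFAULT_ACYL_D_RANGE",
]

# Default search space: covers every species reported for LpPC-labeled cells
# with margin on both ends.
DEFAULT_SPECIES_C_RANGE = (28, 44)
DEFAULT_SPECIES_D_RANGE = (0, 8)
DEFAULT_ACYL_C_RANGE = (12, 26)
DEFAULT_ACYL_D_RANGE = (0, 6)


class LipidClass(Enum):
    """Choline-phospholipid classes, propargyl-labeled and unlabeled."""

    PPC = "pPC"
    PPC_O = "pPC O"
    LPPC = "LpPC"
    LPPC_O = "LpPC O"
    PSM = "pSM"
    PC = "PC"
    PC_O = "PC O"
    SM = "SM"

    @property
    def is_propargyl(self) -> bool:
        return self in (LipidClass.PPC, LipidClass.PPC_O, LipidClass.LPPC,
                        LipidClass.LPPC_O, LipidClass.PSM)

    @property
    def is_ether(self) -> bool:
        return self in (LipidClass.PPC_O, LipidClass.LPPC_O, LipidClass.PC_O)

    @property
    def is_lyso(self) -> bool:
        return self in (LipidClass.LPPC, LipidClass.LPPC_O)

    @property
    def is_sphingo(self) -> bool:
        return self in (LipidClass.PSM, LipidClass.SM)

    @property
    def is_diradyl(self) -> bool:
        return not self.is_lyso

    @property
    def n_fa_fragments(self) -> int:
        """Carboxylate fragments observable per subspecies in negative mode.

        Diacyl species release both chains; ether species release only the
        sn-2 acyl (the sn-1 alkyl has no carboxylate); sphingo species release
        only the amide-linked acyl; lyso species carry a single chain.
        """
        if self.is_lyso:
            return 1
        if self.is_ether or self.is_sphingo:
            return 1
        return 2

    @classmethod
    def from_name(cls, name: str) -> "LipidClass":
        for member in cls:
            if member.value == name:
                return member
        raise ValueError(f"unknown lipid class {name!r}")


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty acyl (or, in ether/sphingo context, a radyl chain): carbons and double bonds."""

    c: int
    d: int

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError(f"acyl must have at least 2 carbons, got {self.c}")
        if not (0 <= self.d <= (self.c - 1) // 2):
            raise ValueError(f"FA {self.c}:{self.d} has an impossible double-bond count")

    @property
    def name(self) -> str:
        return f"{self.c}:{self.d}"

    @classmethod
    def from_name(cls, name: str) -> "FattyAcyl":
        c, d = name.replace("FA", "").strip().split(":")
        return cls(int(c), int(d))

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class SumSpecies:
    """A lipid at sum-composition level: class, total radyl carbons, total double bonds."""

    lipid_class: LipidClass
    c: int
    d: int

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError(f"{self.lipid_class.value} {self.c}:{self.d}: no radyl carbons")
        if self.d < 0:
            raise ValueError("negative double-bond count")

    @property
    def name(self) -> str:
        return f"{self.lipid_class.value} {self.c}:{self.d}"

    @classmethod
    def from_name(cls, name: str) -> "SumSpecies":
        head, cd = name.rsplit(" ", 1)
        c, d = cd.split(":")
        return cls(LipidClass.from_name(head), int(c), int(d))

    @property
    def composition(self) -> ElementalComposition:
        return species_composition(self)

    def __str__(self) -> str:
        return self.name

    # deterministic sort key used for report ordering
    @property
    def sort_key(self) -> tuple:
        return (self.lipid_class.value, self.c, self.d)


@dataclass(frozen=True)
class Subspecies:
    """A diradyl species resolved into its two chains.

    For diacyl classes the pair is unordered and stored canonically with
    ``fa1 <= fa2`` by (c, d).  For ether and sphingo classes ``fa1`` is the
    non-acyl chain (sn-1 alkyl or sphingoid base) and ``fa2`` the observable
    acyl, so the pair is ordered and not canonicalized.
    """

    parent: SumSpecies
    fa1: FattyAcyl
    fa2: FattyAcyl

    def __post_init__(self) -> None:
        cls = self.parent.lipid_class
        if cls.is_lyso:
            raise ValueError("lyso species have a single chain; no subspecies")
        if self.fa1.c + self.fa2.c != self.parent.c or self.fa1.d + self.fa2.d != self.parent.d:
            raise ValueError(
                f"chains {self.fa1}+{self.fa2} do not sum to {self.parent.name}"
            )
        if not (cls.is_ether or cls.is_sphingo) and self.fa1 > self.fa2:
            raise ValueError("diacyl subspecies must be canonical (fa1 <= fa2)")

    @property
    def is_homoacyl(self) -> bool:
        return self.fa1 == self.fa2

    @property
    def observable_fas(self) -> tuple[FattyAcyl, ...]:
        """Chains that yield a carboxylate fragment in negative mode."""
        if self.parent.lipid_class.n_fa_fragments == 1:
            return (self.fa2,)
        if self.is_homoacyl:
            return (self.fa1,)  # single shared peak
        return (self.fa1, self.fa2)

    @property
    def name(self) -> str:
        sep = "O-" if self.parent.lipid_class.is_ether else ""
        return f"{sep}{self.fa1.name}_{self.fa2.name}"

    def __str__(self) -> str:
        return f"{self.parent.name} [{self.name}]"


@dataclass(frozen=True)
class ReporterDefinition:
    """A click (CuAAC) azide reporter and its diagnostic fragmentation constants."""

    name: str
    composition: ElementalComposition  # atoms added to the lipid on cycloaddition
    polarity: Polarity
    precursor_adduct: Adduct
    neutral_loss: ElementalComposition  # diagnostic NL composition
    head_fragment_mzs: tuple[float, ...] = ()  # optional confirmatory constants

    @property
    def nl_mass(self) -> float:
        return monoisotopic_mass(self.neutral_loss)


# Azidopalmitate (16-azidohexadecanoic acid): negative-mode reporter.  The
# diagnostic NL is the triazole-palmitate neutral: reporter + the C3H2
# propargyl unit retained in the triazole ring.
N3PAL = ReporterDefinition(
    name="N3Pal",
    composition=parse_formula("C16H31N3O2"),
    polarity=Polarity.NEGATIVE,
    precursor_adduct=Adduct.DEPROTONATED,
    neutral_loss=parse_formula("C19H33N3O2"),  # 335.2573 Da
    head_fragment_mzs=(379.34,),
)

# Quaternary-ammonium reporter for positive mode; clicked products are
# intrinsic cations.  The exact reporter structure is configurable; the
# default composition C8H19N4 (cation m/z 171.1604, nominal +171) and NL
# C4H11N (73.0891 Da) reproduce its printed diagnostic masses.
C171 = ReporterDefinition(
    name="C171",
    composition=parse_formula("C8H19N4"),
    polarity=Polarity.POSITIVE,
    precursor_adduct=Adduct.INTRINSIC_CATION,
    neutral_loss=parse_formula("C4H11N"),  # 73.0891 Da
    head_fragment_mzs=(208.0733,),
)

REPORTERS = {"N3Pal": N3PAL, "C171": C171}

_PROPARGYL_EXTRA = ElementalComposition({"C": 2})  # propargyl replaces one N-methyl


def _choline_backbone(cls: LipidClass, c: int, d: int) -> ElementalComposition:
    h = 2 * c - 2 * d
    if cls in (LipidClass.PC, LipidClass.PPC):
        return ElementalComposition({"C": c + 8, "H": h + 16, "N": 1, "O": 8, "P": 1})
    if cls in (LipidClass.PC_O, LipidClass.PPC_O):
        return ElementalComposition({"C": c + 8, "H": h + 18, "N": 1, "O": 7, "P": 1})
    if cls is LipidClass.LPPC:
        return ElementalComposition({"C": c + 8, "H": h + 18, "N": 1, "O": 7, "P": 1})
    if cls is LipidClass.LPPC_O:
        return ElementalComposition({"C": c + 8, "H": h + 20, "N": 1, "O": 6, "P": 1})
    if cls in (LipidClass.SM, LipidClass.PSM):
        # dihydroxy sphingoid base; base double bond counted in d
        return ElementalComposition({"C": c + 5, "H": h + 13, "N": 2, "O": 6, "P": 1})
    raise ValueError(f"unsupported lipid class {cls!r}")


def species_composition(s: SumSpecies) -> ElementalComposition:
    """Molecular formula of a sum species from backbone arithmetic."""
    comp = _choline_backbone(s.lipid_class, s.c, s.d)
    if s.lipid_class.is_propargyl:
        comp = comp + _PROPARGYL_EXTRA
    return comp


def clicked_precursor(s: SumSpecies, reporter: ReporterDefinition) -> IonDescriptor:
    """The clicked-product precursor ion for a propargyl species.

    The cycloaddition adds the reporter's full composition; the ion follows
    the reporter's adduct rule ([M'-H]- for azidopalmitate, intrinsic [M']+
    for the quaternary-ammonium reporter).
    """
    if not s.lipid_class.is_propargyl:
        raise ValueError(f"{s.name} carries no alkyne to click")
    return IonDescriptor(species_composition(s) + reporter.composition,
                         reporter.precursor_adduct)


def nl_fragment_mz(precursor_mz: float, reporter: ReporterDefinition, charge: int = 1) -> float:
    """m/z of the diagnostic fragment after the reporter's neutral loss."""
    mz = precursor_mz - reporter.nl_mass / charge
    if mz <= 0:
        raise ValueError("neutral loss exceeds precursor m/z")
    return mz


def fa_fragment_mz(fa: FattyAcyl) -> float:
    """m/z of the deprotonated carboxylate fragment [CcH(2c-2d)O2 - H]-."""
    comp = ElementalComposition({"C": fa.c, "H": 2 * fa.c - 2 * fa.d, "O": 2})
    return monoisotopic_mass(comp) - PROTON_MASS


def enumerate_species(
    lipid_class: LipidClass,
    c_range: tuple[int, int] = DEFAULT_SPECIES_C_RANGE,
    d_range: tuple[int, int] = DEFAULT_SPECIES_D_RANGE,
    even_c_only: bool = False,
) -> list[SumSpecies]:
    """All sum species of a class in the given inclusive (C, D) ranges, ordered by (C, D)."""
    c_lo, c_hi = c_range
    d_lo, d_hi = d_range
    if c_lo > c_hi or d_lo > d_hi:
        raise ValueError("reversed enumeration range")
    out = []
    for c in range(c_lo, c_hi + 1):
        if even_c_only and c % 2:
            continue
        for d in range(d_lo, d_hi + 1):
            out.append(SumSpecies(lipid_class, c, d))
    return out


def enumerate_subspecies(
    s: SumSpecies,
    acyl_c_range: tuple[int, int] = DEFAULT_ACYL_C_RANGE,
    acyl_d_range: tuple[int, int] = DEFAULT_ACYL_D_RANGE,
) -> list[Subspecies]:
    """All chain pairs consistent with a diradyl sum species.

    Diacyl pairs are canonical (fa1 <= fa2); ether/sphingo pairs are ordered
    (non-acyl chain, acyl).  Within a species every observable FA fragment
    determines its subspecies uniquely, since the partner chain is fixed by
    the sum constraint.
    """
    cls = s.lipid_class
    if cls.is_lyso:
        raise ValueError(f"{s.name} is a lyso species; it has no chain pairs")
    c_lo, c_hi = acyl_c_range
    d_lo, d_hi = acyl_d_range
    if c_lo > c_hi or d_lo > d_hi:
        raise ValueError("reversed enumeration range")
    ordered_pair = cls.is_ether or cls.is_sphingo
    out: list[Subspecies] = []
    for c1 in range(c_lo, c_hi + 1):
        c2 = s.c - c1
        if not (c_lo <= c2 <= c_hi):
            continue
        for d1 in range(d_lo, d_hi + 1):
            d2 = s.d - d1
            if not (d_lo <= d2 <= d_hi):
                continue
            try:
                fa1, fa2 = FattyAcyl(c1, d1), FattyAcyl(c2, d2)
            except ValueError:
                continue
            if not ordered_pair and fa1 > fa2:
                continue  # canonical representative only
            out.append(Subspecies(s, fa1, fa2))
    out.sort(key=lambda ss: (ss.fa1.c, ss.fa1.d, ss.fa2.c, ss.fa2.d))
    return out


@dataclass(frozen=True)
class InternalStandard:
    """A spiked standard of known amount, optionally with an explicit acyl pair."""

    species: SumSpecies
    amount_pmol: float
    acyl_pair: tuple[FattyAcyl, FattyAcyl] | None = None

    def __post_init__(self) -> None:
        if self.amount_pmol <= 0:
            raise ValueError("internal-standard amount must be positive")

    @property
    def subspecies(self) -> Subspecies:
        if self.acyl_pair is None:
            raise ValueError(
                f"internal standard {self.species.name} has no explicit acyl pair; "
                "subspecies-level quantification needs one"
            )
        fa1, fa2 = sorted(self.acyl_pair)
        if self.species.lipid_class.is_ether or self.species.lipid_class.is_sphingo:
            fa1, fa2 = self.acyl_pair
        return Subspecies(self.species, fa1, fa2)


# The standard spike: 240 pmol pPC 31:1 (FA 14:0 + FA 17:1).
PPC_31_1_IS = InternalStandard(
    species=SumSpecies(LipidClass.PPC, 31, 1),
    amount_pmol=240.0,
    acyl_pair=(FattyAcyl(14, 0), FattyAcyl(17, 1)),
)

_DB_HEADER = "class\tspecies\tformula\tprecursor_mz\tnl_fragment_mz\tsubspecies\tfa_fragment_mz"


def export_db(
    species: Sequence[SumSpecies],
    reporter: ReporterDefinition,
    path: str | Path | None = None,
    acyl_c_range: tuple[int, int] = DEFAULT_ACYL_C_RANGE,
    acyl_d_range: tuple[int, int] = DEFAULT_ACYL_D_RANGE,
) -> str:
    """Render the search-space database as a deterministic TSV (m/z to 4 decimals).

    Returns the TSV text; writes it to ``path`` when given.
    """
    buf = io.StringIO()
    buf.write(_DB_HEADER + "\n")
    for s in sorted(species, key=lambda x: x.sort_key):
        prec = clicked_precursor(s, reporter)
        nl = nl_fragment_mz(prec.mz, reporter)
        if s.lipid_class.is_lyso:
            subs, frags = "-", "-"
        else:
            sub_list = enumerate_subspecies(s, acyl_c_range, acyl_d_range)
            subs = ";".join(ss.name for ss in sub_list) or "-"
            frags = ";".join(
                ",".join(f"{fa_fragment_mz(fa):.4f}" for fa in ss.observable_fas)
                for ss in sub_list
            ) or "-"
        buf.write(
            f"{s.lipid_class.value}\t{s.name}\t{species_composition(s).formula()}"
            f"\t{prec.mz:.4f}\t{nl:.4f}\t{subs}\t{frags}\n"
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def import_db(path: str | Path) -> list[SumSpecies]:
    """Read back the species column of an exported database."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _DB_HEADER:
        raise ValueError("not a species database file")
    return [SumSpecies.from_name(line.split("\t")[1]) for line in lines[1:] if line]
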