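"""Exact-mass chemistry of diacyl glycerophospholipids.

Everything downstream — annotation, quantification, simulation — does its
mass arithmetic through this module: monoisotopic elemental compositions,
adduct and fragment m/z (electron-corrected), and the class-diagnostic
fragment/neutral-loss rule set used to identify head groups in dual-polarity
LC-MS/MS experiments.

Only diacyl species are modelled; lyso- and ether phospholipids are out of
scope, as are double-bond positions, cis/trans geometry and sn-stereochemistry.
"""

from __future__ import annotations

import dataclasses
import enum
import re
from collections.abc import Mapping
from functools import lru_cache
from typing import Iterator, Literal

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementalComposition",
    "FattyAcyl",
    "HeadGroupClass",
    "SumComposition",
    "AdductSpec",
    "ADDUCTS",
    "IonRule",
    "Polarity",
    "composition_mass",
    "species_formula",
    "precursor_mz",
    "neutral_mass_from_mz",
    "build_rule_table",
    "acyl_anion_mz",
    "internal_standard_composition",
    "internal_standard_mz",
    "INTERNAL_STANDARD_NAME",
]

Polarity = Literal["positive", "negative"]

#: Monoisotopic atomic masses (Da), CODATA/IUPAC values.  D is the deuterium
#: label used by the d70 internal standard.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "D": 2.01410177785,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "S": 31.97207100,
}

ELECTRON_MASS = 0.00054857990907
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalComposition(Mapping):
    """Immutable element -> count map with monoisotopic mass semantics.

    Counts are non-negative integers; subtraction that would drive any count
    negative raises.  Lookup of an absent element returns 0.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for element, n in source.items():
                if n < 0 or n != int(n):
                    raise ValueError(
                        f"negative or non-integer count for element {element!r}: {n}"
                    )
                if n:
                    merged[element] = merged.get(element, 0) + int(n)
        self._counts = dict(sorted(merged.items()))
        self._hash = hash(tuple(self._counts.items()))

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a plain formula string such as ``"C5H15NO4P"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            element = match.group(1)
            counts[element] = counts.get(element, 0) + int(match.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element: object) -> bool:
        return element in self._counts

    # Arithmetic -----------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self._counts)
        for element, n in other.items():
            counts[element] = counts.get(element, 0) + n
        return ElementalComposition(counts)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self._counts)
        for element, n in other.items():
            remaining = counts.get(element, 0) - n
            if remaining < 0:
                raise ValueError(
                    f"subtraction yields negative count for element {element!r}"
                )
            counts[element] = remaining
        return ElementalComposition(counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return self._hash

    @property
    def n_atoms(self) -> int:
        return sum(self._counts.values())

    def formula(self) -> str:
        """Hill-order formula string (C, H, then alphabetical; D after H)."""
        order = ["C", "H", "D"] + sorted(
            e for e in self._counts if e not in ("C", "H", "D")
        )
        parts = []
        for element in order:
            n = self._counts.get(element, 0)
            if n:
                parts.append(element + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ElementalComposition({self.formula()!r})"


def composition_mass(comp: ElementalComposition, charge: int = 0) -> float:
    """Monoisotopic mass of *comp* in Da, corrected for *charge* electrons.

    For an ion the returned value is its m/z (|charge| is restricted to 1;
    multiply-charged ions are not modelled).
    """
    if comp.n_atoms == 0:
        raise ValueError("empty composition")
    if abs(charge) > 1:
        raise ValueError(f"|charge| must be <= 1, got {charge}")
    mass = 0.0
    for element, n in comp.items():
        try:
            mass += n * MONOISOTOPIC_MASS[element]
        except KeyError:
            raise ValueError(f"unknown element symbol {element!r}") from None
    return mass - charge * ELECTRON_MASS


class HeadGroupClass(str, enum.Enum):
    """The seven diacyl glycerophospholipid classes handled by the pipeline."""

    PC = "PC"
    PE = "PE"
    PME = "PME"
    PDME = "PDME"
    PI = "PI"
    PG = "PG"
    PS = "PS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclasses.dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty acyl chain, written ``carbons:DBE`` (e.g. ``22:6`` for DHA).

    DBE counts double bonds plus rings along the chain, so the structural
    feasibility guard ``n_dbe <= n_carbon - 2`` can be relaxed (``strict=False``)
    for exotic chains.
    """

    n_carbon: int
    n_dbe: int
    strict: bool = dataclasses.field(default=True, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_carbon < 2:
            raise ValueError(f"fatty acyl needs >= 2 carbons, got {self.n_carbon}")
        if self.n_dbe < 0:
            raise ValueError(f"negative DBE count: {self.n_dbe}")
        if self.strict and self.n_dbe > self.n_carbon - 2:
            raise ValueError(
                f"infeasible acyl {self.n_carbon}:{self.n_dbe} "
                f"(DBE > carbons - 2); pass strict=False to allow"
            )

    @classmethod
    def parse(cls, token: str, strict: bool = True) -> "FattyAcyl":
        match = re.fullmatch(r"(\d+):(\d+)", token.strip())
        if match is None:
            raise ValueError(f"cannot parse fatty acyl token {token!r}")
        return cls(int(match.group(1)), int(match.group(2)), strict=strict)

    @property
    def name(self) -> str:
        return f"{self.n_carbon}:{self.n_dbe}"

    def anion_composition(self) -> ElementalComposition:
        """Carboxylate anion C_n H_{2n-2d-1} O2 (charge -1)."""
        n_h = 2 * self.n_carbon - 2 * self.n_dbe - 1
        if n_h <= 0:
            raise ValueError(f"infeasible acyl anion for {self.name}")
        return ElementalComposition(C=self.n_carbon, H=n_h, O=2)

    def acid_composition(self) -> ElementalComposition:
        """Neutral free fatty acid C_n H_{2n-2d} O2."""
        n_h = 2 * self.n_carbon - 2 * self.n_dbe
        if n_h <= 0:
            raise ValueError(f"infeasible fatty acid for {self.name}")
        return ElementalComposition(C=self.n_carbon, H=n_h, O=2)


def acyl_anion_mz(fa: FattyAcyl) -> float:
    """m/z of the fatty acyl carboxylate anion observed in ESI- MS2."""
    return composition_mass(fa.anion_composition(), charge=-1)


_SUM_COMP_RE = re.compile(r"([A-Z]+)\((\d+):(\d+)\)")


@dataclasses.dataclass(frozen=True, order=True)
class SumComposition:
    """Head-group class plus summed acyl carbons and DBE, e.g. ``PC(38:6)``."""

    cls: HeadGroupClass
    c_total: int
    dbe_total: int

    def __post_init__(self) -> None:
        if self.c_total < 4:
            raise ValueError(f"c_total must be >= 4, got {self.c_total}")
        if self.dbe_total < 0:
            raise ValueError(f"negative dbe_total: {self.dbe_total}")

    @classmethod
    def parse(cls, name: str) -> "SumComposition":
        match = _SUM_COMP_RE.fullmatch(name.strip())
        if match is None:
            raise ValueError(f"cannot parse species name {name!r}")
        return cls(HeadGroupClass(match.group(1)), int(match.group(2)), int(match.group(3)))

    @property
    def name(self) -> str:
        return f"{self.cls.value}({self.c_total}:{self.dbe_total})"

    def __str__(self) -> str:
        return self.name


# Closed-form neutral diacyl formulas.  With C = c_total, D = dbe_total each
# class is C_{C+dc} H_{2C-2D+dh} N_n O_o P.
_CLASS_FORMULA: dict[HeadGroupClass, tuple[int, int, int, int]] = {
    # cls: (dc, dh, n_N, n_O)
    HeadGroupClass.PC: (8, 16, 1, 8),
    HeadGroupClass.PE: (5, 10, 1, 8),
    HeadGroupClass.PME: (6, 12, 1, 8),
    HeadGroupClass.PDME: (7, 14, 1, 8),
    HeadGroupClass.PS: (6, 10, 1, 10),
    HeadGroupClass.PG: (6, 11, 0, 10),
    HeadGroupClass.PI: (9, 15, 0, 13),
}


def species_formula(sc: SumComposition) -> ElementalComposition:
    """Neutral elemental formula of a diacyl species from its sum composition."""
    dc, dh, n_n, n_o = _CLASS_FORMULA[sc.cls]
    n_h = 2 * sc.c_total - 2 * sc.dbe_total + dh
    if n_h <= 0:
        raise ValueError(f"infeasible composition {sc.name}")
    counts = {"C": sc.c_total + dc, "H": n_h, "O": n_o, "P": 1}
    if n_n:
        counts["N"] = n_n
    return ElementalComposition(counts)


@dataclasses.dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: signed atom delta applied to the neutral formula."""

    name: str
    delta: tuple[tuple[str, int], ...]
    charge: int

    @property
    def delta_mass(self) -> float:
        """Mass added to the neutral monoisotopic mass to obtain m/z."""
        mass = sum(n * MONOISOTOPIC_MASS[el] for el, n in self.delta)
        return mass - self.charge * ELECTRON_MASS

    def ion_mz(self, neutral: ElementalComposition) -> float:
        return composition_mass(neutral) + self.delta_mass


ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", (("H", 1),), +1),
    "[M+NH4]+": AdductSpec("[M+NH4]+", (("N", 1), ("H", 4)), +1),
    "[M-H]-": AdductSpec("[M-H]-", (("H", -1),), -1),
    "[M+HCOO]-": AdductSpec("[M+HCOO]-", (("C", 1), ("H", 1), ("O", 2)), -1),
}

# PI and PG ionize as ammonium adducts in ESI+ (ammonium-acetate buffer); the
# choice is overridable per class.
_DEFAULT_POSITIVE_ADDUCT: dict[HeadGroupClass, str] = {
    cls: ("[M+NH4]+" if cls in (HeadGroupClass.PI, HeadGroupClass.PG) else "[M+H]+")
    for cls in HeadGroupClass
}
_DEFAULT_NEGATIVE_ADDUCT: dict[HeadGroupClass, str] = {
    cls: ("[M+HCOO]-" if cls is HeadGroupClass.PC else "[M-H]-")
    for cls in HeadGroupClass
}


def _adduct_for(cls: HeadGroupClass, mode: Polarity,
                overrides: Mapping[HeadGroupClass, str] | None = None) -> AdductSpec:
    table = _DEFAULT_POSITIVE_ADDUCT if mode == "positive" else _DEFAULT_NEGATIVE_ADDUCT
    name = (overrides or {}).get(cls, table[cls])
    return ADDUCTS[name]


def precursor_mz(sc: SumComposition, mode: Polarity,
                 adduct_overrides: Mapping[HeadGroupClass, str] | None = None,
                 ) -> tuple[float, AdductSpec]:
    """Expected precursor m/z of a species and the adduct producing it."""
    adduct = _adduct_for(sc.cls, mode, adduct_overrides)
    return adduct.ion_mz(species_formula(sc)), adduct


def neutral_mass_from_mz(mz: float, adduct: AdductSpec) -> float:
    """Invert an observed precursor m/z to the implied neutral mass."""
    return mz - adduct.delta_mass


@dataclasses.dataclass(frozen=True)
class IonRule:
    """A class-diagnostic MS2 rule: fragment ion or neutral loss.

    ``mass`` is the m/z for a fragment ion (electron-corrected at the mode's
    charge) and the neutral mass for a neutral loss; it is always computed
    from ``composition`` at construction time.
    """

    cls: HeadGroupClass
    mode: Polarity
    rule_kind: Literal["fragment_ion", "neutral_loss"]
    composition: ElementalComposition
    mass: float

    def __post_init__(self) -> None:
        charge = 0
        if self.rule_kind == "fragment_ion":
            charge = 1 if self.mode == "positive" else -1
        expected = composition_mass(self.composition, charge)
        if abs(expected - self.mass) > 1e-4:
            raise ValueError(
                f"rule mass {self.mass} inconsistent with composition "
                f"{self.composition.formula()} ({expected:.5f})"
            )


def _rule(cls: HeadGroupClass, mode: Polarity,
          kind: Literal["fragment_ion", "neutral_loss"], formula: str) -> IonRule:
    comp = ElementalComposition.from_formula(formula)
    charge = 0
    if kind == "fragment_ion":
        charge = 1 if mode == "positive" else -1
    return IonRule(cls, mode, kind, comp, composition_mass(comp, charge))


@lru_cache(maxsize=1)
def build_rule_table() -> tuple[IonRule, ...]:
    """The class-diagnostic rule set, computed from elemental compositions.

    Positive mode: PCs split off the protonated phosphocholine head group as a
    characteristic fragment ion; all other classes lose the head group as a
    neutral (PI and PG lose head + NH3 from their ammonium adducts).  Negative
    mode: PCs lose methyl formate from the formate adduct (giving [M-CH3]-),
    PIs show the inositol-phosphate fragment, PSs lose the serine moiety.
    """
    H = HeadGroupClass
    return (
        _rule(H.PC, "positive", "fragment_ion", "C5H15NO4P"),
        _rule(H.PC, "negative", "neutral_loss", "C2H4O2"),
        _rule(H.PE, "positive", "neutral_loss", "C2H8NO4P"),
        _rule(H.PME, "positive", "neutral_loss", "C3H10NO4P"),
        _rule(H.PDME, "positive", "neutral_loss", "C4H12NO4P"),
        _rule(H.PI, "positive", "neutral_loss", "C6H16NO9P"),
        _rule(H.PI, "negative", "fragment_ion", "C6H12O9P"),
        _rule(H.PG, "positive", "neutral_loss", "C3H12NO6P"),
        _rule(H.PS, "positive", "neutral_loss", "C3H8NO6P"),
        _rule(H.PS, "negative", "neutral_loss", "C3H5NO2"),
    )


# ---------------------------------------------------------------------------
# Internal standard: 1,2-distearoyl-d70-PC, i.e. PC(36:0) with both stearoyl
# chains perdeuterated (70 D).
# ---------------------------------------------------------------------------

INTERNAL_STANDARD_NAME = "PC(36:0)-d70"
_IS_N_DEUTERIUM = 70


@lru_cache(maxsize=1)
def internal_standard_composition() -> ElementalComposition:
    base = species_formula(SumComposition(HeadGroupClass.PC, 36, 0))
    return (base - ElementalComposition(H=_IS_N_DEUTERIUM)
            + ElementalComposition(D=_IS_N_DEUTERIUM))


def internal_standard_mz(mode: Polarity) -> float:
    """Precursor m/z of the d70-PC internal standard in either polarity."""
    adduct = _adduct_for(HeadGroupClass.PC, mode)
    return adduct.ion_mz(internal_standard_composition())
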