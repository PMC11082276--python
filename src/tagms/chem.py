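"""Elemental formula arithmetic, monoisotopic masses and adduct ion m/z.

Atomic masses are hard-coded from the IUPAC/CIAAW table of monoisotopic
atomic masses (most abundant isotope, quoted to at least six decimals); no
runtime lookup is performed.  Ion m/z values apply the electron-mass
correction by default — positive ions are lighter than the sum of their
atoms by one electron per charge — which is required to reproduce
high-resolution reference masses of sodiated triacylglycerols to four
decimal places.  The correction can be disabled per call.

All m/z values are carried at full double precision; rounding happens only
at presentation or peak-matching layers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "Formula",
    "FattyAcid",
    "Adduct",
    "ADDUCTS",
    "monoisotopic_mass",
    "ion_mz",
    "acyl_neutral_losses",
]

#: Monoisotopic atomic masses in Da (IUPAC/CIAAW, most abundant isotope).
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: Electron rest mass in Da.
ELECTRON_MASS: float = 0.000548579909

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping):
    """Immutable element-count map, the unit of all mass arithmetic.

    Supports elementwise addition, subtraction (raising if any count would
    go negative) and scaling by a non-negative integer.  Zero counts are
    dropped, so ``Formula(C=1) - Formula(C=1) == Formula()``.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}, kw):
            for el, n in src.items():
                n = int(n)
                if n < 0:
                    raise ValueError(f"negative count for element {el}: {n}")
                if n:
                    merged[el] = merged.get(el, 0) + n
        self._counts = merged

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a plain string like ``"C65H118O6"`` into a Formula."""
        pos, counts = 0, {}
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"malformed formula string: {text!r}")
            el, digits = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"malformed formula string: {text!r}")
        return cls(counts)

    # Mapping interface ----------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts[el]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, el: str, default: int = 0) -> int:
        return self._counts.get(el, default)

    # arithmetic -----------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction would give negative {el} count "
                    f"({counts.get(el, 0)} - {n})"
                )
            counts[el] = new
        return Formula({el: n for el, n in counts.items() if n})

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int) or k < 0:
            raise ValueError("formula can only be scaled by a non-negative integer")
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = sorted(self._counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(
            f"{el}{self._counts[el] if self._counts[el] != 1 else ''}" for el in order
        )

    def __repr__(self) -> str:
        return f"Formula({str(self) or ''!r})"


WATER = Formula(H=2, O=1)
AMMONIA = Formula(N=1, H=3)


def monoisotopic_mass(formula: Formula | Mapping[str, int]) -> float:
    """Monoisotopic mass in Da of a neutral elemental composition.

    Raises ``ValueError`` naming the symbol if an element is not in the
    hard-coded mass table.
    """
    total = 0.0
    for el, n in formula.items():
        try:
            total += MONOISOTOPIC_MASS[el] * n
        except KeyError:
            raise ValueError(f"unknown element symbol: {el}") from None
    return total


@dataclass(frozen=True, order=True)
class FattyAcid:
    """An acyl chain in carbons:double-bond shorthand, e.g. 22:1 (erucic).

    Double-bond positions and geometry are not modelled; identity is the
    (carbons, double_bonds) pair.  Validity requires the free-acid formula
    C_c H_(2c-2db) O2 to have a hydrogen count of at least 2, i.e.
    2c - 2db - 2 >= 0.
    """

    carbons: int
    double_bonds: int

    def __post_init__(self):
        if not isinstance(self.carbons, int) or self.carbons < 2:
            raise ValueError(f"acyl carbons must be an integer >= 2, got {self.carbons}")
        if not isinstance(self.double_bonds, int) or self.double_bonds < 0:
            raise ValueError(f"double bonds must be a non-negative integer, got {self.double_bonds}")
        if 2 * self.carbons - 2 * self.double_bonds - 2 < 0:
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} has no valid free-acid formula"
            )

    @classmethod
    def parse(cls, text: str) -> "FattyAcid":
        m = re.fullmatch(r"\s*(\d+):(\d+)\s*", text)
        if not m:
            raise ValueError(f"malformed acyl descriptor: {text!r} (expected 'C:DB')")
        return cls(int(m.group(1)), int(m.group(2)))

    @property
    def name(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    @property
    def acid_formula(self) -> Formula:
        """Formula of the free fatty acid C_c H_(2c-2db) O2."""
        return Formula(C=self.carbons, H=2 * self.carbons - 2 * self.double_bonds, O=2)

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Adduct:
    """An ionising adduct: a formula delta plus a signed unit charge.

    Deprotonation is expressed as a subtraction delta so that applying
    [M-H]- to a hydrogen-free neutral raises.
    """

    name: str
    add: Formula = field(default_factory=Formula)
    sub: Formula = field(default_factory=Formula)
    charge: int = 1

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")


ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", add=Formula(H=1), charge=+1),
    "[M+Na]+": Adduct("[M+Na]+", add=Formula(Na=1), charge=+1),
    "[M+NH4]+": Adduct("[M+NH4]+", add=Formula(N=1, H=4), charge=+1),
    "[M-H]-": Adduct("[M-H]-", sub=Formula(H=1), charge=-1),
}


def _resolve_adduct(adduct: Adduct | str) -> Adduct:
    if isinstance(adduct, Adduct):
        return adduct
    key = adduct.replace("−", "-")  # tolerate unicode minus
    try:
        return ADDUCTS[key]
    except KeyError:
        raise ValueError(
            f"unknown adduct {adduct!r}; registered: {sorted(ADDUCTS)}"
        ) from None


def ion_mz(
    neutral: Formula,
    adduct: Adduct | str,
    electron_correction: bool = True,
) -> float:
    """m/z of the ion formed from a neutral formula and an adduct.

    m/z = (mass(neutral + delta) - sign * z * m_e) / z; positive ions lose
    z electrons, negative ions gain them.  Raises if the adduct delta would
    drive any element count negative.
    """
    ad = _resolve_adduct(adduct)
    ion = neutral + ad.add - ad.sub
    z = abs(ad.charge)
    m = monoisotopic_mass(ion)
    if electron_correction:
        m -= (1 if ad.charge > 0 else -1) * z * ELECTRON_MASS
    return m / z


def acyl_neutral_losses(fa: FattyAcid) -> tuple[float, float]:
    """(free fatty acid loss, sodium-salt loss) in Da for one acyl chain.

    The salt loss replaces the acid's carboxyl hydrogen with sodium, so the
    two losses differ by the Na-H mass difference (21.981944 Da) for every
    acyl.
    """
    acid = monoisotopic_mass(fa.acid_formula)
    salt = acid - MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["Na"]
    return acid, salt
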