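"""Lipid species grammar, neutral formula assembly, and acyl combinatorics.

Species are written in the field's shorthand: a class token plus either a
carbons:double-bonds total ("TAG 62:4") or an explicit acyl list
("TAG 22:1/18:2/22:1", "DAG 18:0-22:6").  Three resolution levels exist:

* class-total  — only the (C, DB) sum is known;
* molecular    — the acyl multiset is known, positions are not;
* sn-resolved  — additionally one acyl is assigned to the sn-2 position.

sn-1 and sn-3 are never distinguished (the fragmentation chemistry this
package models cannot separate the enantiomers); the representation stores
an order-free acyl multiset plus an optional sn-2 member.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Sequence

from .chem import Formula, FattyAcid, WATER

__all__ = [
    "LipidClass",
    "LIPID_CLASSES",
    "HEAD_GROUPS",
    "GLYCEROL",
    "DEFAULT_ACYL_POOL",
    "LipidSpecies",
    "parse_species",
    "format_species",
    "species_formula",
    "class_total_formula",
    "enumerate_compositions",
    "validate_label_consistency",
    "read_species_list",
]

GLYCEROL = Formula(C=3, H=8, O=3)
PHOSPHORIC_ACID = Formula(H=3, O=4, P=1)

#: Free head-group compounds; attachment to glycerol condenses one water.
HEAD_GROUPS: dict[str, Formula] = {
    "PC": Formula(C=5, H=14, N=1, O=4, P=1),   # phosphocholine
    "PE": Formula(C=2, H=8, N=1, O=4, P=1),    # phosphoethanolamine
    "PS": Formula(C=3, H=8, N=1, O=6, P=1),    # phosphoserine
    "PG": Formula(C=3, H=9, O=6, P=1),         # glycerophosphate
    "PI": Formula(C=6, H=13, O=9, P=1),        # inositol phosphate
    "PA": PHOSPHORIC_ACID,
    "MGDG": Formula(C=6, H=12, O=6),           # galactose
    "DGDG": Formula(C=12, H=22, O=11),         # digalactose
    "SQDG": Formula(C=6, H=12, O=8, S=1),      # sulfoquinovose
}


@dataclass(frozen=True)
class LipidClass:
    name: str
    n_acyl: int
    head: Formula | None


LIPID_CLASSES: dict[str, LipidClass] = {
    **{name: LipidClass(name, 2, HEAD_GROUPS[name]) for name in HEAD_GROUPS},
    "DAG": LipidClass("DAG", 2, None),
    "TAG": LipidClass("TAG", 3, None),
    "CL": LipidClass("CL", 4, None),  # backbone/heads handled specially
}

#: Acyl chains observed in the seed-oil system this package models
#: (palmitic through nervonic, including the very long chain monoenes).
DEFAULT_ACYL_POOL: tuple[FattyAcid, ...] = tuple(
    FattyAcid.parse(s)
    for s in ("16:0", "16:1", "18:0", "18:1", "18:2", "18:3",
              "20:0", "20:1", "22:1", "24:1")
)

_INFER_CLASS_BY_COUNT = {2: "DAG", 3: "TAG", 4: "CL"}
_TOTALS_RE = re.compile(r"(\d+):(\d+)")


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species at class-total, molecular or sn-resolved level."""

    lipid_class: str
    level: str  # 'class' | 'molecular' | 'sn'
    carbons: int
    double_bonds: int
    acyls: tuple[FattyAcid, ...] | None = None  # sorted multiset
    sn2: FattyAcid | None = None

    def __post_init__(self):
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.level not in ("class", "molecular", "sn"):
            raise ValueError(f"unknown resolution level {self.level!r}")
        if self.level == "class":
            if self.acyls is not None:
                raise ValueError("class-total species carries no acyl list")
        else:
            cls = LIPID_CLASSES[self.lipid_class]
            if self.acyls is None or len(self.acyls) != cls.n_acyl:
                got = 0 if self.acyls is None else len(self.acyls)
                raise ValueError(
                    f"{self.lipid_class} requires {cls.n_acyl} acyls, got {got}"
                )
            if tuple(sorted(self.acyls)) != self.acyls:
                raise ValueError("acyl multiset must be stored sorted")
            c = sum(a.carbons for a in self.acyls)
            db = sum(a.double_bonds for a in self.acyls)
            if (c, db) != (self.carbons, self.double_bonds):
                raise ValueError(
                    f"acyl sums {c}:{db} disagree with totals "
                    f"{self.carbons}:{self.double_bonds}"
                )
        if self.sn2 is not None:
            if self.level != "sn":
                raise ValueError("sn-2 assignment requires sn-resolved level")
            if self.acyls is None or self.sn2 not in self.acyls:
                raise ValueError("sn-2 acyl must be a member of the acyl multiset")

    @classmethod
    def from_totals(cls, lipid_class: str, carbons: int, double_bonds: int) -> "LipidSpecies":
        return cls(lipid_class, "class", int(carbons), int(double_bonds))

    @classmethod
    def from_acyls(
        cls,
        lipid_class: str,
        acyls: Iterable[FattyAcid],
        sn2: FattyAcid | None = None,
    ) -> "LipidSpecies":
        acyls = tuple(sorted(acyls))
        c = sum(a.carbons for a in acyls)
        db = sum(a.double_bonds for a in acyls)
        return cls(
            lipid_class,
            "sn" if sn2 is not None else "molecular",
            c,
            db,
            acyls,
            sn2,
        )

    @property
    def totals_label(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    def __str__(self) -> str:
        return format_species(self)


def parse_species(text: str) -> LipidSpecies:
    """Parse shorthand like ``"TAG 62:4"``, ``"PC 34:2"``, ``"22:1/18:2/22:1"``
    or ``"DAG 18:0-22:6"``.

    Slash and dash separators are both accepted on input; a bare acyl list
    infers the class from the acyl count (2 -> DAG, 3 -> TAG, 4 -> CL).
    Acyl-list input parses to molecular level: positions are not inferable
    from text.
    """
    s = text.strip()
    if not s:
        raise ValueError("empty species string")
    head, _, rest = s.partition(" ")
    cls_name: str | None = None
    if head.upper() in LIPID_CLASSES:
        cls_name = head.upper()
        body = rest.strip()
        if not body:
            raise ValueError(f"malformed species {text!r}: class without composition")
    else:
        body = s

    if "/" in body or re.search(r"\d-\d", body):
        parts = [p for p in re.split(r"[/-]", body) if p.strip()]
        try:
            acyls = [FattyAcid.parse(p) for p in parts]
        except ValueError as e:
            raise ValueError(f"malformed species {text!r}: {e}") from None
        if cls_name is None:
            cls_name = _INFER_CLASS_BY_COUNT.get(len(acyls))
            if cls_name is None:
                raise ValueError(
                    f"cannot infer class for {len(acyls)} acyls in {text!r}"
                )
        cls = LIPID_CLASSES[cls_name]
        if len(acyls) != cls.n_acyl:
            raise ValueError(
                f"{cls_name} takes {cls.n_acyl} acyls, got {len(acyls)} in {text!r}"
            )
        return LipidSpecies.from_acyls(cls_name, acyls)

    m = _TOTALS_RE.fullmatch(body.strip())
    if m is None or cls_name is None:
        raise ValueError(
            f"malformed species {text!r}: expected 'CLASS C:DB' or an acyl list"
        )
    return LipidSpecies.from_totals(cls_name, int(m.group(1)), int(m.group(2)))


def format_species(sp: LipidSpecies) -> str:
    """Canonical rendering; ``parse_species(format_species(sp))`` recovers the
    class, totals and acyl multiset.

    '/' is the canonical separator.  At sn-resolved level the sn-2 acyl is
    rendered in the middle position; note the flanking positions are an
    unresolved sn-1/3 pair, not a positional claim.
    """
    if sp.level == "class":
        return f"{sp.lipid_class} {sp.totals_label}"
    acyls = list(sp.acyls)
    if sp.level == "sn":
        others = list(acyls)
        others.remove(sp.sn2)
        mid = len(others) // 2
        acyls = others[:mid] + [sp.sn2] + others[mid:]
    return f"{sp.lipid_class} " + "/".join(a.name for a in acyls)


def species_formula(species: LipidSpecies) -> Formula:
    """Neutral molecular formula of a molecular- or sn-level species.

    Assembly: glycerol + sum of free-acid acyl formulas + head compound,
    condensing one water per ester bond and one per head attachment.
    Cardiolipin uses three glycerols bridged by two phosphodiesters (four
    extra condensations).
    """
    if species.level == "class":
        raise ValueError(
            "class-total species has no unique acyl assignment; "
            "use enumerate_compositions to obtain molecular species first "
            "(any composition with the same totals yields the same formula; "
            "see class_total_formula)"
        )
    acids = Formula()
    for a in species.acyls:
        acids = acids + a.acid_formula
    return _assemble(species.lipid_class, acids, len(species.acyls))


def class_total_formula(lipid_class: str, carbons: int, double_bonds: int) -> Formula:
    """Neutral formula from class + totals alone.

    Any acyl split with the same (C, DB) totals gives the same elemental
    composition, so the summed free-acid formula C_c H_(2c-2db) O_(2n) is a
    faithful representative.
    """
    cls = LIPID_CLASSES[lipid_class]
    h = 2 * carbons - 2 * double_bonds
    if carbons < 2 * cls.n_acyl or h < 2 * cls.n_acyl:
        raise ValueError(
            f"{lipid_class} {carbons}:{double_bonds} is not a valid acyl total"
        )
    acids = Formula(C=carbons, H=h, O=2 * cls.n_acyl)
    return _assemble(lipid_class, acids, cls.n_acyl)


def _assemble(lipid_class: str, acids: Formula, n_acyl: int) -> Formula:
    if lipid_class == "CL":
        return GLYCEROL * 3 + PHOSPHORIC_ACID * 2 + acids - WATER * (n_acyl + 4)
    head = LIPID_CLASSES[lipid_class].head
    waters = n_acyl + (1 if head is not None else 0)
    base = GLYCEROL + acids + (head if head is not None else Formula())
    return base - WATER * waters


def enumerate_compositions(
    lipid_class: str,
    total_c: int,
    total_db: int,
    pool: Sequence[FattyAcid] = DEFAULT_ACYL_POOL,
) -> list[tuple[FattyAcid, ...]]:
    """All acyl multisets from the pool matching the (C, DB) totals.

    Multisets are drawn with repetition, deduplicated, and returned in
    deterministic sorted order.  Unsatisfiable totals give an empty list.
    """
    if not pool:
        raise ValueError("acyl pool is empty")
    n = LIPID_CLASSES[lipid_class].n_acyl
    out = []
    for combo in combinations_with_replacement(sorted(set(pool)), n):
        if (
            sum(a.carbons for a in combo) == total_c
            and sum(a.double_bonds for a in combo) == total_db
        ):
            out.append(combo)
    return sorted(out)


def validate_label_consistency(
    total_c: int, total_db: int, acyls: Iterable[FattyAcid]
) -> bool:
    """True iff the acyl sums match the printed C:DB label.

    An empty acyl set is treated as an error rather than vacuously true:
    a label with no composition cannot be checked.
    """
    acyls = tuple(acyls)
    if not acyls:
        raise ValueError("cannot validate a label against an empty acyl set")
    return (
        sum(a.carbons for a in acyls) == total_c
        and sum(a.double_bonds for a in acyls) == total_db
    )


def read_species_list(path) -> list[LipidSpecies]:
    """Read species from one-column text or CSV with a ``species`` column."""
    import pandas as pd

    text = open(path).read()
    first = text.splitlines()[0] if text.splitlines() else ""
    if "," in first or first.strip().lower() == "species":
        df = pd.read_csv(path)
        if "species" not in df.columns:
            raise ValueError(f"{path}: CSV species list needs a 'species' column")
        items = df["species"].astype(str)
    else:
        items = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return [parse_species(s) for s in items]
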