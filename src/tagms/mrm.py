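"""Class-resolved acquisition planning: precursor-ion scans, neutral-loss
scans, and MRM transition tables with collision energies and dwell times.

The head-group diagnostics are computed from the stored head formulas, not
looked up: phosphatidylcholine is detected by precursors of the
phosphocholine cation (m/z 184.0733) in positive mode, sulfolipid by
precursors of the dehydrated sulfoquinovose anion (m/z 225.0074) in
negative mode, and the remaining diacyl classes by neutral loss of the
head from [M+H]+ (PE, PS) or of the head-derived residue plus ammonia from
[M+NH4]+ (PI, PG, PA, MGDG, DGDG).  The adduct-per-class assignment is the
only arithmetic that reproduces the nominal losses used in practice
(141/277/185/189/115/179/341 Da), and is fixed here.

DAG and TAG are acquired as ammoniated MRM pairs, cardiolipin as
deprotonated MRM pairs; these classes have no head-group scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .chem import AMMONIA, Formula, WATER, ion_mz, monoisotopic_mass
from .species import (
    HEAD_GROUPS,
    LIPID_CLASSES,
    LipidSpecies,
    class_total_formula,
    parse_species,
    species_formula,
)

__all__ = [
    "ScanDefinition",
    "CLASS_ADDUCT",
    "head_group_diagnostic",
    "build_transitions",
    "write_transitions",
]

#: Ionising adduct used per lipid class.
CLASS_ADDUCT: dict[str, str] = {
    "PC": "[M+H]+",
    "PE": "[M+H]+",
    "PS": "[M+H]+",
    "PI": "[M+NH4]+",
    "PG": "[M+NH4]+",
    "PA": "[M+NH4]+",
    "MGDG": "[M+NH4]+",
    "DGDG": "[M+NH4]+",
    "SQDG": "[M-H]-",
    "DAG": "[M+NH4]+",
    "TAG": "[M+NH4]+",
    "CL": "[M-H]-",
}

#: Collision energy (eV, signed with polarity) of each head-group scan.
_HEAD_SCAN_CE: dict[str, float] = {
    "PC": 35.0,
    "SQDG": -55.0,
    "PE": 29.0,
    "PI": 21.0,
    "PS": 21.0,
    "PG": 25.0,
    "PA": 25.0,
    "MGDG": 8.0,
    "DGDG": 11.0,
}

_MRM_CE = {"DAG": 19.0, "TAG": 26.0, "CL": -45.0}
_DWELL_MS = {"CL": 50.0}
_DEFAULT_DWELL_MS = 30.0


@dataclass(frozen=True)
class ScanDefinition:
    """One class-level survey scan (precursor-of or neutral-loss)."""

    lipid_class: str
    polarity: str           # '+' or '-'
    scan_type: str          # 'precursor-of' | 'neutral-loss'
    value: float            # diagnostic m/z (precursor-of) or loss in Da
    nominal: int            # integer-rounded diagnostic, as printed on methods
    collision_energy_eV: float
    dwell_ms: float = _DEFAULT_DWELL_MS

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("diagnostic value must be positive")
        if (self.collision_energy_eV < 0) != (self.polarity == "-"):
            raise ValueError("collision-energy sign must match polarity")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _neutral_loss_mass(lipid_class: str) -> float:
    """Head-group neutral loss in Da, derived from the head formula."""
    head = HEAD_GROUPS[lipid_class]
    if lipid_class in ("PE", "PS"):
        loss: Formula = head                      # whole phospho-head from [M+H]+
    elif lipid_class in ("PI", "PG", "PA"):
        loss = head + AMMONIA                     # head + NH3 from [M+NH4]+
    elif lipid_class in ("MGDG", "DGDG"):
        loss = head - WATER + AMMONIA             # glycosyl residue + NH3
    else:  # pragma: no cover - guarded by caller
        raise ValueError(lipid_class)
    return monoisotopic_mass(loss)


def head_group_diagnostic(lipid_class: str) -> ScanDefinition:
    """Survey-scan definition for a diacyl phospho- or glycolipid class.

    DAG, TAG and CL are MRM-only and raise with a pointer to
    :func:`build_transitions`.
    """
    cls = lipid_class.upper()
    if cls in ("DAG", "TAG", "CL"):
        raise ValueError(
            f"{cls} has no head-group survey scan; use build_transitions "
            "(these classes are acquired as MRM pairs only)"
        )
    if cls not in LIPID_CLASSES:
        raise ValueError(f"unknown lipid class {lipid_class!r}")
    ce = _HEAD_SCAN_CE[cls]
    if cls == "PC":
        mz = ion_mz(HEAD_GROUPS["PC"], "[M+H]+")
        return ScanDefinition("PC", "+", "precursor-of", mz, _round_half_away(mz), ce)
    if cls == "SQDG":
        mz = ion_mz(HEAD_GROUPS["SQDG"] - WATER, "[M-H]-")
        return ScanDefinition("SQDG", "-", "precursor-of", mz, _round_half_away(mz), ce)
    loss = _neutral_loss_mass(cls)
    return ScanDefinition(cls, "+", "neutral-loss", loss, _round_half_away(loss), ce)


def _neutral_formula(sp: LipidSpecies) -> Formula:
    if sp.level == "class":
        return class_total_formula(sp.lipid_class, sp.carbons, sp.double_bonds)
    return species_formula(sp)


def _product_mz(sp: LipidSpecies, q1: float) -> float:
    """Q3 for one transition row; see module docstring for the conventions."""
    cls = sp.lipid_class
    if cls in ("DAG", "TAG"):
        if sp.level == "class":
            # acyls unknown: fall back to the ammonia-loss product
            return q1 - monoisotopic_mass(AMMONIA)
        largest = max(sp.acyls)
        loss = monoisotopic_mass(largest.acid_formula) + monoisotopic_mass(AMMONIA)
        return q1 - loss
    if cls == "CL":
        if sp.level == "class":
            raise ValueError(
                "class-total CL has no defined product ion; supply a molecular "
                "species (product is the largest acyl carboxylate anion)"
            )
        largest = max(sp.acyls)
        return ion_mz(largest.acid_formula, "[M-H]-")
    sd = head_group_diagnostic(cls)
    if sd.scan_type == "precursor-of":
        return sd.value
    return q1 - sd.value


def build_transitions(species: Iterable[LipidSpecies | str]) -> pd.DataFrame:
    """MRM transition table for a set of species.

    Columns: species, lipid_class, polarity, Q1_mz, Q3_mz, CE_eV, dwell_ms.
    The table is a pure function of the species *set*: rows are sorted by
    (lipid_class, species) regardless of input order.  Empty input gives an
    empty table.
    """
    rows = []
    for item in species:
        sp = parse_species(item) if isinstance(item, str) else item
        cls = sp.lipid_class
        adduct = CLASS_ADDUCT[cls]
        q1 = ion_mz(_neutral_formula(sp), adduct)
        q3 = _product_mz(sp, q1)
        if cls in _MRM_CE:
            ce = _MRM_CE[cls]
        else:
            ce = head_group_diagnostic(cls).collision_energy_eV
        rows.append(
            {
                "species": str(sp),
                "lipid_class": cls,
                "polarity": "-" if adduct.endswith("-") else "+",
                "Q1_mz": q1,
                "Q3_mz": q3,
                "CE_eV": ce,
                "dwell_ms": _DWELL_MS.get(cls, _DEFAULT_DWELL_MS),
            }
        )
    cols = ["species", "lipid_class", "polarity", "Q1_mz", "Q3_mz", "CE_eV", "dwell_ms"]
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df = df.sort_values(["lipid_class", "species"], kind="mergesort").reset_index(
            drop=True
        )
    return df


def write_transitions(
    df: pd.DataFrame, path, metadata: Mapping[str, str] | None = None
) -> None:
    """Write a transition table as CSV, with optional free-text metadata
    (gradient, flow, column) recorded as '#'-prefixed header lines."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)
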