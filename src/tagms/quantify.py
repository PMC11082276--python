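"""Internal-standard quantification and mole-fraction summaries.

Raw MRM responses are converted to picomoles by ratio to a spiked class
standard of known amount (here 125 pmol per class), optionally corrected
by a per-class response factor.  Classes without their own spiked standard
(only PE, DAG and SQDG are spiked in the reference protocol) borrow a
standard through an explicit fallback table — never silently.  All
downstream summaries are mole fractions (mol%), matching the pmol
accounting, and are invariant to per-sample scaling by construction.

Tabular containers are tidy pandas DataFrames:

* peak table     — columns sample, stage, replicate, species, response
* lipidome profile — columns sample, stage, replicate, species, amount_pmol

A species missing from a sample means 0 pmol; a missing standard row in a
sample is an error (the sample cannot be quantified at all).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .chem import FattyAcid
from .species import parse_species

__all__ = [
    "InternalStandard",
    "InternalStandardSet",
    "default_standards",
    "is_normalize",
    "class_fractions",
    "species_fraction_within_class",
    "acyl_mole_pct",
    "stage_summary",
]

PEAK_COLUMNS = ["sample", "stage", "replicate", "species", "response"]
PROFILE_COLUMNS = ["sample", "stage", "replicate", "species", "amount_pmol"]


@dataclass(frozen=True)
class InternalStandard:
    species: str
    pmol: float
    response_factor: float = 1.0

    def __post_init__(self):
        if self.pmol <= 0:
            raise ValueError("spiked amount must be positive")
        if self.response_factor <= 0:
            raise ValueError("response factor must be positive")


@dataclass(frozen=True)
class InternalStandardSet:
    """Map lipid class -> spiked standard, plus an explicit fallback table
    assigning a standard-bearing class to each class without its own spike."""

    standards: Mapping[str, InternalStandard]
    fallback: Mapping[str, str] = field(default_factory=dict)

    def standard_for(self, lipid_class: str) -> tuple[str, InternalStandard]:
        if lipid_class in self.standards:
            return lipid_class, self.standards[lipid_class]
        if lipid_class in self.fallback:
            target = self.fallback[lipid_class]
            return target, self.standards[target]
        raise ValueError(
            f"no internal standard (or fallback mapping) for class {lipid_class}"
        )

    @property
    def standard_species(self) -> set[str]:
        return {std.species for std in self.standards.values()}

    @classmethod
    def from_yaml(cls, path) -> "InternalStandardSet":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        standards = {
            k: InternalStandard(
                species=v["species"],
                pmol=float(v["pmol"]),
                response_factor=float(v.get("response_factor", 1.0)),
            )
            for k, v in doc.get("standards", {}).items()
        }
        return cls(standards, dict(doc.get("fallback", {})))

    def to_yaml(self, path) -> None:
        import yaml

        doc = {
            "standards": {
                k: {
                    "species": v.species,
                    "pmol": v.pmol,
                    "response_factor": v.response_factor,
                }
                for k, v in self.standards.items()
            },
            "fallback": dict(self.fallback),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def default_standards() -> InternalStandardSet:
    """The reference spike set: 125 pmol each of PE 18:0/18:0, DAG 18:0/22:6
    and SQDG 16:0/18:0, with phospholipids borrowing the PE standard,
    neutral lipids the DAG one and galactolipids the SQDG one."""
    return InternalStandardSet(
        standards={
            "PE": InternalStandard("PE 18:0/18:0", 125.0),
            "DAG": InternalStandard("DAG 18:0/22:6", 125.0),
            "SQDG": InternalStandard("SQDG 16:0/18:0", 125.0),
        },
        fallback={
            "PC": "PE",
            "PI": "PE",
            "PS": "PE",
            "PG": "PE",
            "PA": "PE",
            "CL": "PE",
            "TAG": "DAG",
            "MGDG": "SQDG",
            "DGDG": "SQDG",
        },
    )


def _check_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def _species_class(name: str) -> str:
    return parse_species(name).lipid_class


def is_normalize(peaks: pd.DataFrame, standards: InternalStandardSet) -> pd.DataFrame:
    """Convert raw responses to pmol against the class internal standards.

    amount = (response / response of the class standard) x spiked pmol
    x response factor.  Standard rows are excluded from the output profile.
    Raises listing sample and class when a needed standard row is absent.
    Inputs are not mutated.
    """
    _check_columns(peaks, PEAK_COLUMNS, "peak table")
    if peaks.duplicated(["sample", "species"]).any():
        dup = peaks[peaks.duplicated(["sample", "species"], keep=False)]
        raise ValueError(
            f"(sample, species) pairs must be unique; duplicates:\n{dup}"
        )
    if (peaks["response"] < 0).any():
        raise ValueError("responses must be non-negative")
    std_species = standards.standard_species
    classes = {s: _species_class(s) for s in peaks["species"].unique()}
    rows = []
    for sample, grp in peaks.groupby("sample", sort=True):
        responses = dict(zip(grp["species"], grp["response"]))
        for _, row in grp.iterrows():
            sp = row["species"]
            if sp in std_species:
                continue
            cls = classes[sp]
            _, std = standards.standard_for(cls)
            std_resp = responses.get(std.species)
            if std_resp is None or std_resp <= 0:
                raise ValueError(
                    f"sample {sample!r}: missing or zero response for internal "
                    f"standard {std.species!r} (needed to quantify class {cls})"
                )
            rows.append(
                {
                    "sample": sample,
                    "stage": row["stage"],
                    "replicate": row["replicate"],
                    "species": sp,
                    "amount_pmol": row["response"] / std_resp * std.pmol
                    * std.response_factor,
                }
            )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def class_fractions(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-sample class mole percentages (sum to 100 per sample).

    Columns: sample, stage, replicate, lipid_class, mol_pct.  Combine with
    :func:`stage_summary` (key_col='lipid_class', value_col='mol_pct') for
    per-stage mean +/- SD.  An all-zero sample is an error.
    """
    _check_columns(profile, PROFILE_COLUMNS, "profile")
    if profile.empty:
        raise ValueError("profile is empty")
    df = profile.copy()
    df["lipid_class"] = df["species"].map(_species_class)
    out = (
        df.groupby(["sample", "stage", "replicate", "lipid_class"], sort=True)[
            "amount_pmol"
        ]
        .sum()
        .reset_index()
    )
    totals = out.groupby("sample")["amount_pmol"].transform("sum")
    if (totals <= 0).any():
        bad = sorted(out.loc[totals <= 0, "sample"].unique())
        raise ValueError(f"all-zero profile for sample(s) {bad}")
    out["mol_pct"] = 100.0 * out["amount_pmol"] / totals
    return out.drop(columns="amount_pmol")


def species_fraction_within_class(profile: pd.DataFrame, lipid_class: str) -> pd.DataFrame:
    """Per-sample species percentages within one class (sum to 100)."""
    _check_columns(profile, PROFILE_COLUMNS, "profile")
    df = profile.copy()
    df["lipid_class"] = df["species"].map(_species_class)
    df = df[df["lipid_class"] == lipid_class]
    if df.empty:
        raise ValueError(f"profile contains no {lipid_class} species")
    out = (
        df.groupby(["sample", "stage", "replicate", "species"], sort=True)[
            "amount_pmol"
        ]
        .sum()
        .reset_index()
    )
    totals = out.groupby("sample")["amount_pmol"].transform("sum")
    if (totals <= 0).any():
        bad = sorted(out.loc[totals <= 0, "sample"].unique())
        raise ValueError(f"zero total {lipid_class} for sample(s) {bad}")
    out["pct_of_class"] = 100.0 * out["amount_pmol"] / totals
    return out.drop(columns="amount_pmol")


def acyl_mole_pct(profile: pd.DataFrame) -> pd.Series:
    """Mole percent of each acyl chain across the whole profile.

    Each molecular-level species contributes amount x (occurrences of the
    acyl).  Class-total species carry no acyl information and are excluded
    with a warning.  The result is invariant to profile scaling.
    """
    _check_columns(profile, PROFILE_COLUMNS, "profile")
    tally: dict[FattyAcid, float] = {}
    skipped = set()
    for _, row in profile.iterrows():
        sp = parse_species(row["species"])
        if sp.level == "class":
            skipped.add(row["species"])
            continue
        for acyl in sp.acyls:
            tally[acyl] = tally.get(acyl, 0.0) + float(row["amount_pmol"])
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} class-total species without acyl "
            f"composition: {sorted(skipped)}"
        )
    if not tally:
        raise ValueError("no molecular-level species in profile")
    total = sum(tally.values())
    acyls = sorted(tally)
    return pd.Series(
        [100.0 * tally[a] / total for a in acyls],
        index=[a.name for a in acyls],
        name="acyl_mol_pct",
    )


def stage_summary(
    df: pd.DataFrame,
    value_col: str = "amount_pmol",
    key_col: str = "species",
    anova: bool = False,
) -> pd.DataFrame:
    """Per-key, per-stage mean, SD and n.

    SD is reported as missing (NaN), not 0, for a single replicate.  With
    ``anova=True`` an auxiliary one-way ANOVA p-value across stages is
    attached per key; it is descriptive plumbing, not a calibrated test.
    """
    _check_columns(df, ["stage", key_col, value_col], "summary input")
    g = df.groupby([key_col, "stage"], sort=True)[value_col]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    out.loc[out["n"] < 2, "sd"] = np.nan
    if anova:
        from scipy.stats import f_oneway

        pvals = {}
        for key, sub in df.groupby(key_col):
            groups = [
                grp[value_col].to_numpy()
                for _, grp in sub.groupby("stage")
                if len(grp) > 0
            ]
            if len(groups) >= 2 and all(len(g_) > 1 for g_ in groups):
                pvals[key] = float(f_oneway(*groups).pvalue)
            else:
                pvals[key] = np.nan
        out["anova_p"] = out[key_col].map(pvals)
    return out
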