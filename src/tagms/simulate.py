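"""Stage-resolved synthetic lipidome generation.

The generator emulates the study conditions of a maturing high-erucic
oilseed sampled at five stages (G, GY, YG, Y, M — green through mature,
12-45 days after flowering): a mixed glycerolipid profile at the green
stage (TAG 29.3 mol%, PA 28.5%, PC 10.1%, DGDG 8.4%, MGDG 7.1%, PE 3.4%,
DAG 3.3%, PG 2.7%, the remainder split over PI/PS/SQDG) shifting to a
TAG-dominated one (79.5% at GY, 85.6% at Y, 90.8% at M), with
22:1-containing TAG and DAG species rising through maturation.  Stage
values not printed in the reference data are filled once — class shares
proportionally to the green-stage profile, within-class remainders
uniformly — and documented in the package methods note.

Replicate noise is multiplicative lognormal (concentrations are positive
and spreads are reported as CVs); simulated MS/MS spectra of sodiated TAGs
obey the sn-1/3 > sn-2 acid-loss intensity rule with salt losses far
weaker than acid losses.  A single global seed derives independent
sub-streams for profiles, responses and spectra, so each component can be
regenerated on its own, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import MS2Spectrum
from .chem import FattyAcid, acyl_neutral_losses, ion_mz
from .quantify import InternalStandardSet, default_standards
from .species import LipidSpecies, parse_species, species_formula

__all__ = [
    "MS2Model",
    "StageParams",
    "SyntheticDataset",
    "STAGES",
    "default_stage_params",
    "simulate_profile",
    "simulate_peak_table",
    "simulate_ms2",
    "generate_dataset",
    "write_dataset",
]

STAGES = ("G", "GY", "YG", "Y", "M")

_SUM_TOL = 1e-9

# --------------------------------------------------------------------------
# calibrated stage composition
#
# Printed class mole percentages; the green-stage remainder (7.2%) is split
# evenly over PI/PS/SQDG.  Later stages pin the printed values and scale the
# remaining classes proportionally to their green-stage shares.  The YG TAG
# share is not printed and is set to the GY/Y midpoint.

_G_CLASS_PCT: dict[str, float] = {
    "TAG": 29.3, "PA": 28.5, "PC": 10.1, "DGDG": 8.4, "MGDG": 7.1,
    "PE": 3.4, "DAG": 3.3, "PG": 2.7, "PI": 2.4, "PS": 2.4, "SQDG": 2.4,
}

_CLASS_PINS: dict[str, dict[str, float]] = {
    "G": dict(_G_CLASS_PCT),
    "GY": {"TAG": 79.5, "DAG": 3.0},
    "YG": {"TAG": 82.5, "DAG": 3.0},
    "Y": {"TAG": 85.6, "MGDG": 0.8, "DAG": 2.0},
    "M": {"TAG": 90.8, "PC": 5.4, "MGDG": 0.09, "DAG": 0.8},
}

# molecular species per class (canonical shorthand), with printed
# within-class percentages pinned per stage and the remainder spread
# uniformly over the unpinned species.

_TAG_SPECIES = {
    "54:4": "TAG 18:1/18:1/18:2",
    "54:5": "TAG 18:1/18:2/18:2",
    "56:3": "TAG 16:0/18:2/22:1",
    "58:4": "TAG 18:1/18:2/22:1",
    "58:5": "TAG 18:2/18:2/22:1",
    "62:4": "TAG 18:2/22:1/22:1",
    "62:5": "TAG 18:3/22:1/22:1",
    "64:4": "TAG 18:2/22:1/24:1",
}

_TAG_PCT: dict[str, dict[str, float]] = {
    "G":  {"54:4": 13, "54:5": 13, "56:3": 13, "58:4": 18, "58:5": 18,
           "62:4": 14, "62:5": 9, "64:4": 2},
    "GY": {"54:4": 5, "54:5": 5, "56:3": 10, "58:4": 16, "58:5": 16,
           "62:4": 28, "62:5": 16, "64:4": 4},
    "YG": {"54:4": 3, "54:5": 3, "56:3": 8, "58:4": 14, "58:5": 14,
           "62:4": 30, "62:5": 20, "64:4": 8},
    "Y":  {"54:4": 2, "54:5": 2, "56:3": 7, "58:4": 12, "58:5": 14,
           "62:4": 30, "62:5": 22, "64:4": 11},
    "M":  {"54:4": 2, "54:5": 2, "56:3": 7, "58:4": 12, "58:5": 16,
           "62:4": 28, "62:5": 22, "64:4": 11},
}

_DAG_SPECIES = (
    "DAG 16:0/18:2",   # 34:2
    "DAG 18:1/18:2",   # 36:3
    "DAG 18:2/18:2",   # 36:4
    "DAG 18:2/18:3",   # 36:5
    "DAG 18:3/18:3",   # 36:6
    "DAG 18:2/20:1",   # 38:3
    "DAG 18:3/20:1",   # 38:4
    "DAG 18:2/22:1",   # 40:3
    "DAG 18:3/22:1",   # 40:4
)

_DAG_PINS: dict[str, dict[str, float]] = {
    "G":  {"DAG 16:0/18:2": 22.21, "DAG 18:2/22:1": 2.6,
           "DAG 18:2/20:1": 3.2, "DAG 18:3/22:1": 3.0},
    "GY": {"DAG 18:2/22:1": 9.0, "DAG 18:2/20:1": 8.0, "DAG 18:3/22:1": 7.5},
    "YG": {"DAG 18:2/22:1": 8.8, "DAG 18:2/20:1": 7.2, "DAG 18:3/22:1": 6.4},
    "Y":  {"DAG 18:2/22:1": 12.7, "DAG 18:2/20:1": 13.6, "DAG 18:3/22:1": 9.5},
    "M":  {"DAG 18:2/22:1": 17.8, "DAG 18:2/20:1": 23.8, "DAG 18:3/22:1": 21.3},
}

_PC_SPECIES = (
    "PC 16:0/18:1",    # 34:1
    "PC 16:0/18:2",    # 34:2
    "PC 18:1/18:1",    # 36:2
    "PC 18:1/18:2",    # 36:3
    "PC 18:2/18:2",    # 36:4
    "PC 18:2/18:3",    # 36:5
    "PC 18:1/20:1",    # 38:2
    "PC 18:2/20:1",    # 38:3
    "PC 18:2/22:1",    # 40:3
)

_PC_PINS: dict[str, dict[str, float]] = {
    "G": {"PC 16:0/18:1": 14.4, "PC 16:0/18:2": 14.6,
          "PC 18:1/18:2": 19.3, "PC 18:2/18:2": 17.4},
}

_OTHER_SPECIES: dict[str, tuple[str, ...]] = {
    "PE": ("PE 16:0/18:2", "PE 18:2/18:2"),
    "PA": ("PA 16:0/18:2", "PA 18:2/22:1"),
    "PG": ("PG 16:0/18:2", "PG 16:0/18:3"),
    "PI": ("PI 16:0/18:2", "PI 18:2/18:2"),
    "PS": ("PS 16:0/18:2", "PS 18:2/22:1"),
    "MGDG": ("MGDG 16:0/18:3", "MGDG 18:3/18:3"),
    "DGDG": ("DGDG 16:0/18:3", "DGDG 18:3/18:3"),
    "SQDG": ("SQDG 16:0/18:3",),
}


@dataclass(frozen=True)
class MS2Model:
    """Intensity model of a simulated sodiated-TAG product-ion spectrum.

    Each distinct acyl contributes one acid-loss channel: base intensity if
    the acyl occupies an sn-1/3 position, base/ratio if it sits only at
    sn-2.  Salt-loss channels mirror the acid channels scaled by
    ``salt_to_acid``.  m/z values are jittered with Gaussian noise,
    intensities with multiplicative lognormal noise.
    """

    sn13_sn2_ratio: float = 2.5
    salt_to_acid: float = 0.08
    mz_jitter_sd: float = 0.02
    base_intensity: float = 100.0
    intensity_cv: float = 0.05

    def __post_init__(self):
        if self.sn13_sn2_ratio <= 0 or self.salt_to_acid <= 0:
            raise ValueError("intensity ratios must be positive")
        if self.mz_jitter_sd < 0 or self.intensity_cv < 0 or self.base_intensity <= 0:
            raise ValueError("invalid MS2 noise model")


@dataclass(frozen=True)
class StageParams:
    """Ground-truth composition and noise model of one maturation stage."""

    stage: str
    class_fractions: Mapping[str, float]
    species_fractions: Mapping[str, Mapping[str, float]]
    total_pmol: float = 2000.0
    replicate_cv: float = 0.05
    ms2: MS2Model = field(default_factory=MS2Model)

    def __post_init__(self):
        if self.total_pmol <= 0:
            raise ValueError("total lipid scale must be positive")
        if self.replicate_cv < 0:
            raise ValueError("replicate CV must be non-negative")
        s = sum(self.class_fractions.values())
        if abs(s - 1.0) > _SUM_TOL:
            raise ValueError(f"class fractions sum to {s}, expected 1")
        if any(not 0 <= f <= 1 for f in self.class_fractions.values()):
            raise ValueError("class fractions must lie in [0, 1]")
        for cls, fr in self.species_fractions.items():
            s = sum(fr.values())
            if abs(s - 1.0) > _SUM_TOL:
                raise ValueError(f"{cls} species fractions sum to {s}, expected 1")
            if any(not 0 <= f <= 1 for f in fr.values()):
                raise ValueError(f"{cls} species fractions must lie in [0, 1]")


def _fill_remainder(
    pins: Mapping[str, float], keys: Sequence[str], weights: Mapping[str, float] | None
) -> dict[str, float]:
    """Pin the printed percentages and distribute the remainder over the
    unpinned keys, proportionally to ``weights`` or uniformly."""
    pinned = sum(pins.values())
    free = [k for k in keys if k not in pins]
    out = {k: float(v) for k, v in pins.items()}
    rem = 100.0 - pinned
    if free:
        if weights is not None:
            wsum = sum(weights[k] for k in free)
            for k in free:
                out[k] = rem * weights[k] / wsum
        else:
            for k in free:
                out[k] = rem / len(free)
    # exact renormalisation to absorb float dust
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}


def default_stage_params(
    total_pmol: float = 2000.0,
    replicate_cv: float = 0.05,
    ms2: MS2Model | None = None,
) -> dict[str, StageParams]:
    """Calibrated parameters for the five maturation stages."""
    ms2 = ms2 or MS2Model()
    out: dict[str, StageParams] = {}
    class_keys = list(_G_CLASS_PCT)
    for stage in STAGES:
        cls_fr = _fill_remainder(_CLASS_PINS[stage], class_keys, _G_CLASS_PCT)
        sp_fr: dict[str, dict[str, float]] = {}
        tag = {
            _TAG_SPECIES[label]: pct for label, pct in _TAG_PCT[stage].items()
        }
        sp_fr["TAG"] = _fill_remainder(tag, list(tag), None)
        sp_fr["DAG"] = _fill_remainder(_DAG_PINS[stage], _DAG_SPECIES, None)
        sp_fr["PC"] = _fill_remainder(_PC_PINS.get(stage, {}), _PC_SPECIES, None)
        for cls, species in _OTHER_SPECIES.items():
            sp_fr[cls] = _fill_remainder({}, species, None)
        out[stage] = StageParams(
            stage=stage,
            class_fractions=cls_fr,
            species_fractions=sp_fr,
            total_pmol=total_pmol,
            replicate_cv=replicate_cv,
            ms2=ms2,
        )
    return out


def _stream_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


_PROFILE_STREAM, _RESPONSE_STREAM, _SPECTRUM_STREAM = 0, 1, 2


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_profile(
    params: StageParams | Mapping[str, StageParams],
    n_replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Ground-truth lipidome profiles, one row per replicate and species.

    amount = scale x class fraction x species fraction x LN(1, CV).
    Deterministic under a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    stage_params = params if isinstance(params, Mapping) else {params.stage: params}
    rng = _stream_rng(seed, _PROFILE_STREAM)
    rows = []
    for stage, sp in stage_params.items():
        for rep in range(1, n_replicates + 1):
            sample = f"{stage}_{rep}"
            for cls, cfrac in sp.class_fractions.items():
                for species, sfrac in sp.species_fractions.get(cls, {}).items():
                    noise = _lognormal_factor(rng, sp.replicate_cv)
                    rows.append(
                        {
                            "sample": sample,
                            "stage": stage,
                            "replicate": rep,
                            "species": species,
                            "amount_pmol": sp.total_pmol * cfrac * sfrac * float(noise),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_peak_table(
    profile: pd.DataFrame,
    standards: InternalStandardSet | None = None,
    response_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Invert quantification: turn true amounts into raw MRM responses.

    The class standard's response is fixed at 1.0 per sample, so
    response = amount / (spiked pmol x response factor); this is the exact
    inverse of internal-standard normalisation at zero noise.  Optional
    multiplicative lognormal response noise applies to endogenous species
    only (the standard defines the scale).
    """
    standards = standards or default_standards()
    rng = _stream_rng(seed, _RESPONSE_STREAM)
    rows = []
    for (sample, stage, rep), grp in profile.groupby(
        ["sample", "stage", "replicate"], sort=True
    ):
        std_added = set()
        for _, row in grp.iterrows():
            cls = parse_species(row["species"]).lipid_class
            _, std = standards.standard_for(cls)
            resp = row["amount_pmol"] / (std.pmol * std.response_factor)
            resp *= float(_lognormal_factor(rng, response_cv))
            rows.append(
                {
                    "sample": sample,
                    "stage": stage,
                    "replicate": rep,
                    "species": row["species"],
                    "response": resp,
                }
            )
            std_added.add(std.species)
        for std_species in sorted(std_added):
            rows.append(
                {
                    "sample": sample,
                    "stage": stage,
                    "replicate": rep,
                    "species": std_species,
                    "response": 1.0,
                }
            )
    return pd.DataFrame(rows)


def simulate_ms2(
    species: LipidSpecies,
    model: MS2Model | None = None,
    seed: int = 0,
    metadata: Mapping[str, object] | None = None,
) -> MS2Spectrum:
    """One simulated [TAG+Na]+ product-ion spectrum with known sn-2 truth."""
    model = model or MS2Model()
    if species.lipid_class != "TAG":
        raise ValueError("MS2 simulation is defined for TAG species only")
    if species.level != "sn" or species.sn2 is None:
        raise ValueError("species must be sn-resolved (designated sn-2 acyl)")
    rng = _stream_rng(seed, _SPECTRUM_STREAM)
    prec_theo = ion_mz(species_formula(species), "[M+Na]+")
    sn13 = list(species.acyls)
    sn13.remove(species.sn2)
    peaks = []
    for acyl in sorted(set(species.acyls)):
        acid_loss, salt_loss = acyl_neutral_losses(acyl)
        base = (
            model.base_intensity
            if acyl in sn13
            else model.base_intensity / model.sn13_sn2_ratio
        )
        for loss, inten in (
            (acid_loss, base),
            (salt_loss, base * model.salt_to_acid),
        ):
            mz = prec_theo - loss + rng.normal(0.0, model.mz_jitter_sd)
            inten = inten * float(_lognormal_factor(rng, model.intensity_cv))
            peaks.append((mz, inten))
    prec_obs = prec_theo + rng.normal(0.0, model.mz_jitter_sd)
    meta = {
        "species": str(species),
        "true_sn2": species.sn2.name,
        "model": asdict(model),
        **(metadata or {}),
    }
    return MS2Spectrum(prec_obs, tuple(peaks), adduct="[M+Na]+", metadata=meta)


@dataclass(frozen=True)
class SyntheticDataset:
    """A reproducible synthetic study: truth, raw data and spectra.

    Regenerating with the same seed and parameters reproduces every table
    and spectrum bit for bit; the parameter record travels with the data.
    """

    seed: int
    n_replicates: int
    params: Mapping[str, StageParams]
    profile: pd.DataFrame
    peak_table: pd.DataFrame
    spectra: tuple[MS2Spectrum, ...]

    @property
    def params_record(self) -> dict:
        return {
            "seed": self.seed,
            "n_replicates": self.n_replicates,
            "stages": {
                stage: {
                    "total_pmol": sp.total_pmol,
                    "replicate_cv": sp.replicate_cv,
                    "class_fractions": dict(sp.class_fractions),
                    "ms2": asdict(sp.ms2),
                }
                for stage, sp in self.params.items()
            },
        }


def _sn_resolved_tag(species_str: str) -> LipidSpecies | None:
    """Interpret a simulated TAG as sn-resolved with 18:2 at sn-2 when the
    triad contains exactly one 18:2 — the configuration the fragmentation
    rule can resolve and the one observed across the reference system."""
    sp = parse_species(species_str)
    if sp.lipid_class != "TAG":
        return None
    linoleic = FattyAcid(18, 2)
    if sum(a == linoleic for a in sp.acyls) == 1:
        return LipidSpecies.from_acyls("TAG", sp.acyls, sn2=linoleic)
    return None


def generate_dataset(
    params: Mapping[str, StageParams] | None = None,
    n_replicates: int = 3,
    seed: int = 1,
    standards: InternalStandardSet | None = None,
    response_cv: float = 0.0,
) -> SyntheticDataset:
    """Simulate the full study: profiles, raw peak table and TAG spectra."""
    params = params or default_stage_params()
    profile = simulate_profile(params, n_replicates, seed)
    peaks = simulate_peak_table(profile, standards, response_cv=response_cv, seed=seed)
    spectra = []
    for i, (stage, sp) in enumerate(params.items()):
        for species_str in sp.species_fractions.get("TAG", {}):
            resolved = _sn_resolved_tag(species_str)
            if resolved is None:
                continue
            spectra.append(
                simulate_ms2(
                    resolved, sp.ms2, seed=seed * 1000 + i, metadata={"stage": stage}
                )
            )
    return SyntheticDataset(
        seed=seed,
        n_replicates=n_replicates,
        params=dict(params),
        profile=profile,
        peak_table=peaks,
        spectra=tuple(spectra),
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write profile/peak CSVs (provenance in '#' headers) and an MGF of the
    simulated spectra with ground-truth sn-2 labels in the titles."""
    import json

    from pyteomics import mgf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# generated-by: tagms simulate\n# params: {json.dumps(dataset.params_record)}\n"
    for name, df in (("profile.csv", dataset.profile), ("peaks.csv", dataset.peak_table)):
        with open(outdir / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    entries = [
        {
            "m/z array": np.array([m for m, _ in sp.peaks]),
            "intensity array": np.array([i for _, i in sp.peaks]),
            "params": {
                "title": f"{sp.metadata.get('species')} sn2={sp.metadata.get('true_sn2')} "
                f"stage={sp.metadata.get('stage')}",
                "pepmass": (sp.precursor_mz,),
            },
        }
        for sp in dataset.spectra
    ]
    mgf.write(entries, str(outdir / "spectra.mgf"), file_mode="w")
    with open(outdir / "params.json", "w") as fh:
        json.dump(dataset.params_record, fh, indent=2)
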