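"""Annotation of sodiated triacylglycerol MS/MS spectra.

Collision-induced dissociation of [TAG+Na]+ ejects each acyl substituent
either as the free fatty acid (RCOOH) or, less efficiently, as its sodium
salt (RCOONa).  Losses from the outer sn-1/3 positions are preferred over
the sn-2 position, so among the acid-loss ions the *least* intense one
marks the sn-2 acyl — provided the outer losses dominate it clearly and,
for triads of three distinct acyls, resemble each other ("two ions of
similar abundance").  Enantiomers (sn-1 vs sn-3 swaps) are indistinguishable
and never resolved.

The annotator enumerates every acyl triad from a pool whose theoretical
[M+Na]+ m/z lies within tolerance of the observed precursor, predicts both
loss series per triad, matches them against the peak list, scores each
candidate by fragment coverage weighted by matched intensity, and calls
sn-2 on the top candidate only when it is unambiguous.  Many isobaric TAGs
can contribute to one precursor; the ambiguity flag is set whenever more
than one candidate clears the coverage threshold, and a flagged annotation
never carries an sn-2 call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import FattyAcid, Formula, acyl_neutral_losses, ion_mz
from .species import (
    DEFAULT_ACYL_POOL,
    LipidSpecies,
    enumerate_compositions,
    species_formula,
)

__all__ = [
    "MS2Spectrum",
    "FragmentPrediction",
    "FragmentMatch",
    "MatchResult",
    "TriadAnnotation",
    "AnnotatorConfig",
    "predict_fragments",
    "match_spectrum",
    "assign_sn2",
    "annotate",
    "read_spectrum",
    "write_annotation_report",
]


@dataclass(frozen=True)
class MS2Spectrum:
    """A product-ion spectrum: precursor m/z, assumed adduct, (m/z, intensity)
    peaks sorted by m/z, and free-form metadata (stage label, band id...)."""

    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]
    adduct: str = "[M+Na]+"
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        for m, i in pk:
            if not (np.isfinite(m) and np.isfinite(i)) or i < 0:
                raise ValueError(f"invalid peak ({m}, {i})")
        object.__setattr__(self, "peaks", pk)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])

    @property
    def total_intensity(self) -> float:
        return float(sum(i for _, i in self.peaks))


@dataclass(frozen=True)
class FragmentPrediction:
    """A predicted neutral loss from a sodiated TAG precursor."""

    triad: tuple[FattyAcid, ...]
    acyl: FattyAcid
    kind: str                  # 'acid' | 'sodium-salt'
    mz: float
    loss_mass: float
    sn_role: str = "undetermined"


@dataclass(frozen=True)
class FragmentMatch:
    prediction: FragmentPrediction
    observed_mz: float
    intensity: float
    error_da: float
    shared: bool = False       # one peak satisfies several predictions


@dataclass(frozen=True)
class MatchResult:
    matches: tuple[FragmentMatch, ...]
    unmatched: tuple[FragmentPrediction, ...]


@dataclass(frozen=True)
class TriadAnnotation:
    """One candidate triad with its evidence and (possibly abstained) sn-2 call."""

    triad: tuple[FattyAcid, ...]
    totals_label: str
    theoretical_precursor_mz: float
    matches: tuple[FragmentMatch, ...]
    unmatched: tuple[FragmentPrediction, ...]
    coverage: float            # in [0, 1]
    matched_intensity: float
    sn2: FattyAcid | None
    ambiguous: bool

    @property
    def triad_label(self) -> str:
        return "/".join(a.name for a in self.triad)


@dataclass(frozen=True)
class AnnotatorConfig:
    """Tunable knobs of the annotator.

    Tolerances default to 0.3 Da, the nominal-mass regime of an ion trap
    (wide enough to absorb rounding differences between reported values of
    the same ion); for high-resolution spectra use ``ppm_mode`` with a ppm
    window instead.  The dominance ratio (outer/inner acid-loss intensity
    needed for an sn-2 call) and the similarity factor (maximum spread
    tolerated between the two outer losses of an asymmetric triad) encode
    "significantly more abundant" and "similar abundance"; they are the two
    assignment thresholds and deliberately conservative.

    The coverage threshold separates genuine isobaric co-contributors from
    incidental overlap: a competitor triad sharing a single acyl with the
    species actually present can match at most its shared acid- and
    salt-loss pair, a weighted coverage of exactly 0.5 for symmetric
    triads and 1/3 for asymmetric ones.  The default of 0.6 therefore
    flags only candidates whose fragment evidence exceeds what one shared
    chain can explain.
    """

    fragment_tol: float = 0.3
    precursor_tol: float = 0.3
    ppm_mode: bool = False
    ppm_tol: float = 10.0
    dominance_ratio: float = 1.5
    similarity_factor: float = 3.0
    coverage_threshold: float = 0.6

    def fragment_window(self, mz: float) -> float:
        return mz * self.ppm_tol * 1e-6 if self.ppm_mode else self.fragment_tol

    def precursor_window(self, mz: float) -> float:
        return mz * self.ppm_tol * 1e-6 if self.ppm_mode else self.precursor_tol


def _tag_formula(triad: Sequence[FattyAcid]) -> Formula:
    return species_formula(LipidSpecies.from_acyls("TAG", triad))


def predict_fragments(
    triad: Sequence[FattyAcid],
    precursor_formula: Formula | None = None,
    adduct: str = "[M+Na]+",
) -> list[FragmentPrediction]:
    """Acid- and sodium-salt-loss predictions for each *distinct* acyl.

    Symmetric triads (A/B/A) yield four predictions, asymmetric ones six.
    Conservation holds by construction: predicted m/z + loss mass equals
    the theoretical precursor m/z.
    """
    triad = tuple(sorted(triad))
    if len(triad) != 3:
        raise ValueError(f"a TAG triad has 3 acyls, got {len(triad)}")
    formula = _tag_formula(triad)
    if precursor_formula is not None and precursor_formula != formula:
        raise ValueError(
            f"precursor formula {precursor_formula} does not match triad "
            f"{'/'.join(a.name for a in triad)} ({formula})"
        )
    prec_mz = ion_mz(formula, adduct)
    out = []
    for acyl in sorted(set(triad)):
        acid, salt = acyl_neutral_losses(acyl)
        out.append(FragmentPrediction(triad, acyl, "acid", prec_mz - acid, acid))
        out.append(FragmentPrediction(triad, acyl, "sodium-salt", prec_mz - salt, salt))
    return out


def match_spectrum(
    spectrum: MS2Spectrum,
    predictions: Iterable[FragmentPrediction],
    tolerance: float = 0.3,
) -> MatchResult:
    """Match each prediction to its nearest peak within the tolerance.

    One peak may satisfy several near-isobaric predictions; such matches
    are flagged ``shared`` rather than arbitrated.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    mz = spectrum.mz
    matches: list[FragmentMatch] = []
    unmatched: list[FragmentPrediction] = []
    hits: list[int] = []
    for pred in predictions:
        if len(mz) == 0:
            unmatched.append(pred)
            continue
        idx = int(np.argmin(np.abs(mz - pred.mz)))
        err = float(mz[idx] - pred.mz)
        if abs(err) <= tolerance:
            matches.append(
                FragmentMatch(pred, float(mz[idx]), float(spectrum.intensity[idx]), err)
            )
            hits.append(idx)
        else:
            unmatched.append(pred)
    counts = {i: hits.count(i) for i in hits}
    shared_idx = {i for i, c in counts.items() if c > 1}
    if shared_idx:
        matches = [
            replace(m, shared=True)
            if int(np.argmin(np.abs(mz - m.prediction.mz))) in shared_idx
            else m
            for m in matches
        ]
    return MatchResult(tuple(matches), tuple(unmatched))


def assign_sn2(
    triad: Sequence[FattyAcid],
    acid_intensities: Mapping[FattyAcid, float],
    dominance_ratio: float = 1.5,
    similarity_factor: float = 3.0,
) -> FattyAcid | None:
    """Call the sn-2 acyl from acid-loss intensities, or abstain (None).

    The least intense acid-loss channel is the sn-2 candidate.  The call is
    made iff every other channel is at least ``dominance_ratio`` times the
    minimum and, for triads of three distinct acyls, the two outer channels
    agree within ``similarity_factor``.  Missing channels, single-acyl
    triads, and ties all abstain; abstention is a value, not an error.
    """
    distinct = sorted(set(triad))
    if len(distinct) < 2:
        return None
    if any(a not in acid_intensities for a in distinct):
        return None
    intensities = {a: float(acid_intensities[a]) for a in distinct}
    sn2 = min(intensities, key=lambda a: (intensities[a], a))
    low = intensities[sn2]
    others = [v for a, v in intensities.items() if a != sn2]
    if not all(v >= dominance_ratio * low for v in others):
        return None
    if len(distinct) == 3:
        hi, lo = max(others), min(others)
        if lo <= 0 or hi / lo > similarity_factor:
            return None
    return sn2


def _candidate_triads(
    spectrum: MS2Spectrum,
    pool: Sequence[FattyAcid],
    config: AnnotatorConfig,
) -> list[tuple[tuple[FattyAcid, ...], float]]:
    prec = spectrum.precursor_mz
    cmin, cmax = min(a.carbons for a in pool), max(a.carbons for a in pool)
    dbmax = max(a.double_bonds for a in pool)
    out = []
    seen_totals = set()
    for c in range(3 * cmin, 3 * cmax + 1):
        for db in range(0, 3 * dbmax + 1):
            if (c, db) in seen_totals:
                continue
            seen_totals.add((c, db))
            try:
                mz = ion_mz(_totals_formula(c, db), spectrum.adduct)
            except ValueError:
                continue
            if abs(mz - prec) > config.precursor_window(prec):
                continue
            for triad in enumerate_compositions("TAG", c, db, pool):
                out.append((triad, mz))
    return out


def _totals_formula(c: int, db: int) -> Formula:
    from .species import class_total_formula

    return class_total_formula("TAG", c, db)


def annotate(
    spectrum: MS2Spectrum,
    pool: Sequence[FattyAcid] = DEFAULT_ACYL_POOL,
    config: AnnotatorConfig | None = None,
) -> list[TriadAnnotation]:
    """Rank candidate triads for one spectrum and call sn-2 when safe.

    Coverage is the weighted fraction of predicted fragments observed, with
    acid losses weighted twice the much weaker salt losses; it lies in
    [0, 1].  Ranking is by coverage, then summed matched intensity (so
    among structurally equivalent candidates the one explaining more ion
    current wins), then lexicographic triad order — a deterministic,
    documented tie-break.  sn-2 is called only on the top candidate, only
    for sodiated precursors, and only when no other candidate clears the
    coverage threshold.
    """
    cfg = config or AnnotatorConfig()
    candidates = _candidate_triads(spectrum, pool, cfg)
    anns: list[TriadAnnotation] = []
    for triad, theo_mz in candidates:
        preds = predict_fragments(triad)
        result = match_spectrum(spectrum, preds, cfg.fragment_window(theo_mz))
        w_tot = sum(2.0 if p.kind == "acid" else 1.0 for p in preds)
        w_hit = sum(2.0 if m.prediction.kind == "acid" else 1.0 for m in result.matches)
        matched_peaks = {m.observed_mz: m.intensity for m in result.matches}
        matched_int = float(sum(matched_peaks.values()))
        coverage = w_hit / w_tot
        anns.append(
            TriadAnnotation(
                triad=triad,
                totals_label=(
                    f"{sum(a.carbons for a in triad)}:"
                    f"{sum(a.double_bonds for a in triad)}"
                ),
                theoretical_precursor_mz=theo_mz,
                matches=result.matches,
                unmatched=result.unmatched,
                coverage=coverage,
                matched_intensity=matched_int,
                sn2=None,
                ambiguous=False,
            )
        )
    anns.sort(key=lambda a: (-a.coverage, -a.matched_intensity, a.triad))
    n_above = sum(a.coverage >= cfg.coverage_threshold for a in anns)
    ambiguous = n_above > 1
    out = []
    for rank, ann in enumerate(anns):
        sn2 = None
        if (
            rank == 0
            and not ambiguous
            and spectrum.adduct == "[M+Na]+"
            and ann.coverage >= cfg.coverage_threshold
        ):
            acid_int = {
                m.prediction.acyl: m.intensity
                for m in ann.matches
                if m.prediction.kind == "acid"
            }
            sn2 = assign_sn2(
                ann.triad, acid_int, cfg.dominance_ratio, cfg.similarity_factor
            )
        out.append(replace(ann, sn2=sn2, ambiguous=ambiguous))
    return out


# ---------------------------------------------------------------------------
# IO


def read_spectrum(path, adduct: str = "[M+Na]+") -> MS2Spectrum:
    """Read an MGF peak list (first spectrum; PEPMASS as precursor) or a
    two-column m/z,intensity CSV with a ``# precursor=<mz>`` header line."""
    path = str(path)
    if path.lower().endswith(".mgf"):
        from pyteomics import mgf

        with mgf.MGF(path) as reader:
            try:
                entry = next(iter(reader))
            except StopIteration:
                raise ValueError(f"{path}: no spectra found") from None
        prec = float(entry["params"]["pepmass"][0])
        peaks = tuple(zip(entry["m/z array"], entry["intensity array"]))
        meta = {
            k: v for k, v in entry["params"].items() if k not in ("pepmass", "charge")
        }
        return MS2Spectrum(prec, peaks, adduct=adduct, metadata=meta)
    prec = None
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "precursor" in line and "=" in line:
                    prec = float(line.split("=", 1)[1])
                continue
            parts = line.replace(",", " ").split()
            if parts[0].lower() in ("mz", "m/z"):
                continue
            peaks.append((float(parts[0]), float(parts[1])))
    if prec is None:
        raise ValueError(f"{path}: missing '# precursor=<mz>' header")
    return MS2Spectrum(prec, tuple(peaks), adduct=adduct)


def write_annotation_report(annotations: Sequence[TriadAnnotation], csv_path, json_path=None):
    """Write one CSV row per candidate triad, plus optional full-detail JSON."""
    import pandas as pd

    rows = [
        {
            "triad": a.triad_label,
            "totals": a.totals_label,
            "theoretical_precursor_mz": a.theoretical_precursor_mz,
            "coverage": a.coverage,
            "matched_intensity": a.matched_intensity,
            "n_matched": len(a.matches),
            "n_unmatched": len(a.unmatched),
            "sn2": a.sn2.name if a.sn2 else "",
            "ambiguous": a.ambiguous,
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        detail = [
            {
                "triad": a.triad_label,
                "totals": a.totals_label,
                "theoretical_precursor_mz": a.theoretical_precursor_mz,
                "coverage": a.coverage,
                "ambiguous": a.ambiguous,
                "sn2": a.sn2.name if a.sn2 else None,
                "matches": [
                    {
                        "acyl": m.prediction.acyl.name,
                        "kind": m.prediction.kind,
                        "predicted_mz": m.prediction.mz,
                        "observed_mz": m.observed_mz,
                        "intensity": m.intensity,
                        "error_da": m.error_da,
                        "shared": m.shared,
                    }
                    for m in a.matches
                ],
                "unmatched": [
                    {"acyl": p.acyl.name, "kind": p.kind, "predicted_mz": p.mz}
                    for p in a.unmatched
                ],
            }
            for a in annotations
        ]
        with open(json_path, "w") as fh:
            json.dump(detail, fh, indent=2)
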