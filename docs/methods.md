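# Methods

## Mass model

All arithmetic is monoisotopic. Atomic masses (H, C, N, O, Na, P, S) are
hard-coded from the IUPAC/CIAAW table at ≥ 6 decimals; there is no runtime
lookup. Ion m/z applies the electron-mass correction
(m<sub>e</sub> = 0.000548579909 Da): positive ions are lighter by
z·m<sub>e</sub>, negative ions heavier. The correction is a per-call toggle
defaulting to on; without it sodiated TAG masses come out ≈ 5 × 10⁻⁴ Da
heavy and no longer match four-decimal high-resolution reference values.
m/z is carried at full double precision; rounding happens only in
presentation and peak matching.

Neutral species formulas are assembled as

    glycerol (C3H8O3) + Σ free acids (CcH2c−2dbO2) + head compound
      − (n_acyl + n_head) · H2O

where the head compounds are the free alcohols/acids (phosphocholine,
phosphoethanolamine, phosphoserine, glycerophosphate, inositol phosphate,
phosphoric acid, galactose, digalactose, sulfoquinovose) and attachment
condenses one water. Cardiolipin is special-cased: three glycerols bridged
by two phosphodiesters, i.e. n_acyl + 4 condensations. Acyl identity is the
(carbons, double-bonds) pair only; double-bond position and geometry are
not modelled, so 22:1Δ13 and any positional isomer are the same species.

## Species grammar

Three resolution levels: class-total ("TAG 62:4"), molecular
("TAG 22:1/18:2/22:1") and sn-resolved (molecular plus a designated sn-2
acyl). "/" and "-" are both accepted separators on input; "/" is canonical
on output. A bare acyl list infers the class from the count (2 → DAG,
3 → TAG, 4 → CL). sn-resolved output places the sn-2 chain in the middle
position, with the caveat that the flanking positions are an unresolved
sn-1/3 *pair* — the fragmentation chemistry cannot separate enantiomers,
and neither does the data model. Because plain text cannot carry positional
information, parsing an acyl list always yields molecular level; round
trips preserve class, totals and the acyl multiset.

## Acquisition planning

Head-group diagnostics are derived from the stored head formulas:

| class | scan | adduct | diagnostic | CE (eV) |
|---|---|---|---|---|
| PC | precursor-of | [M+H]⁺ | 184.0733 | 35 |
| SQDG | precursor-of | [M−H]⁻ | 225.0074 | −55 |
| PE, PS | neutral loss | [M+H]⁺ | 141.0191, 185.0089 | 29, 21 |
| PI, PG, PA | neutral loss | [M+NH₄]⁺ | head + NH₃: 277.0563, 189.0402, 115.0035 | 21, 25, 25 |
| MGDG, DGDG | neutral loss | [M+NH₄]⁺ | residue + NH₃: 179.0794, 341.1322 | 8, 11 |

The adduct-per-class assignment (PE/PS protonated, the others ammoniated)
is the only arithmetic that reproduces the integer nominals used on triple
quadrupoles; it is fixed here and stated prominently because acquisition
methods rarely spell it out. Nominals are round-half-away-from-zero of the
exact loss.

DAG and TAG are quantified as [M+NH₄]⁺ MRM pairs at CE 19/26 eV, 30 ms
dwell; CL as [M−H]⁻ at −45 eV, 50 ms. The product ion for a
molecular-level DAG/TAG is the loss of its largest acyl as RCOOH + NH₃ (a
[M+H−RCOOH]⁺-type fragment); for class-total species, whose acyls are
unknown, the ammonia-loss product is used as a placeholder and documented
as such. CL product ions are the largest acyl carboxylate anion, so
class-total CL input is rejected rather than guessed. Chromatographic
settings are free-text metadata in output headers only.

## TAG MS/MS annotation

Candidate generation: every (C, DB) total whose theoretical [M+Na]⁺ lies
within the precursor tolerance is expanded into acyl triads over the pool
(default: 16:0, 16:1, 18:0, 18:1, 18:2, 18:3, 20:0, 20:1, 22:1, 24:1 — the
chains observed in the target seed system). Per distinct acyl the acid and
sodium-salt losses are predicted (4 predictions for symmetric A/B/A triads,
6 for asymmetric); conservation (fragment + loss = precursor) holds by
construction to 10⁻⁶ Da.

Matching takes each prediction to its nearest peak within tolerance.
Near-isobaric predictions may legitimately share one peak (e.g. an 18:3
acid loss and a 16:0 salt loss differ by only ~0.003 Da); shared matches
are flagged, never arbitrated.

Scoring: coverage is the weighted fraction of predicted fragments observed,
acid losses counting twice the far weaker salt losses (salt losses support
a candidate but are never required for a positional call). Ranking is by
coverage, then summed matched intensity, then lexicographic triad order — a
deterministic tie-break; ties are additionally surfaced through the
ambiguity flag rather than silently resolved.

The ambiguity threshold (default 0.6) comes from an identifiability
argument: a competitor triad sharing exactly one acyl with the species
actually present can match at most that chain's acid + salt pair, giving
coverage 0.5 for a symmetric competitor and 1/3 for an asymmetric one.
Candidates above 0.6 therefore carry more fragment evidence than any
single shared chain can explain; when two or more candidates clear it, the
annotation is flagged ambiguous and sn-2 is abstained for all — mirroring
the practice of not excluding co-eluting isomers on crowded precursors.

sn-2 assignment: among matched acid-loss channels the least intense marks
the sn-2 chain, called only if every other channel is ≥ r times the
minimum (dominance ratio, default 1.5) and, for triads of three distinct
chains, the two outer channels agree within a factor s (similarity, default
3.0). Missing channels, single-chain triads and ties abstain; abstention is
a value, not an error. Only sodiated precursors are eligible for positional
calls — ammoniated spectra can be annotated compositionally but always
abstain on position. Default tolerances are 0.3 Da for both precursor and
fragments (ion-trap nominal-mass regime; wide enough to absorb the ~0.1 Da
scatter between independently reported values of the same fragment); a
10 ppm mode serves high-resolution spectra.

The intensity rule can only resolve triads whose sn-2 chain occurs exactly
once: if the sn-2 chain also occupies an outer position, its loss channel
is fed from both positions and the minimum-intensity criterion goes
uninformative — such spectra abstain by design.

## Quantification

amount (pmol) = response / response(class standard) × spiked pmol ×
response factor. The default spike set is 125 pmol each of PE 18:0/18:0,
DAG 18:0/22:6 and SQDG 16:0/18:0; classes without a spike borrow one via an
explicit fallback table (phospholipids and CL → PE, TAG → DAG,
galactolipids → SQDG). There are no silent defaults: an unmapped class and
a sample missing its standard row are both errors naming the offender.
Response factors model per-class QC correction and default to 1.0 (no QC
reference values are bundled). Standard rows are excluded from the output
profile. All summaries are mole fractions; per-sample totals are not
renormalized to injected amount because every downstream fraction is
invariant to that scaling. A species absent from a sample is 0 pmol; SD
over a single replicate is reported missing, not zero. All operations are
pure transformations of their input frames.

## Synthetic data

Class mole fractions are calibrated to the reference maturation study:
green-stage values as measured (TAG 29.3 … PG 2.7, remainder split evenly
over PI/PS/SQDG), TAG pinned at 79.5 / 82.5 / 85.6 / 90.8% for GY/YG/Y/M
(the YG value is not reported and is set to the GY–Y midpoint), plus the
reported PC, MGDG and DAG trajectories; unpinned classes scale
proportionally to their green-stage shares so fractions always sum to 1.
Within-class distributions pin the reported species values (DAG 34:2 at
22.21% green; the DAG 38:3/40:3/40:4 trajectories; the four major PC
species at green) and spread remainders uniformly over the default species
list. The eight TAG species span 54:4 through 64:4 with 22:1-containing
species rising through maturation.

Replicate noise is multiplicative lognormal with unit mean — concentrations
are positive and spreads are reported as CVs, so additive Gaussian noise
was rejected. The default CV is 5%, a typical targeted-lipidomics replicate
spread; the reference figures quote SD bars without numbers, so this is a
package choice, exposed in config. The peak-table inverter fixes each
standard's response at 1.0 and divides amounts by the spiked pmol, making
normalization its exact inverse up to one floating-point rounding.

Simulated [TAG+Na]⁺ spectra emit one acid-loss channel per distinct acyl
(base intensity 100 for sn-1/3 chains, base/ratio for the sn-2-only chain,
dominance ratio default 2.5), salt channels at 8% of their acid channel,
Gaussian m/z jitter (SD 0.02 Da) and lognormal intensity jitter (CV 5%).
One global seed derives independent sub-streams (profiles, responses,
spectra) via numpy SeedSequence spawn keys, so any component regenerates
bit-for-bit on its own; every written dataset embeds its parameter record.

What the generator does *not* emulate: chromatographic peak shape and
integration error, isotopic envelopes, in-source fragmentation, co-eluting
isobaric mixtures within one spectrum, detector saturation, and
between-batch drift. Passing tests therefore demonstrate the correctness of
the arithmetic and the decision rules under the stated noise model, not
robustness to every artefact of real instrument data.

## Numerical choices and degenerate inputs

- Problem sizes: property checks use 200 simulated spectra and 100–1000
  Monte-Carlo replicates — large enough for the binomial/SE arguments in
  the tests while keeping the whole suite in seconds.
- Round-half-away-from-zero for nominal masses (not banker's rounding).
- Empty species list → empty transition table; empty spectrum → candidates
  with zero coverage, all abstained; no candidate totals in tolerance →
  empty annotation list; all-zero sample → error (fractions undefined).
- An empty acyl set cannot be validated against a C:DB label and raises
  rather than returning vacuous truth.
- Formula subtraction that would drive an element negative raises; the
  deprotonated adduct is expressed as a subtraction so [M−H]⁻ on a
  hydrogen-free formula fails loudly.

## Known limitations

- Positional analysis is relative-intensity based; it cannot see TAG
  enantiomers, mixtures of regioisomers under one precursor beyond the
  ambiguity flag, or sn-2 chains that repeat at an outer position.
- The label grammar treats (C:DB) as identity; distinct double-bond
  positional isomers are indistinguishable.
- MRM product ions for class-total neutral lipids are placeholders (see
  Acquisition planning) pending molecular-level input.
- The quantification model is single-point (one standard per class, linear
  response); saturation and cross-class response differences beyond the
  scalar factor are out of scope.
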