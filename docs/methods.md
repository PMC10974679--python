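# Methods

## Problem setting

Designer drugs ("new psychoactive substances", NPS) are produced by small
structural modifications of known illicit compounds, which preserves the
pharmacology while changing the EI mass spectrum enough to defeat reference
library search. `npscreen` addresses the resulting identification gap: given
the GC/EI-MS spectrum of an unknown that matches no library entry, it builds
a database of plausible derivatives of a chosen template drug and ranks them
against the unknown with an integrated spectrum + fingerprint similarity
score, returning a short list of candidate structures for confirmatory
synthesis.

## Derivative enumeration

The template's heavy-atom skeleton is held fixed; only hydrogens are
replaced. Each functional group in the modification library is an R-group
fragment with a single attachment point (a `*` dummy atom). Replacing a
hydrogen removes one H from the addressed heavy atom and forms a single bond
to the fragment's anchor atom; products that violate valence rules are
silently skipped. Applying this recursively to depth *n* yields all
derivatives with 1..*n* modifications, deduplicated by canonical SMILES
(RDKit canonicalization is the identity key everywhere). "Depth *d*" means
exactly *d* modifications; the emitted database covers depths 1..*n*
cumulatively. Sites are visited in canonical atom order, which is irrelevant
to the final set because of the canonical dedup.

### Synthesis-difficulty pruning

The enumeration space grows exponentially, and some modifications are far
harder to synthesize than others. Before enumeration, each functional group
is stress-tested: it is added to the template *d* times in all distinct
ways, the resulting compounds are scored with a synthesis-complexity scorer,
and the group is retained at recursion depth *d* (for *d* ≥ 2) only if the
mean score increase over the template (ΔSCScore) is strictly below α^*d*
(defaults α = 1.2, *n* = 3; α must exceed 1, and larger values retain more
groups at more depths). Depth 1 always retains the full library. The
averaging set is capped at 256 canonically distinct products per (group,
depth), subsampled uniformly with a fixed internal seed, so the pruning pass
is bounded and deterministic.

The scorer is a contract: any deterministic `Mol -> float`. The shipped
`HeuristicComplexityScorer` is a structural proxy — a weighted count of
heavy atoms (0.06 each), rings (0.30), heteroatoms (0.08) and stereocenters
(0.20), offset by 1 and clipped to the 1–5 range conventional for
reaction-step complexity scores. A trained synthesis-complexity model can be
plugged in through the same contract; retained-group counts will differ
accordingly.

## Drug-likeness filtering

After enumeration, a registry of 57 pure predicates removes unstable or
pharmaceutically implausible structures. The registry is data-driven
(`druglike_rules_synthetic.tsv`, a curated in-house compilation): each line
names a predicate family (forbidden SMARTS substructure, capped descriptor,
element whitelist, SSSR cap) and its parameters, so the set can be audited
or replaced. The messy-rings rule (fail if the molecule has more than 7
smallest sets of smallest rings) is the pinned literature threshold; the
remaining caps (MW ≤ 900, Crippen logP ≤ 7.5, rotatable bonds ≤ 12, ≤ 7
donors / ≤ 12 acceptors, neutral net charge, no reactive groups such as
peroxides, acyl halides, azides, enols, hemiacetals, …) are package choices
in the spirit of published stability filters. A molecule fails iff any rule
fails; for the per-rule statistics the failure is attributed to the first
failing rule in priority order (messy rings first), and the per-rule
proportions plus the retention rate sum to 1 by construction.

## Spectra

Spectra are nominal-mass stick spectra over integer m/z bins 1..700 (the
default covers all molecules in scope; configurable). Intensities are
base-peak normalized to 1.0 internally and scaled to 999 on MSP export
(NIST convention). Raw peaks are binned by nearest-integer rounding (halves
round up, fixed for determinism); collisions within a bin are summed.
MSP reading and writing go through matchms.

Spectrum prediction is a contract (`MoleculeRecord -> MassSpectrum`). The
shipped baseline is a single-cleavage fragmenter: the molecular ion at the
nominal mass with intensity 1.0, plus — for every acyclic single bond
between heavy atoms — the heavier fragment of that cleavage at its nominal
mass (each fragment keeps its hydrogens), with intensity equal to the
fragment's share of the molecule's heavy atoms; colliding fragments keep the
larger intensity. This ignores rearrangements, multi-bond cleavages and
charge-site chemistry; it exists so every downstream stage has a fixed,
explainable spectrum source, not as a physical model. Consequences worth
knowing: positional isomers often get byte-identical baseline spectra, and
the M+ peak is always present (real EI spectra may lack it).

Molecular-mass inference takes a metadata mass when present (emulating a
complementary soft-ionization measurement), else the highest m/z bin with
relative intensity ≥ 1% is treated as the molecular ion; if neither exists
the mass is unknown. The mass filter keeps candidates within ±1 Da of the
analyte mass by default (absorbing isotope and prediction artifacts), has a
±5 Da preset, and can be lifted entirely — with an unknown mass it passes
everything.

## Similarity and ranking

Candidates are ranked by SMSF, a convex combination of three [0, 1]
components:

* **cosine similarity** between the binned intensity vectors;
* **top-n Jaccard** (n = 4): the Jaccard index between the m/z positions of
  the n most intense peaks of each spectrum, capturing the prominent-peak
  pattern an analyst inspects first (intensity ties at the cutoff are broken
  toward lower m/z, fixed for determinism);
* **fingerprint similarity**: the Jaccard (Tanimoto) index between the
  candidate's Morgan fingerprint (radius 2, 2048 bits, configurable) and
  the fingerprint predicted from the analyte spectrum. Probabilistic
  fingerprints are binarized at 0.5 first; two all-zero fingerprints score 0.

Default weights are equal thirds. `optimize_weights` recalibrates them on a
labelled validation set by exhaustive search over a simplex lattice,
minimizing the mean relative ranking position (RRP) of the true candidates;
ties prefer cosine-heavy, then Jaccard-heavy points. The
spectrum-to-fingerprint step is a contract; the shipped baseline returns the
cosine-weighted mean fingerprint of the k nearest reference spectra (k = 5
default) — a retrieval model, deterministic given the reference list.

The screening report sorts by SMSF descending with ties broken by canonical
SMILES (isomers can tie exactly), and declares a match iff the top score
strictly exceeds the threshold (default τ = 0.55, the pinned literature
value; always recorded in the report so recalibration is auditable).

### Threshold calibration

Given similarity scores for a positive (derivative-like) and a negative
class, each class is fitted with a Gaussian (sample mean, sample SD with
ddof = 1) and τ is placed at the intersection of the two densities: equating
log-densities gives a quadratic in the score, both roots are reported, and
the root between the class means is selected. Equal SDs degenerate to the
midpoint of the means. Identical fitted distributions or zero variance are
errors, not silent defaults.

## Evaluation metrics

RRP of a truth ranked r among N candidates is (r − 1)/(N − 1) — 0 for a
perfect top rank, 0.5 in expectation under random ranking (the definition is
chosen precisely so that the random anchor is exactly 0.5); a sole candidate
scores 0. Ranking-proportion curves report the fraction of queries whose
truth ranks ≤ k. Confusion metrics (sensitivity, specificity, precision,
F1) report NaN, not 0, when a denominator is empty.

## Synthetic test world

`make_toy_world` pairs a small aromatic template (toluene, phenol or
fluorobenzene, selected by seed) with a fixed four-group library (methyl,
fluoro, hydroxy, methoxy); depth-2 enumeration yields 114–175 derivatives,
small enough for whole-pipeline tests in seconds. `simulate_analyte`
multiplies each predicted peak intensity by exp(σ·z) with seeded standard
normal z (log-normal multiplicative noise, the stand-in for purity and
instrument variation), drops peaks below a floor, and renormalizes; σ = 0
with floor 0 reproduces the predicted spectrum exactly. The generator does
not emulate instrument artifacts (column bleed, co-elution) or missing M+
peaks, so passing tests demonstrate pipeline correctness under controlled
perturbation, not field performance on real seized samples.

`holdout_experiment` enumerates the toy database, holds out one member,
simulates its analyte spectrum and screens it. By default the analyte
fingerprint is the held-out member's own structure fingerprint — an ideal
spectrum-to-fingerprint model — because baseline spectra of positional
isomers are identical and a spectrum-derived fingerprint therefore cannot
distinguish them even in principle; this choice isolates the effect of
spectral noise on ranking. With `fingerprint_source="knn"` the retrieval
baseline is used instead, and isomer ties surface exactly as they do in
real screens. Under the oracle default, the noiseless hold-out provably
ranks the truth first with SMSF 1.0 (isomers lose strictly on the
fingerprint term); at σ = 0.1 the truth stays in the top 3 in 20/20 seeded
runs (regression-pinned), and an out-of-world aliphatic control scores far
below τ (top SMSF ≈ 0.06) and is declared no-match.

## Numerical and degenerate-input choices

* Nominal mass = sum of most-abundant-isotope mass numbers (explicit isotope
  labels honored); always within 1 Da of the rounded monoisotopic mass.
* Canonical SMILES identity for all dedup; stereo marks are preserved but
  never enumerated.
* Binning rounds half up; bin 0 and bins beyond max_mz are hard errors.
* Cosine against an all-zero spectrum is an error, not 0.
* Fingerprint binarization cutoff 0.5; Jaccard of two empty bit sets is 0.
* All randomness (noise, hold-out selection, ΔSCScore subsampling) is
  seeded; identical inputs give byte-identical reports.

## Known limitations

* The baseline predictors are intentionally simple; reported ranks quantify
  the pipeline, not the attainable accuracy with trained spectrum and
  fingerprint models.
* The heuristic complexity scorer orders molecules by size/complexity only;
  pruning decisions with a trained model will differ.
* The shipped functional-group library and rule registry are curated
  stand-ins (see the file headers); both are replaceable via the documented
  tabular formats.
* Isomer discrimination is limited by the spectrum source — an inherent
  property of nominal-mass EI data that trained predictors only partially
  overcome.
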