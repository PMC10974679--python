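"""Candidate database construction, query screening and threshold calibration.

The screening pipeline mirrors how an unknown EI spectrum is matched
against a database of enumerated derivatives:

1. infer the analyte's molecular mass from its spectrum (or take the mass
   supplied by a soft-ionization run) and discard candidates outside the
   mass tolerance (default +/-1 Da, liftable);
2. predict the analyte's fingerprint from its spectrum (once per query);
3. score every surviving candidate with SMSF (cosine + top-4 Jaccard
   spectrum similarity + fingerprint Jaccard);
4. rank by SMSF (ties broken by canonical SMILES for reproducibility) and
   declare a match iff the top score exceeds the decision threshold.

The default threshold 0.55 separates derivative-like from unrelated
analytes on reference score distributions; :func:`calibrate_threshold`
refits it for any user-supplied positive/negative score sets by locating
the intersection of the two fitted Gaussian densities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_core import Fingerprint, MoleculeRecord, structure_fingerprint
from .similarity import (
    FingerprintPredictor,
    SmsfWeights,
    cosine_similarity,
    fp_similarity,
    smsf,
    top_n_jaccard,
)
from .spectra import (
    MassSpectrum,
    SpectrumPredictor,
    infer_molecular_mass,
    mass_filter,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.55

__all__ = [
    "DEFAULT_THRESHOLD",
    "CandidateDatabase",
    "CandidateScore",
    "ScreeningReport",
    "ThresholdModel",
    "build_database",
    "calibrate_threshold",
    "screen",
]


@dataclass(frozen=True)
class CandidateEntry:
    record: MoleculeRecord
    spectrum: MassSpectrum
    fingerprint: Fingerprint


@dataclass
class CandidateDatabase:
    """Deduplicated candidate records with spectra, fingerprints and a mass index."""

    entries: list[CandidateEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_smiles = {e.record.canonical_smiles: e for e in self.entries}
        if len(self._by_smiles) != len(self.entries):
            raise ValueError("database entries must be unique by canonical SMILES")
        self._by_mass: dict[int, list[CandidateEntry]] = {}
        for e in self.entries:
            self._by_mass.setdefault(e.record.nominal_mass, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, smiles: str) -> bool:
        return smiles in self._by_smiles

    def get(self, smiles: str) -> CandidateEntry:
        return self._by_smiles[smiles]

    def by_mass(self, mass: int, tol: int = 0) -> list[CandidateEntry]:
        out: list[CandidateEntry] = []
        for m in range(mass - tol, mass + tol + 1):
            out.extend(self._by_mass.get(m, []))
        return out


def build_database(
    mols: Iterable[MoleculeRecord],
    predictor: SpectrumPredictor,
    fp_length: int = 2048,
) -> CandidateDatabase:
    """Predict a spectrum and compute a structure fingerprint for every molecule.

    Duplicate canonical SMILES collapse to one entry.  A predictor failure on
    a molecule skips that record with a logged warning rather than aborting
    the build.
    """
    entries = []
    seen: set[str] = set()
    for mol in mols:
        if mol.canonical_smiles in seen:
            continue
        seen.add(mol.canonical_smiles)
        try:
            spectrum = predictor(mol)
        except Exception as exc:  # predictor contract: any failure skips
            logger.warning(
                "spectrum prediction failed for %s: %s", mol.canonical_smiles, exc
            )
            continue
        fp = mol.fingerprint
        if fp is None or fp.length != fp_length:
            fp = structure_fingerprint(mol.mol(), fp_length)
        entries.append(CandidateEntry(mol.with_fingerprint(fp), spectrum, fp))
    return CandidateDatabase(entries)


@dataclass(frozen=True)
class CandidateScore:
    smiles: str
    nominal_mass: int
    cos: float
    jac: float
    fps: float
    smsf: float


@dataclass
class ScreeningReport:
    """Ranked candidates with component similarities and the match decision."""

    ranked: list[CandidateScore]
    decision: bool
    threshold: float
    analyte_name: str = ""
    analyte_mass: int | None = None
    weights: SmsfWeights = field(default_factory=SmsfWeights)

    @property
    def top_score(self) -> float | None:
        return self.ranked[0].smsf if self.ranked else None

    def rank_of(self, smiles: str) -> int | None:
        """Positional rank (1-based) of a candidate, or None if absent."""
        for i, cand in enumerate(self.ranked, 1):
            if cand.smiles == smiles:
                return i
        return None

    def to_frame(self, top: int | None = None) -> pd.DataFrame:
        rows = self.ranked if top is None else self.ranked[:top]
        return pd.DataFrame(
            {
                "rank": range(1, len(rows) + 1),
                "smiles": [r.smiles for r in rows],
                "nominal_mass": [r.nominal_mass for r in rows],
                "cos": [r.cos for r in rows],
                "jac4": [r.jac for r in rows],
                "fp_sim": [r.fps for r in rows],
                "smsf": [r.smsf for r in rows],
                "above_threshold": [r.smsf > self.threshold for r in rows],
            }
        )


def screen(
    analyte: MassSpectrum,
    db: CandidateDatabase,
    fpred: FingerprintPredictor,
    weights: SmsfWeights = SmsfWeights(),
    tol: int | None = 1,
    threshold: float = DEFAULT_THRESHOLD,
    top_n: int = 4,
    mass_floor: float = 0.01,
) -> ScreeningReport:
    """Rank database candidates against an analyte spectrum and decide match.

    ``tol=None`` lifts the mass filter.  An empty database after mass
    filtering yields an empty report with a no-match decision.
    """
    if len(db) == 0:
        raise ValueError("candidate database is empty")
    analyte_mass = infer_molecular_mass(analyte, floor=mass_floor)
    records = [e.record for e in db.entries]
    survivors = mass_filter(records, analyte_mass, tol)
    analyte_fp = fpred(analyte)
    scored = []
    for record in survivors:
        entry = db.get(record.canonical_smiles)
        cos = cosine_similarity(analyte, entry.spectrum)
        jac = top_n_jaccard(analyte, entry.spectrum, top_n)
        fps = fp_similarity(analyte_fp, entry.fingerprint)
        scored.append(
            CandidateScore(
                smiles=record.canonical_smiles,
                nominal_mass=record.nominal_mass,
                cos=cos,
                jac=jac,
                fps=fps,
                smsf=smsf(cos, jac, fps, weights),
            )
        )
    scored.sort(key=lambda c: (-c.smsf, c.smiles))
    decision = bool(scored) and scored[0].smsf > threshold
    return ScreeningReport(
        ranked=scored,
        decision=decision,
        threshold=threshold,
        analyte_name=analyte.name,
        analyte_mass=analyte_mass,
        weights=weights,
    )


@dataclass(frozen=True)
class ThresholdModel:
    """Two fitted Gaussians over similarity scores and their intersection."""

    pos_mean: float
    pos_sd: float
    neg_mean: float
    neg_sd: float
    threshold: float
    roots: tuple[float, ...]


def calibrate_threshold(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> ThresholdModel:
    """Fit a Gaussian per class and set the threshold at their intersection.

    Equating the two log-densities gives a quadratic in the score; both
    roots are reported and the root lying between the two class means is
    selected (with equal standard deviations the quadratic degenerates to
    the midpoint of the means).  Sample means and standard deviations
    (ddof=1) are used as the fitted parameters.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least two scores per class")
    m1, s1 = float(np.mean(pos)), float(np.std(pos, ddof=1))
    m2, s2 = float(np.mean(neg)), float(np.std(neg, ddof=1))
    if s1 == 0 or s2 == 0:
        raise ValueError("zero variance in a score class")
    if math.isclose(m1, m2) and math.isclose(s1, s2):
        raise ValueError("identical fitted distributions have no unique intersection")
    lo, hi = min(m1, m2), max(m1, m2)
    if math.isclose(s1, s2):
        tau = (m1 + m2) / 2.0
        roots = (tau,)
    else:
        # equate log N(x; m1, s1) = log N(x; m2, s2)
        a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
        b = m1 / s1**2 - m2 / s2**2
        c = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + math.log(s2 / s1)
        disc = b**2 - 4 * a * c
        if disc < 0:
            raise ValueError("Gaussian densities do not intersect in the real line")
        r1 = (-b + math.sqrt(disc)) / (2 * a)
        r2 = (-b - math.sqrt(disc)) / (2 * a)
        roots = tuple(sorted((r1, r2)))
        between = [r for r in roots if lo <= r <= hi]
        if not between:
            raise ValueError(
                f"no density intersection between the class means {lo}..{hi}"
            )
        tau = between[0]
    return ThresholdModel(m1, s1, m2, s2, float(tau), roots)
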