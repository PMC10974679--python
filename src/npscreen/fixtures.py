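"""Deterministic synthetic data for end-to-end testing without trained models.

``make_toy_world`` provides a small aromatic template and a four-group
modification library whose depth-2 enumeration stays under 200 derivatives,
so whole-pipeline experiments run in seconds.  ``simulate_analyte`` turns a
predicted spectrum into a noisy "measured" one with seeded multiplicative
log-normal intensity noise and a peak-drop floor — a stand-in for the
purity and instrument variation of real seized samples; it does not emulate
instrument-specific artifacts (column bleed, co-elution).

``holdout_experiment`` is the desk-scale analogue of a screening
validation: enumerate a database, hold out one member, simulate its
analyte spectrum, screen it against the database, and report where the
truth ranked.  By default the analyte fingerprint is the held-out member's
own structure fingerprint, emulating an ideal spectrum-to-fingerprint
model so the experiment isolates the effect of spectral noise; pass
``fingerprint_source="knn"`` to use the retrieval baseline instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_core import FunctionalGroup, MoleculeRecord, molecule_record
from .enumeration import EnumerationConfig, PrunedLibrary, enumerate_derivatives
from .screening import (
    DEFAULT_THRESHOLD,
    CandidateDatabase,
    ScreeningReport,
    build_database,
    screen,
)
from .similarity import SmsfWeights, baseline_fingerprint_predictor
from .spectra import MassSpectrum, SpectrumPredictor, baseline_predict_spectrum

__all__ = [
    "HoldoutSummary",
    "NoiseModel",
    "build_toy_database",
    "holdout_experiment",
    "make_toy_world",
    "simulate_analyte",
]

_TEMPLATES = [
    ("toluene", "Cc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("fluorobenzene", "Fc1ccccc1"),
]

_TOY_LIBRARY = (
    FunctionalGroup("methyl", "methyl", "*C"),
    FunctionalGroup("fluoro", "fluoro", "*F"),
    FunctionalGroup("hydroxy", "hydroxy", "*O"),
    FunctionalGroup("methoxy", "methoxy", "*OC"),
)


@dataclass(frozen=True)
class NoiseModel:
    """Seeded multiplicative intensity noise with a peak-drop floor."""

    sigma: float = 0.1
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise scale sigma must be >= 0")
        if not 0.0 <= self.floor < 1.0:
            raise ValueError("peak-drop floor must lie in [0, 1)")


def make_toy_world(seed: int = 0) -> tuple[MoleculeRecord, tuple[FunctionalGroup, ...]]:
    """A small aromatic template plus a fixed four-group library.

    Deterministic per seed: the seed selects the template scaffold; the
    library (methyl, fluoro, hydroxy, methoxy) is fixed.  Depth-2
    enumeration of any toy world yields fewer than 200 unique derivatives.
    """
    name, smi = _TEMPLATES[seed % len(_TEMPLATES)]
    template = molecule_record(smi, template_id=name)
    return template, _TOY_LIBRARY


def build_toy_database(
    seed: int = 0,
    depth: int = 2,
    predictor: SpectrumPredictor = baseline_predict_spectrum,
) -> tuple[MoleculeRecord, CandidateDatabase]:
    """Enumerate the toy world to ``depth`` and build its candidate database."""
    template, library = make_toy_world(seed)
    pruned = PrunedLibrary.unpruned(library, depth)
    config = EnumerationConfig(depth_n=depth)
    derivatives = enumerate_derivatives(template, pruned, config)
    return template, build_database(derivatives, predictor)


def simulate_analyte(
    mol: MoleculeRecord,
    predictor: SpectrumPredictor,
    noise: NoiseModel,
) -> MassSpectrum:
    """Predictor spectrum perturbed by the noise model.

    Each peak intensity is multiplied by ``exp(sigma * z)`` with seeded
    standard-normal ``z``; after renormalization, peaks below the floor are
    dropped and the spectrum renormalized again.  With ``sigma=0`` and
    ``floor=0`` the predicted spectrum is returned unchanged.
    """
    spectrum = predictor(mol)
    arr = spectrum.intensities.copy()
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        bins = np.nonzero(arr)[0]
        arr[bins] *= np.exp(noise.sigma * rng.standard_normal(bins.size))
    arr /= arr.max()
    if noise.floor > 0:
        arr[arr < noise.floor] = 0.0
    if arr.max() == 0:
        raise ValueError("noise floor dropped every peak")
    return MassSpectrum(
        arr,
        name=f"{spectrum.name} (simulated)",
        smiles=spectrum.smiles,
        molecular_mass=None,
        max_mz=spectrum.max_mz,
    )


@dataclass(frozen=True)
class HoldoutSummary:
    truth_smiles: str
    truth_rank: int | None
    truth_smsf: float | None
    top_smiles: str
    top_smsf: float
    in_top1: bool
    in_top3: bool
    decision: bool
    n_candidates: int


def holdout_experiment(
    seed: int = 0,
    depth: int = 2,
    noise: NoiseModel | None = None,
    weights: SmsfWeights = SmsfWeights(),
    threshold: float = DEFAULT_THRESHOLD,
    tol: int | None = 1,
    fingerprint_source: str = "oracle",
    analyte: MoleculeRecord | None = None,
    db: CandidateDatabase | None = None,
) -> HoldoutSummary:
    """Hold out one toy-database member, screen its simulated spectrum, and
    report the truth's rank and the match decision.

    Deterministic per seed (the seed drives the world choice, the held-out
    member and the noise).  Passing ``analyte`` screens an external molecule
    against the toy database instead (negative control); its "truth rank" is
    then None.  ``db`` short-circuits the database build when screening many
    analytes against one world.
    """
    if noise is None:
        noise = NoiseModel(sigma=0.0, floor=0.0, seed=seed)
    if db is None:
        _, db = build_toy_database(seed, depth)
    rng = np.random.default_rng(seed)
    if analyte is None:
        truth = db.entries[int(rng.integers(len(db)))].record
        external = False
    else:
        truth = analyte
        external = truth.canonical_smiles not in db
    spectrum = simulate_analyte(truth, baseline_predict_spectrum, noise)

    if fingerprint_source == "oracle":
        truth_fp = truth.fingerprint
        if truth_fp is None:
            truth_fp = molecule_record(truth.canonical_smiles).fingerprint
        fpred = lambda s: truth_fp  # noqa: E731 — ideal spectrum->fp model
    elif fingerprint_source == "knn":
        fpred = baseline_fingerprint_predictor(
            [(e.spectrum, e.fingerprint) for e in db.entries]
        )
    else:
        raise ValueError("fingerprint_source must be 'oracle' or 'knn'")

    report: ScreeningReport = screen(
        spectrum, db, fpred, weights=weights, tol=tol, threshold=threshold
    )
    rank = None if external else report.rank_of(truth.canonical_smiles)
    truth_smsf = None
    if rank is not None:
        truth_smsf = report.ranked[rank - 1].smsf
    top = report.ranked[0] if report.ranked else None
    return HoldoutSummary(
        truth_smiles=truth.canonical_smiles,
        truth_rank=rank,
        truth_smsf=truth_smsf,
        top_smiles=top.smiles if top else "",
        top_smsf=top.smsf if top else float("nan"),
        in_top1=rank == 1,
        in_top3=rank is not None and rank <= 3,
        decision=report.decision,
        n_candidates=len(report.ranked),
    )
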