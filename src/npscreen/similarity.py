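"""Spectral and fingerprint similarity metrics and the integrated SMSF score.

Candidates are ranked by SMSF, a weighted sum of three components, each in
[0, 1]:

* cosine similarity between the analyte and candidate stick spectra;
* top-n Jaccard similarity — the Jaccard index between the m/z positions of
  the n most intense peaks of the two spectra (n = 4 by default), which
  captures the base-peak pattern a human analyst inspects first;
* fingerprint similarity — the Jaccard (Tanimoto) index between the
  candidate's structure fingerprint and the fingerprint predicted from the
  analyte spectrum (probabilistic fingerprints are binarized at 0.5 first).

The spectrum-to-fingerprint step is a pluggable contract
(:data:`FingerprintPredictor`); :func:`baseline_fingerprint_predictor`
ships a deterministic k-nearest-neighbour retrieval baseline so the
pipeline runs without trained model weights.

:func:`optimize_weights` recalibrates the three SMSF weights on a labelled
validation set by exhaustive search over a simplex lattice, minimizing the
mean relative ranking position of the true candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .chem_core import Fingerprint
from .evaluation import RankOutcome, mean_rrp
from .spectra import MassSpectrum

DEFAULT_TOP_N = 4

FingerprintPredictor = Callable[[MassSpectrum], Fingerprint]

__all__ = [
    "DEFAULT_TOP_N",
    "FingerprintPredictor",
    "SmsfWeights",
    "baseline_fingerprint_predictor",
    "cosine_similarity",
    "fp_similarity",
    "simplex_grid",
    "smsf",
    "top_n_jaccard",
    "top_peaks",
    "optimize_weights",
]


@dataclass(frozen=True)
class SmsfWeights:
    """Convex weights for the cosine, top-n Jaccard and fingerprint terms."""

    w_cos: float = 1 / 3
    w_jac: float = 1 / 3
    w_fp: float = 1 / 3

    def __post_init__(self) -> None:
        if min(self.w_cos, self.w_jac, self.w_fp) < 0:
            raise ValueError("SMSF weights must be non-negative")
        if abs(self.w_cos + self.w_jac + self.w_fp - 1.0) > 1e-9:
            raise ValueError("SMSF weights must sum to 1")


def cosine_similarity(a: MassSpectrum, b: MassSpectrum) -> float:
    """Cosine of the angle between the two binned intensity vectors."""
    if a.max_mz != b.max_mz:
        raise ValueError("spectra use different m/z ranges")
    va, vb = a.intensities, b.intensities
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for an empty spectrum")
    return float(np.clip(va @ vb / (na * nb), 0.0, 1.0))


def top_peaks(spectrum: MassSpectrum, n: int = DEFAULT_TOP_N) -> frozenset[int]:
    """m/z bins of the ``n`` most intense peaks (ties broken by lower m/z)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mz = spectrum.mz
    if mz.size == 0:
        raise ValueError("spectrum has no peaks")
    order = sorted(mz, key=lambda b: (-spectrum.intensities[b], b))
    return frozenset(int(b) for b in order[:n])


def top_n_jaccard(a: MassSpectrum, b: MassSpectrum, n: int = DEFAULT_TOP_N) -> float:
    """Jaccard index between the top-``n`` peak positions of two spectra."""
    ta, tb = top_peaks(a, n), top_peaks(b, n)
    return len(ta & tb) / len(ta | tb)


def fp_similarity(p: Fingerprint, q: Fingerprint) -> float:
    """Jaccard (Tanimoto) index over set bits; both-empty is defined as 0."""
    if p.length != q.length:
        raise ValueError(
            f"fingerprint length mismatch: {p.length} vs {q.length}"
        )
    pb = p.binarized().bits.astype(bool)
    qb = q.binarized().bits.astype(bool)
    union = np.count_nonzero(pb | qb)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(pb & qb) / union)


def smsf(cos: float, jac: float, fps: float, w: SmsfWeights = SmsfWeights()) -> float:
    """Weighted sum of the three similarity components."""
    for label, value in (("cosine", cos), ("jaccard", jac), ("fingerprint", fps)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{label} component {value} outside [0, 1]")
    return w.w_cos * cos + w.w_jac * jac + w.w_fp * fps


def baseline_fingerprint_predictor(
    reference: Sequence[tuple[MassSpectrum, Fingerprint]], k: int = 5
) -> FingerprintPredictor:
    """Retrieval baseline: cosine-weighted mean fingerprint of the k nearest
    reference spectra.

    A deterministic stand-in for a learned spectrum-to-fingerprint model;
    output is a probabilistic fingerprint.  Neighbour ties at the k-th place
    are broken by reference order.
    """
    reference = list(reference)
    if not reference:
        raise ValueError("reference set must be nonempty")
    if k < 1:
        raise ValueError("k must be >= 1")
    length = reference[0][1].length

    def predict(query: MassSpectrum) -> Fingerprint:
        sims = np.array([cosine_similarity(query, s) for s, _ in reference])
        order = np.argsort(-sims, kind="stable")[: min(k, len(reference))]
        weights = sims[order]
        if weights.sum() == 0:
            weights = np.ones_like(weights)
        weights = weights / weights.sum()
        bits = np.zeros(length)
        for w_i, idx in zip(weights, order):
            bits += w_i * reference[idx][1].binarized().bits
        return Fingerprint(np.clip(bits, 0.0, 1.0), "probabilistic", length)

    return predict


def simplex_grid(step: float) -> list[tuple[float, float, float]]:
    """All weight triples on the simplex lattice with the given step."""
    if not 0 < step <= 1:
        raise ValueError("grid step must be in (0, 1]")
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError("grid step must divide 1 evenly")
    return [
        (i / m, j / m, (m - i - j) / m)
        for i in range(m + 1)
        for j in range(m - i + 1)
    ]


def optimize_weights(
    queries: Sequence[tuple[MassSpectrum, Fingerprint, Sequence[tuple[str, MassSpectrum, Fingerprint]], str]],
    grid_step: float = 0.1,
) -> SmsfWeights:
    """Grid-search the SMSF weights minimizing the mean RRP of true candidates.

    Each query is ``(analyte_spectrum, analyte_fingerprint, candidates,
    true_id)`` where ``candidates`` is a sequence of ``(id, spectrum,
    fingerprint)`` containing the true candidate.  Ties between grid points
    are broken toward larger cosine weight, then larger Jaccard weight.
    """
    if not queries:
        raise ValueError("at least one query is required")
    # component similarities are weight-independent: compute once per query
    prepared = []
    for spec, fp, candidates, true_id in queries:
        comps = []
        true_seen = False
        for cid, cspec, cfp in candidates:
            comps.append(
                (
                    cid,
                    cosine_similarity(spec, cspec),
                    top_n_jaccard(spec, cspec),
                    fp_similarity(fp, cfp),
                )
            )
            true_seen = true_seen or cid == true_id
        if not true_seen:
            raise ValueError(f"true candidate {true_id!r} absent from its database")
        prepared.append((comps, true_id))

    best: tuple[float, float, float, SmsfWeights] | None = None
    for w_cos, w_jac, w_fp in simplex_grid(grid_step):
        w = SmsfWeights(w_cos, w_jac, w_fp)
        outcomes = []
        for comps, true_id in prepared:
            scored = sorted(
                ((smsf(c, j, f, w), cid) for cid, c, j, f in comps),
                key=lambda t: (-t[0], t[1]),
            )
            rank = next(i for i, (_, cid) in enumerate(scored, 1) if cid == true_id)
            outcomes.append(RankOutcome(rank, len(scored)))
        score = mean_rrp(outcomes)
        key = (score, -w_cos, -w_jac)
        if best is None or key < (best[0], best[1], best[2]):
            best = (score, -w_cos, -w_jac, w)
    return best[3]
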