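"""EI mass-spectrum model, MSP I/O, baseline spectrum prediction and mass filter.

Spectra are nominal-mass stick spectra held as a dense intensity vector over
integer m/z bins ``1..max_mz`` (default 700, which covers the molecules in
scope).  Internally every spectrum is base-peak normalized (maximum
intensity 1.0); on MSP export intensities are scaled to 999 following the
NIST library convention.

Spectrum prediction is a pluggable contract: any deterministic callable
``MoleculeRecord -> MassSpectrum``.  The shipped
:func:`baseline_predict_spectrum` is a deterministic single-cleavage
fragmenter — the molecular ion plus the heavier fragment of every acyclic
single-bond cleavage between heavy atoms — so the whole pipeline runs and
is testable without trained spectrum-prediction weights; a neural predictor
attaches through the same contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from matchms import Spectrum as _MatchmsSpectrum
from matchms.exporting import save_as_msp
from matchms.importing import load_from_msp
from rdkit import Chem

from .chem_core import MoleculeRecord

DEFAULT_MAX_MZ = 700
UNKNOWN_MASS = None

SpectrumPredictor = Callable[[MoleculeRecord], "MassSpectrum"]

__all__ = [
    "DEFAULT_MAX_MZ",
    "MassSpectrum",
    "SpectrumPredictor",
    "baseline_predict_spectrum",
    "bin_and_normalize",
    "infer_molecular_mass",
    "mass_filter",
    "read_msp",
    "write_msp",
]


@dataclass
class MassSpectrum:
    """Unit-m/z binned, base-peak-normalized EI stick spectrum.

    ``intensities[i]`` is the relative intensity at m/z ``i`` (index 0 is
    unused and always zero); the base peak has intensity 1.0.
    """

    intensities: np.ndarray
    name: str = ""
    smiles: str | None = None
    molecular_mass: int | None = None
    max_mz: int = DEFAULT_MAX_MZ

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.shape != (self.max_mz + 1,):
            raise ValueError(
                f"intensity vector must have length max_mz+1 = {self.max_mz + 1}"
            )
        if arr.min() < 0:
            raise ValueError("intensities must be non-negative")
        peak_max = arr.max()
        if peak_max > 0 and not math.isclose(peak_max, 1.0):
            arr = arr / peak_max
        arr[0] = 0.0
        self.intensities = arr

    @property
    def mz(self) -> np.ndarray:
        """m/z bins carrying nonzero intensity."""
        return np.nonzero(self.intensities)[0]

    def peaks(self) -> list[tuple[int, float]]:
        return [(int(i), float(self.intensities[i])) for i in self.mz]

    def n_peaks(self) -> int:
        return int(np.count_nonzero(self.intensities))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def bin_and_normalize(
    peaks: Sequence[tuple[float, float]], max_mz: int = DEFAULT_MAX_MZ, **metadata
) -> MassSpectrum:
    """Bin raw (m/z, intensity) pairs to integer bins and normalize.

    m/z values round to the nearest integer bin (halves round up); peaks
    colliding in one bin are summed; intensities are divided by the maximum.
    Peaks rounding to bin 0 or beyond ``max_mz`` are rejected.
    """
    arr = np.zeros(max_mz + 1)
    any_signal = False
    for mz, inten in peaks:
        if inten < 0:
            raise ValueError(f"negative intensity at m/z {mz}")
        if inten == 0:
            continue
        b = _round_half_up(mz)
        if b < 1 or b > max_mz:
            raise ValueError(f"m/z {mz} falls outside bins 1..{max_mz}")
        arr[b] += inten
        any_signal = True
    if not any_signal:
        raise ValueError("spectrum has no peak with positive intensity")
    return MassSpectrum(arr / arr.max(), max_mz=max_mz, **metadata)


# ---------------------------------------------------------------------------
# MSP I/O (NIST dialect, via matchms)

def read_msp(path: str | Path, max_mz: int = DEFAULT_MAX_MZ) -> list[MassSpectrum]:
    """Read an MSP library into binned, normalized spectra.

    Tolerant of the usual NIST-dialect variations matchms accepts; m/z
    values are rounded to the nearest integer bin on ingest.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    for spec in load_from_msp(str(path), metadata_harmonization=False):
        meta = {k.lower(): v for k, v in spec.metadata.items()}
        name = meta.get("compound_name") or meta.get("name") or ""
        if not name:
            import warnings

            warnings.warn(f"{path}: MSP record without a Name field", stacklevel=2)
        mass = meta.get("nominal_mass") or meta.get("mw") or meta.get("molecular_mass")
        out.append(
            bin_and_normalize(
                list(zip(spec.peaks.mz, spec.peaks.intensities)),
                max_mz=max_mz,
                name=str(name),
                smiles=meta.get("smiles"),
                molecular_mass=_round_half_up(float(mass)) if mass else None,
            )
        )
    return out


def write_msp(spectra: Iterable[MassSpectrum], path: str | Path) -> None:
    """Write spectra to MSP, base peak scaled to 999 (NIST convention)."""
    records = []
    for s in spectra:
        mz = s.mz.astype(float)
        if mz.size == 0:
            raise ValueError(f"refusing to write empty spectrum {s.name!r}")
        metadata = {"name": s.name}
        if s.smiles:
            metadata["smiles"] = s.smiles
        if s.molecular_mass is not None:
            metadata["mw"] = int(s.molecular_mass)
        records.append(
            _MatchmsSpectrum(
                mz=mz,
                intensities=np.round(s.intensities[s.mz] * 999.0, 3),
                metadata=metadata,
                metadata_harmonization=False,
            )
        )
    path = Path(path)
    if path.exists():
        path.unlink()  # save_as_msp appends
    save_as_msp(records, str(path))


# ---------------------------------------------------------------------------
# baseline spectrum predictor

def baseline_predict_spectrum(
    mol: MoleculeRecord, max_mz: int = DEFAULT_MAX_MZ
) -> MassSpectrum:
    """Deterministic single-cleavage fragmenter.

    Emits the molecular ion at the nominal mass (intensity 1.0) plus, for
    every acyclic single bond between heavy atoms, the heavier fragment of
    that cleavage at its nominal mass, weighted by the fragment's share of
    the molecule's heavy atoms.  This is a crude but fixed and explainable
    stand-in for a learned EI spectrum predictor.
    """
    rdmol = mol.mol()
    m_plus = mol.nominal_mass
    if m_plus > max_mz:
        raise ValueError(f"molecular ion {m_plus} exceeds max_mz={max_mz}")
    peaks: dict[int, float] = {m_plus: 1.0}
    heavy_total = rdmol.GetNumHeavyAtoms()
    pt = Chem.GetPeriodicTable()
    atom_mass = [
        (a.GetIsotope() or pt.GetMostCommonIsotope(a.GetAtomicNum()))
        + a.GetTotalNumHs()
        for a in rdmol.GetAtoms()
    ]
    for bond in rdmol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        # each fragment keeps its hydrogens; walk one side of the cleaved bond
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        side = {u}
        stack = [u]
        while stack:
            for nbr in rdmol.GetAtomWithIdx(stack.pop()).GetNeighbors():
                i = nbr.GetIdx()
                if i != v and i not in side:
                    side.add(i)
                    stack.append(i)
        side_mass = sum(atom_mass[i] for i in side)
        masses = (side_mass, m_plus - side_mass)
        heavies = (len(side), heavy_total - len(side))
        hi = int(np.argmax(masses))
        frag_mass = masses[hi]
        weight = heavies[hi] / heavy_total
        if 1 <= frag_mass <= max_mz:
            peaks[frag_mass] = max(peaks.get(frag_mass, 0.0), weight)
    arr = np.zeros(max_mz + 1)
    for b, inten in peaks.items():
        arr[b] = inten
    return MassSpectrum(
        arr, name=mol.canonical_smiles, smiles=mol.canonical_smiles,
        molecular_mass=m_plus, max_mz=max_mz,
    )


# ---------------------------------------------------------------------------
# molecular-mass inference and the mass filter

def infer_molecular_mass(
    spectrum: MassSpectrum, floor: float = 0.01
) -> int | None:
    """Infer the analyte's nominal molecular mass from its spectrum.

    A mass supplied in the spectrum metadata (e.g. from a soft-ionization
    run) overrides the spectrum; otherwise the highest m/z bin with relative
    intensity >= ``floor`` is taken as the molecular-ion peak.  Returns
    ``None`` (unknown) when neither is available — under hard ionization the
    molecular ion may be absent entirely.
    """
    if spectrum.molecular_mass is not None:
        return int(spectrum.molecular_mass)
    candidates = np.nonzero(spectrum.intensities >= floor)[0]
    if candidates.size == 0:
        return None
    return int(candidates[-1])


def mass_filter(
    candidates: Sequence[MoleculeRecord],
    analyte_mass: int | None,
    tol: int | None = 1,
) -> list[MoleculeRecord]:
    """Keep candidates whose nominal mass is within ``tol`` Da of the analyte.

    The default +/-1 Da tolerance absorbs isotope and prediction artifacts.
    With ``analyte_mass=None`` (unknown) or ``tol=None`` (filter lifted) all
    candidates are returned.
    """
    if tol is not None and tol < 0:
        raise ValueError("tol must be >= 0 or None (lifted)")
    if analyte_mass is None or tol is None:
        return list(candidates)
    return [c for c in candidates if abs(c.nominal_mass - analyte_mass) <= tol]
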