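"""Shared structure handling: canonical SMILES, fingerprints and masses.

Molecule identity throughout the package is the RDKit canonical SMILES
string.  Masses are the nominal (most-abundant-isotope, integer) and
monoisotopic masses used by the mass filter and the molecular-ion peak
of predicted spectra.  Fingerprints are circular (Morgan/ECFP-like)
binary vectors of configurable length; probabilistic fingerprints (entries
in [0, 1]) arise only as the output of spectrum-to-fingerprint predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator

RDLogger.DisableLog("rdApp.*")

DEFAULT_FP_LENGTH = 2048
DEFAULT_FP_RADIUS = 2

__all__ = [
    "Fingerprint",
    "FunctionalGroup",
    "MoleculeRecord",
    "ParseError",
    "canonicalize",
    "mol_from_smiles",
    "molecule_record",
    "monoisotopic_mass",
    "nominal_mass",
    "r_group_nominal_mass",
    "structure_fingerprint",
]


class ParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule or raise :class:`ParseError`."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the unique canonical SMILES for ``smiles``.

    Idempotent; two SMILES spellings of the same molecule map to the same
    string.  Stereo marks present in the input are preserved verbatim.
    """
    return Chem.MolToSmiles(mol_from_smiles(smiles))


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length structural descriptor.

    ``binary`` mode holds 0/1 entries (structure-derived fingerprints);
    ``probabilistic`` mode holds entries in [0, 1] (spectrum-predicted
    fingerprints, before binarization).
    """

    bits: np.ndarray
    mode: str = "binary"
    length: int = DEFAULT_FP_LENGTH

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=float)
        object.__setattr__(self, "bits", bits)
        if bits.shape != (self.length,):
            raise ValueError(
                f"fingerprint has {bits.shape[0]} entries, expected {self.length}"
            )
        if self.mode == "binary":
            if not np.all(np.isin(bits, (0.0, 1.0))):
                raise ValueError("binary fingerprint entries must be 0 or 1")
        elif self.mode == "probabilistic":
            if bits.min() < 0.0 or bits.max() > 1.0:
                raise ValueError("probabilistic fingerprint entries must lie in [0, 1]")
        else:
            raise ValueError(f"unknown fingerprint mode {self.mode!r}")

    def binarized(self, cutoff: float = 0.5) -> "Fingerprint":
        """Binary view of this fingerprint (entries >= cutoff become 1)."""
        if self.mode == "binary":
            return self
        return Fingerprint((self.bits >= cutoff).astype(float), "binary", self.length)

    def to_hex(self) -> str:
        return np.packbits(self.binarized().bits.astype(np.uint8)).tobytes().hex()

    @classmethod
    def from_hex(cls, hexstr: str, length: int = DEFAULT_FP_LENGTH) -> "Fingerprint":
        raw = np.unpackbits(np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8))
        return cls(raw[:length].astype(float), "binary", length)


@dataclass(frozen=True)
class FunctionalGroup:
    """An R-group fragment with a single attachment point.

    ``r_group_smiles`` uses a dummy atom ``[*]`` (or ``*``) to mark where the
    fragment bonds to the heavy atom whose hydrogen it replaces.
    """

    fg_id: str
    name: str
    r_group_smiles: str

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.r_group_smiles)
        if mol is None:
            raise ParseError(
                f"functional group {self.fg_id!r}: unparsable R-group SMILES "
                f"{self.r_group_smiles!r}"
            )
        dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise ValueError(
                f"functional group {self.fg_id!r} must have exactly one attachment "
                f"point, found {len(dummies)}"
            )
        if dummies[0].GetDegree() != 1:
            raise ValueError(
                f"functional group {self.fg_id!r}: attachment dummy must have "
                "exactly one neighbor"
            )


@dataclass(frozen=True)
class MoleculeRecord:
    """A molecule with its identity, masses, fingerprint and provenance.

    ``provenance`` records the template identifier and the ordered list of
    ``(site, fg_id)`` modifications that produced a derivative; it is empty
    for templates and analyte standards.
    """

    canonical_smiles: str
    nominal_mass: int
    monoisotopic_mass: float
    fingerprint: Fingerprint | None = None
    template_id: str | None = None
    modifications: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.canonical_smiles)

    def with_fingerprint(self, fp: Fingerprint) -> "MoleculeRecord":
        return replace(self, fingerprint=fp)


_PT = Chem.GetPeriodicTable()


def nominal_mass(mol: Chem.Mol | str) -> int:
    """Nominal mass: sum of most-abundant-isotope mass numbers over all atoms.

    Implicit hydrogens are counted (1 Da each).  Explicit isotope labels in
    the input override the most-common isotope.
    """
    if isinstance(mol, str):
        mol = mol_from_smiles(mol)
    total = 0
    for atom in mol.GetAtoms():
        if atom.GetIsotope():
            total += atom.GetIsotope()
        else:
            total += _PT.GetMostCommonIsotope(atom.GetAtomicNum())
        total += atom.GetTotalNumHs()
    return total


def monoisotopic_mass(mol: Chem.Mol | str) -> float:
    if isinstance(mol, str):
        mol = mol_from_smiles(mol)
    return Descriptors.ExactMolWt(mol)


def structure_fingerprint(
    mol: Chem.Mol | str,
    length: int = DEFAULT_FP_LENGTH,
    radius: int = DEFAULT_FP_RADIUS,
) -> Fingerprint:
    """Binary circular fingerprint of the molecule (deterministic per config)."""
    if isinstance(mol, str):
        mol = mol_from_smiles(mol)
    if length <= 0:
        raise ValueError("fingerprint length must be positive")
    gen = GetMorganGenerator(radius=radius, fpSize=length)
    arr = np.zeros(length, dtype=float)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        arr[bit] = 1.0
    return Fingerprint(arr, "binary", length)


def molecule_record(
    smiles: str,
    fp_length: int | None = DEFAULT_FP_LENGTH,
    template_id: str | None = None,
    modifications: tuple[tuple[int, str], ...] = (),
) -> MoleculeRecord:
    """Build a :class:`MoleculeRecord` from a SMILES string.

    Pass ``fp_length=None`` to skip fingerprint computation (cheaper when
    only masses are needed, e.g. during enumeration).
    """
    smi = canonicalize(smiles)
    mol = mol_from_smiles(smi)
    fp = structure_fingerprint(mol, fp_length) if fp_length else None
    return MoleculeRecord(
        canonical_smiles=smi,
        nominal_mass=nominal_mass(mol),
        monoisotopic_mass=monoisotopic_mass(mol),
        fingerprint=fp,
        template_id=template_id,
        modifications=tuple(modifications),
    )


def r_group_nominal_mass(fg: FunctionalGroup) -> int:
    """Nominal mass contributed by an R-group (dummy atom excluded).

    Attaching the group to a hydrogen site changes the product mass by
    this value minus 1 (the hydrogen it replaces).
    """
    mol = mol_from_smiles(fg.r_group_smiles)
    total = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            continue
        total += _PT.GetMostCommonIsotope(atom.GetAtomicNum())
        total += atom.GetTotalNumHs()
    return total
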