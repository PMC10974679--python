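import numpy as np
import pytest
from rdkit import Chem

from npscreen.chem_core import FunctionalGroup, molecule_record
from npscreen.spectra import DEFAULT_MAX_MZ, MassSpectrum


@pytest.fixture(scope="session")
def methyl():
    return FunctionalGroup("methyl", "methyl", "*C")


@pytest.fixture(scope="session")
def fluoro():
    return FunctionalGroup("fluoro", "fluoro", "*F")


@pytest.fixture(scope="session")
def hydroxy():
    return FunctionalGroup("hydroxy", "hydroxy", "*O")


@pytest.fixture(scope="session")
def methane():
    return molecule_record("C")


@pytest.fixture(scope="session")
def benzene():
    return molecule_record("c1ccccc1")


def spectrum_from_peaks(peaks, max_mz=DEFAULT_MAX_MZ, **meta):
    """Build a MassSpectrum from {mz: intensity} (test helper)."""
    arr = np.zeros(max_mz + 1)
    for mz, inten in peaks.items():
        arr[mz] = inten
    return MassSpectrum(arr, max_mz=max_mz, **meta)


@pytest.fixture(scope="session")
def make_spectrum():
    return spectrum_from_peaks


def random_molecule(rng, max_atoms=10):
    """Random acyclic molecule built atom by atom (test-side generator)."""
    symbols = ["C", "C", "C", "N", "O", "S", "F", "Cl"]
    mol = Chem.RWMol()
    mol.AddAtom(Chem.Atom(rng.choice(symbols[:3])))
    n = int(rng.integers(1, max_atoms))
    for _ in range(n):
        sym = rng.choice(symbols)
        idx = mol.AddAtom(Chem.Atom(sym))
        partner = int(rng.integers(0, idx))
        if mol.GetAtomWithIdx(partner).GetSymbol() in ("F", "Cl"):
            partner = 0
        mol.AddBond(partner, idx, Chem.BondType.SINGLE)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol
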