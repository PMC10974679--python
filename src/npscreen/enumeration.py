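"""Recursive derivative enumeration by hydrogen replacement.

A template drug is expanded by replacing one hydrogen at a time with an
R-group from a functional-group library, recursively up to ``depth_n``
modifications.  Because the enumeration space grows exponentially with
depth, the library is pruned per depth: a functional group survives depth
``d`` only if the average synthesis-difficulty increase of the compounds
obtained by adding it ``d`` times (its delta complexity score against the
template baseline) stays below ``alpha**d``.

The synthesis-difficulty model is pluggable (any deterministic
``molecule -> float`` callable).  :class:`HeuristicComplexityScorer` ships
as the default so the pipeline runs without trained model weights; a
neural synthesis-complexity model can be dropped in through the same
contract.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_core import (
    FunctionalGroup,
    MoleculeRecord,
    molecule_record,
    mol_from_smiles,
    monoisotopic_mass,
    nominal_mass,
)

logger = logging.getLogger(__name__)

ComplexityScorer = Callable[[Chem.Mol], float]

__all__ = [
    "ComplexityScorer",
    "EnumerationConfig",
    "HeuristicComplexityScorer",
    "NotApplicableError",
    "PrunedLibrary",
    "SiteError",
    "default_library",
    "delta_scscore",
    "enumerate_derivatives",
    "load_library",
    "prune_library",
    "substitute_hydrogen",
]


class SiteError(ValueError):
    """The addressed heavy atom has no hydrogen available for replacement."""


class NotApplicableError(ValueError):
    """A functional group cannot be placed on the template even once."""


@dataclass(frozen=True)
class EnumerationConfig:
    depth_n: int = 3
    alpha: float = 1.2
    dedup: bool = True
    max_records: int | None = None

    def __post_init__(self) -> None:
        if self.depth_n < 1:
            raise ValueError("depth_n must be >= 1")
        if self.alpha <= 1.0:
            raise ValueError("alpha must be greater than 1")


@dataclass(frozen=True)
class PrunedLibrary:
    """Per-depth retained functional groups; depth 1 is always the full library."""

    library: tuple[FunctionalGroup, ...]
    retained_ids: dict[int, frozenset[str]] = field(default_factory=dict)

    def retained(self, depth: int) -> tuple[FunctionalGroup, ...]:
        if depth <= 1 or depth not in self.retained_ids:
            if depth <= 1:
                return self.library
            raise KeyError(f"no retained set computed for depth {depth}")
        ids = self.retained_ids[depth]
        return tuple(fg for fg in self.library if fg.fg_id in ids)

    @classmethod
    def unpruned(cls, library: Iterable[FunctionalGroup], depth_n: int) -> "PrunedLibrary":
        lib = tuple(library)
        ids = frozenset(fg.fg_id for fg in lib)
        return cls(lib, {d: ids for d in range(2, depth_n + 1)})


class HeuristicComplexityScorer:
    """Deterministic structural proxy for expected synthesis difficulty.

    Weighted count of heavy atoms, rings, heteroatoms and stereocenters,
    clipped to the 1-5 range used by reaction-step complexity scores.
    Larger, more ring-rich and more heteroatom-rich molecules score higher.
    """

    def __init__(
        self,
        w_heavy: float = 0.06,
        w_ring: float = 0.30,
        w_hetero: float = 0.08,
        w_stereo: float = 0.20,
    ) -> None:
        self.w_heavy = w_heavy
        self.w_ring = w_ring
        self.w_hetero = w_hetero
        self.w_stereo = w_stereo

    def __call__(self, mol: Chem.Mol) -> float:
        heavy = mol.GetNumHeavyAtoms()
        rings = len(Chem.GetSSSR(mol))
        hetero = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
        stereo = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True))
        raw = (
            1.0
            + self.w_heavy * heavy
            + self.w_ring * rings
            + self.w_hetero * hetero
            + self.w_stereo * stereo
        )
        return float(min(5.0, max(1.0, raw)))


def _attachment_info(fg: FunctionalGroup) -> tuple[Chem.Mol, int, int]:
    """R-group fragment and the index of the atom bonded to the dummy."""
    frag = mol_from_smiles(fg.r_group_smiles)
    dummy = next(a for a in frag.GetAtoms() if a.GetAtomicNum() == 0)
    anchor = dummy.GetNeighbors()[0].GetIdx()
    return frag, dummy.GetIdx(), anchor


def _substitute_mol(mol: Chem.Mol, heavy_atom_index: int, fg: FunctionalGroup) -> Chem.Mol | None:
    """Replace one hydrogen on ``heavy_atom_index`` with the R-group.

    Returns the sanitized product, or ``None`` when the substitution gives
    an invalid valence (rejected, not an error).  Raises :class:`SiteError`
    when the site carries no hydrogen.
    """
    if heavy_atom_index < 0 or heavy_atom_index >= mol.GetNumAtoms():
        raise SiteError(f"heavy atom index {heavy_atom_index} out of range")
    atom = mol.GetAtomWithIdx(heavy_atom_index)
    if atom.GetTotalNumHs() < 1:
        raise SiteError(
            f"atom {heavy_atom_index} ({atom.GetSymbol()}) has no hydrogen to replace"
        )
    frag, dummy_idx, anchor_idx = _attachment_info(fg)
    offset = mol.GetNumAtoms()
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    target = combo.GetAtomWithIdx(heavy_atom_index)
    if target.GetNumExplicitHs() > 0:
        target.SetNumExplicitHs(target.GetNumExplicitHs() - 1)
    combo.AddBond(heavy_atom_index, offset + anchor_idx, Chem.BondType.SINGLE)
    combo.RemoveAtom(offset + dummy_idx)
    product = combo.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception:
        return None
    return product


def substitute_hydrogen(
    record: MoleculeRecord, heavy_atom_index: int, fg: FunctionalGroup
) -> MoleculeRecord:
    """Replace one hydrogen of ``record`` at a heavy-atom site with ``fg``.

    The core heavy atoms and bonds of the input are preserved; provenance is
    extended by ``(site, fg_id)``.  Raises :class:`SiteError` if the site has
    no hydrogen and :class:`ValueError` if the product valence is invalid.
    """
    product = _substitute_mol(record.mol(), heavy_atom_index, fg)
    if product is None:
        raise ValueError(
            f"substituting {fg.fg_id} at atom {heavy_atom_index} of "
            f"{record.canonical_smiles} gives an invalid valence"
        )
    smi = Chem.MolToSmiles(product)
    return MoleculeRecord(
        canonical_smiles=smi,
        nominal_mass=nominal_mass(product),
        monoisotopic_mass=monoisotopic_mass(product),
        fingerprint=None,
        template_id=record.template_id or record.canonical_smiles,
        modifications=record.modifications + ((heavy_atom_index, fg.fg_id),),
    )


def _products_one_step(mol: Chem.Mol, fg: FunctionalGroup) -> dict[str, Chem.Mol]:
    """All canonically distinct single placements of ``fg`` on ``mol``."""
    out: dict[str, Chem.Mol] = {}
    for atom in mol.GetAtoms():
        if atom.GetTotalNumHs() < 1:
            continue
        product = _substitute_mol(mol, atom.GetIdx(), fg)
        if product is None:
            continue
        out.setdefault(Chem.MolToSmiles(product), product)
    return out


# Cap on the number of distinct products averaged per (fg, n); keeps the
# pruning pass bounded on large templates while staying deterministic.
DELTA_SAMPLE_CAP = 256
_DELTA_SAMPLE_SEED = 20240315


def delta_scscore(
    template: MoleculeRecord,
    fg: FunctionalGroup,
    n: int,
    scorer: ComplexityScorer,
    sample_cap: int = DELTA_SAMPLE_CAP,
) -> float:
    """Average complexity increase after ``n`` successive additions of ``fg``.

    Applies ``fg`` ``n`` times in all distinct ways (each level's product set
    deduplicated by canonical SMILES and, beyond ``sample_cap``, subsampled
    uniformly without replacement with a fixed seed), scores the resulting
    compounds, and returns the mean score minus the template's score.

    Raises :class:`NotApplicableError` when the group cannot be placed even
    once; callers treat that as pruned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(_DELTA_SAMPLE_SEED)
    template_mol = template.mol()
    frontier: dict[str, Chem.Mol] = {template.canonical_smiles: template_mol}
    for _ in range(n):
        nxt: dict[str, Chem.Mol] = {}
        for mol in frontier.values():
            nxt.update(_products_one_step(mol, fg))
        if not nxt:
            raise NotApplicableError(
                f"functional group {fg.fg_id} has no valid placement"
            )
        if len(nxt) > sample_cap:
            keys = sorted(nxt)
            keep = rng.choice(len(keys), size=sample_cap, replace=False)
            nxt = {keys[i]: nxt[keys[i]] for i in sorted(keep)}
        frontier = nxt
    scores = [scorer(mol) for mol in frontier.values()]
    return float(np.mean(scores) - scorer(template_mol))


def prune_library(
    template: MoleculeRecord,
    library: Iterable[FunctionalGroup],
    n: int,
    alpha: float,
    scorer: ComplexityScorer,
) -> PrunedLibrary:
    """Per-depth functional-group pruning against the ``alpha**d`` threshold.

    Depth 1 retains the full library; at each depth ``d`` in ``2..n`` a group
    is retained iff its delta complexity score for ``d`` placements is below
    ``alpha**d``.
    """
    if alpha <= 1.0:
        raise ValueError("alpha must be greater than 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    lib = tuple(library)
    retained: dict[int, frozenset[str]] = {}
    for depth in range(2, n + 1):
        threshold = alpha**depth
        kept = []
        for fg in lib:
            try:
                delta = delta_scscore(template, fg, depth, scorer)
            except NotApplicableError:
                continue
            if delta < threshold:
                kept.append(fg.fg_id)
        retained[depth] = frozenset(kept)
    return PrunedLibrary(lib, retained)


def enumerate_derivatives(
    template: MoleculeRecord,
    pruned: PrunedLibrary,
    config: EnumerationConfig,
) -> Iterator[MoleculeRecord]:
    """Stream all canonically distinct derivatives with 1..depth_n modifications.

    At recursion level ``d`` only the groups retained at depth ``d`` are
    applied.  Sites are visited in canonical atom order; duplicates are
    removed by canonical SMILES so site order does not affect the emitted
    set.  The template itself is not emitted.
    """
    seen: set[str] = {template.canonical_smiles}
    frontier: list[MoleculeRecord] = [template]
    emitted = 0
    for depth in range(1, config.depth_n + 1):
        groups = pruned.retained(depth)
        level: list[MoleculeRecord] = []
        for parent in frontier:
            mol = parent.mol()
            for atom in mol.GetAtoms():
                if atom.GetTotalNumHs() < 1:
                    continue
                for fg in groups:
                    product = _substitute_mol(mol, atom.GetIdx(), fg)
                    if product is None:
                        continue
                    smi = Chem.MolToSmiles(product)
                    if config.dedup and smi in seen:
                        continue
                    seen.add(smi)
                    record = MoleculeRecord(
                        canonical_smiles=smi,
                        nominal_mass=nominal_mass(product),
                        monoisotopic_mass=monoisotopic_mass(product),
                        fingerprint=None,
                        template_id=template.template_id
                        or template.canonical_smiles,
                        modifications=parent.modifications
                        + ((atom.GetIdx(), fg.fg_id),),
                    )
                    level.append(record)
                    yield record
                    emitted += 1
                    if config.max_records is not None and emitted >= config.max_records:
                        logger.warning(
                            "enumeration truncated at max_records=%d", config.max_records
                        )
                        return
        frontier = level


def load_library(path: str | Path) -> tuple[FunctionalGroup, ...]:
    """Read a functional-group library from a tab-separated file.

    Expected columns: ``fg_id``, ``name``, ``r_group_smiles`` (attachment
    point marked with a ``*`` dummy atom).  Lines starting with ``#`` are
    comments; ``#`` inside a SMILES (e.g. a nitrile) is data.
    """
    text = "\n".join(
        line
        for line in Path(path).read_text().splitlines()
        if not line.startswith("#")
    )
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    required = {"fg_id", "name", "r_group_smiles"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library file {path} is missing columns: {sorted(missing)}")
    groups = tuple(
        FunctionalGroup(row.fg_id, row.name, row.r_group_smiles)
        for row in df.itertuples(index=False)
    )
    ids = [fg.fg_id for fg in groups]
    if len(set(ids)) != len(ids):
        raise ValueError(f"library file {path} has duplicate fg_id entries")
    return groups


def default_library() -> tuple[FunctionalGroup, ...]:
    """The shipped 204-entry functional-group modification library."""
    path = Path(__file__).parent / "data" / "functional_groups_synthetic.tsv"
    return load_library(path)
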