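"""Declarative drug-likeness / stability filter for enumerated derivatives.

Each rule is a pure, deterministic predicate over a molecule, built from a
small set of predicate families (forbidden substructure by SMARTS, capped
property value, allowed element set, smallest-set-of-smallest-rings cap).
The default registry holds 57 rules spanning structural-stability filters
(reactive or hydrolytically unstable groups) and pharmaceutical-plausibility
caps (size, lipophilicity, ring complexity).  The registry is data-driven —
a tab-separated file with one rule per line — so rule sets can be audited,
edited or replaced wholesale.

A molecule fails the filter iff at least one rule fails; for reporting, the
failure is attributed to the *first* failing rule in priority order.  The
default order puts the historically most effective rule (messy rings: more
than 7 smallest sets of smallest rings) first, which also lets short-circuit
evaluation skip most of the registry for the worst offenders.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .chem_core import MoleculeRecord, mol_from_smiles

__all__ = [
    "Rule",
    "RuleSet",
    "Verdict",
    "apply_rules",
    "default_rules",
    "filter_stats",
    "load_rules",
]


@dataclass(frozen=True)
class Rule:
    rule_id: str
    name: str
    predicate: Callable[[Chem.Mol], bool]  # True = molecule passes this rule
    params: dict

    def passes(self, mol: Chem.Mol) -> bool:
        return self.predicate(mol)


@dataclass(frozen=True)
class RuleSet:
    """Ordered rule collection; evaluation order is priority order."""

    rules: tuple[Rule, ...]

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("rule_ids must be unique")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterator[Rule]:
        return iter(self.rules)

    def __getitem__(self, rule_id: str) -> Rule:
        for rule in self.rules:
            if rule.rule_id == rule_id:
                return rule
        raise KeyError(rule_id)


@dataclass(frozen=True)
class Verdict:
    passed: bool
    failed_rule_id: str | None = None


# ---------------------------------------------------------------------------
# predicate families

def _max_sssr(params: dict) -> Callable[[Chem.Mol], bool]:
    limit = int(params["max"])
    return lambda mol: len(Chem.GetSSSR(mol)) <= limit


def _smarts_limit(params: dict) -> Callable[[Chem.Mol], bool]:
    pattern = Chem.MolFromSmarts(params["smarts"])
    if pattern is None:
        raise ValueError(f"bad SMARTS: {params['smarts']!r}")
    limit = int(params.get("max", 0))
    return lambda mol: len(mol.GetSubstructMatches(pattern)) <= limit


def _allowed_elements(params: dict) -> Callable[[Chem.Mol], bool]:
    allowed = set(params["elements"])
    return lambda mol: all(a.GetSymbol() in allowed for a in mol.GetAtoms())


_PROPERTIES: dict[str, Callable[[Chem.Mol], float]] = {
    "mw": Descriptors.MolWt,
    "logp": Crippen.MolLogP,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "rot_bonds": rdMolDescriptors.CalcNumRotatableBonds,
    "hbd": rdMolDescriptors.CalcNumHBD,
    "hba": rdMolDescriptors.CalcNumHBA,
    "heavy_atoms": lambda m: m.GetNumHeavyAtoms(),
    "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings,
    "stereocenters": lambda m: len(Chem.FindMolChiralCenters(m, includeUnassigned=True)),
    "abs_net_charge": lambda m: abs(Chem.GetFormalCharge(m)),
    "max_ring_size": lambda m: max(
        (len(r) for r in m.GetRingInfo().AtomRings()), default=0
    ),
}


def _property_max(params: dict) -> Callable[[Chem.Mol], bool]:
    prop = _PROPERTIES[params["property"]]
    limit = float(params["max"])
    return lambda mol: prop(mol) <= limit


_PREDICATE_FACTORIES: dict[str, Callable[[dict], Callable[[Chem.Mol], bool]]] = {
    "max_sssr": _max_sssr,
    "smarts_limit": _smarts_limit,
    "allowed_elements": _allowed_elements,
    "property_max": _property_max,
}


# ---------------------------------------------------------------------------

def load_rules(path: str | Path) -> RuleSet:
    """Load a rule registry (TSV: rule_id, name, predicate, params-as-JSON).

    Lines starting with ``#`` are comments; ``#`` inside a field (e.g. in a
    SMARTS pattern) is data.
    """
    text = "\n".join(
        line
        for line in Path(path).read_text().splitlines()
        if not line.startswith("#")
    )
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    rules = []
    for row in df.itertuples(index=False):
        params = json.loads(row.params)
        factory = _PREDICATE_FACTORIES[row.predicate]
        rules.append(Rule(row.rule_id, row.name, factory(params), params))
    return RuleSet(tuple(rules))


def default_rules() -> RuleSet:
    """The shipped 57-rule drug-likeness/stability registry."""
    path = Path(__file__).parent / "data" / "druglike_rules_synthetic.tsv"
    return load_rules(path)


def _as_mol(mol: MoleculeRecord | Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, MoleculeRecord):
        return mol.mol()
    if isinstance(mol, str):
        return mol_from_smiles(mol)
    return mol


def apply_rules(mol: MoleculeRecord | Chem.Mol | str, rules: RuleSet) -> Verdict:
    """Pass/fail verdict with first-fail attribution.

    The verdict is order-independent (fail iff any rule fails); only the
    attributed rule depends on the priority order.  An empty rule set
    passes every molecule.
    """
    m = _as_mol(mol)
    for rule in rules:
        if not rule.passes(m):
            return Verdict(False, rule.rule_id)
    return Verdict(True, None)


def filter_stats(
    mols: Iterable[MoleculeRecord | Chem.Mol | str], rules: RuleSet
) -> tuple[dict[str, float], float]:
    """Per-rule filtered proportions (by first-fail) and overall retention.

    The per-rule proportions and the retention rate sum to 1 on any
    nonempty input.  An empty input yields empty statistics with a warning.
    """
    counts: dict[str, int] = {rule.rule_id: 0 for rule in rules}
    total = 0
    kept = 0
    for mol in mols:
        total += 1
        verdict = apply_rules(mol, rules)
        if verdict.passed:
            kept += 1
        else:
            counts[verdict.failed_rule_id] += 1
    if total == 0:
        warnings.warn("filter_stats: empty input stream", stacklevel=2)
        return {}, float("nan")
    proportions = {rid: c / total for rid, c in counts.items()}
    return proportions, kept / total
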