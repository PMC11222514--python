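"""Molecule-quality metrics: bond inference, stability, validity, novelty,
and the conformer energy-ratio statistic.

Bond orders are inferred purely from inter-atomic distances and element
pairs against a table of covalent reference lengths with per-order margins
(single 10 pm, double 5 pm, triple 3 pm): a pair is assigned the highest
order whose reference length plus margin still bounds the observed distance,
else no bond.  An atom is *stable* when its summed inferred bond orders hit
a permitted valence for its element (and formal charge where tabled); a
molecule is stable when every atom is.  Validity and uniqueness use RDKit
sanitisation of the inferred bond graph and canonical SMILES; novelty
compares canonical SMILES of valid-and-unique samples against a reference
set.  The energy ratio divides a conformer's UFF energy by the mean UFF
energy of distance-geometry (ETKDGv3) re-embeddings of the same molecular
graph — ratios above 7 flag highly unlikely conformations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .molecules import MoleculeRecord

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "BondTable",
    "StabilityReport",
    "EnergyRatioResult",
    "load_bond_table",
    "infer_bonds",
    "atom_and_molecule_stability",
    "to_rdkit",
    "canonical_smiles",
    "validity_uniqueness",
    "novelty",
    "energy_ratio",
    "evaluate_set",
]

ENERGY_RATIO_CUTOFF = 7.0


@dataclass(frozen=True)
class BondTable:
    """Reference bond lengths (pm), per-order margins (pm), allowed valences."""

    lengths: dict  # order -> {frozenset/tuple key "A-B" -> pm}
    margins: dict  # order -> pm
    allowed_valences: dict  # element -> {charge -> tuple of valences}
    version: int = 1

    def reference(self, el1: str, el2: str, order: int) -> float | None:
        table = self.lengths.get(order)
        if table is None:
            return None
        return table.get((el1, el2)) or table.get((el2, el1))

    def valences_for(self, element: str, charge: int = 0) -> tuple[int, ...]:
        entry = self.allowed_valences.get(element)
        if entry is None:
            return ()
        # fall back to the neutral entry when the charge is not tabled
        return tuple(entry.get(int(charge), entry.get(0, ())))


@lru_cache(maxsize=1)
def load_bond_table() -> BondTable:
    """Load the bundled versioned bond/valence reference table."""
    raw = json.loads(
        resources.files("diffmol.data").joinpath("bond_table.json").read_text()
    )
    lengths = {
        int(order): {tuple(k.split("-")): float(v) for k, v in table.items()}
        for order, table in raw["lengths"].items()
    }
    margins = {int(k): float(v) for k, v in raw["margins"].items()}
    valences = {
        el: {int(ch): tuple(vals) for ch, vals in entry.items()}
        for el, entry in raw["allowed_valences"].items()
    }
    return BondTable(lengths=lengths, margins=margins,
                     allowed_valences=valences, version=raw["version"])


@dataclass(frozen=True)
class StabilityReport:
    """Aggregate metric results over a set of molecules (fractions in [0,1])."""

    atom_stable_frac: float
    mol_stable_frac: float
    valid_frac: float | None = None
    unique_frac: float | None = None
    novel_frac: float | None = None
    n_molecules: int = 0


@dataclass(frozen=True)
class EnergyRatioResult:
    """UFF energy of a conformer relative to re-embedded reference conformers."""

    ratio: float
    n_reference_conformers: int
    flag_unlikely: bool
    available: bool = True


def infer_bonds(mol: MoleculeRecord, table: BondTable | None = None) -> np.ndarray:
    """Symmetric (N, N) bond-order matrix inferred from distances and types."""
    table = table or load_bond_table()
    coords = mol.coords
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    n = mol.N
    orders = np.zeros((n, n), dtype=np.int64)
    dists_pm = mol.pairwise_distances() * 100.0
    for i in range(n):
        for j in range(i + 1, n):
            d = dists_pm[i, j]
            assigned = 0
            for order in (1, 2, 3):
                ref = table.reference(mol.elements[i], mol.elements[j], order)
                if ref is not None and d < ref + table.margins[order]:
                    assigned = order
            orders[i, j] = orders[j, i] = assigned
    return orders


def atom_and_molecule_stability(
    mols: list[MoleculeRecord], table: BondTable | None = None
) -> StabilityReport:
    """Atom stability (valency matches an allowed value) and molecule stability."""
    if not mols:
        raise ValueError("stability metrics need a non-empty molecule list")
    table = table or load_bond_table()
    n_atoms = 0
    n_stable_atoms = 0
    n_stable_mols = 0
    for mol in mols:
        orders = infer_bonds(mol, table)
        valences = orders.sum(axis=1)
        stable = np.array([
            int(v) in table.valences_for(el, int(q))
            for el, q, v in zip(mol.elements, mol.charges, valences)
        ])
        n_atoms += mol.N
        n_stable_atoms += int(stable.sum())
        n_stable_mols += int(stable.all())
    return StabilityReport(
        atom_stable_frac=n_stable_atoms / n_atoms,
        mol_stable_frac=n_stable_mols / len(mols),
        n_molecules=len(mols),
    )


_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
               3: Chem.BondType.TRIPLE}


def to_rdkit(mol: MoleculeRecord, table: BondTable | None = None,
             sanitize: bool = True, orders: np.ndarray | None = None):
    """Assemble an RDKit molecule from the (inferred) bond graph.

    ``orders`` overrides distance-based inference with an explicit symmetric
    bond-order matrix.  Returns None when sanitisation fails (standard
    valence rules violated).
    """
    if orders is None:
        orders = infer_bonds(mol, table)
    rw = Chem.RWMol()
    for el, q in zip(mol.elements, mol.charges):
        atom = Chem.Atom(el)
        atom.SetFormalCharge(int(q))
        rw.AddAtom(atom)
    for i in range(mol.N):
        for j in range(i + 1, mol.N):
            if orders[i, j] > 0:
                rw.AddBond(i, j, _BOND_TYPES[orders[i, j]])
    conf = Chem.Conformer(mol.N)
    for i, xyz in enumerate(mol.coords):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    m = rw.GetMol()
    m.AddConformer(conf)
    if sanitize:
        try:
            Chem.SanitizeMol(m)
        except (Chem.AtomValenceException, Chem.KekulizeException, ValueError):
            return None
    return m


def canonical_smiles(mol: MoleculeRecord, table: BondTable | None = None) -> str | None:
    """Canonical SMILES of the inferred bond graph, or None when invalid."""
    m = to_rdkit(mol, table)
    if m is None:
        return None
    try:
        return Chem.MolToSmiles(Chem.RemoveHs(m))
    except ValueError:
        return None


def validity_uniqueness(
    mols: list[MoleculeRecord], table: BondTable | None = None
) -> tuple[float, float]:
    """(valid %, valid-and-unique %) over the sampled set.

    Valid = the inferred bond graph sanitises; unique = distinct canonical
    SMILES among the valid molecules, both as percentages of the total set.
    """
    if not mols:
        raise ValueError("validity metrics need a non-empty molecule list")
    smiles = [canonical_smiles(m, table) for m in mols]
    valid = [s for s in smiles if s is not None]
    n = len(mols)
    return 100.0 * len(valid) / n, 100.0 * len(set(valid)) / n


def novelty(generated_smiles: list[str], reference_smiles: set[str]) -> float:
    """Percentage of valid-and-unique samples absent from the reference set.

    Both sides must already be canonical SMILES; duplicates in the input are
    collapsed before comparison.
    """
    unique = set(s for s in generated_smiles if s is not None)
    if not unique:
        raise ValueError("novelty undefined for an empty generated set")
    new = unique - set(reference_smiles)
    return 100.0 * len(new) / len(unique)


def energy_ratio(
    mol: MoleculeRecord,
    n_conformers: int = 50,
    seed: int = 0,
    table: BondTable | None = None,
    orders: np.ndarray | None = None,
) -> EnergyRatioResult:
    """UFF energy of the given conformer over the mean UFF energy of
    ETKDGv3-re-embedded conformers of the same molecular graph.

    ``orders`` fixes the molecular graph explicitly (e.g. to score a
    distorted conformer of a known topology); otherwise bonds are inferred
    from the conformer's own distances.
    """
    m = to_rdkit(mol, table, orders=orders)
    if m is None:
        return EnergyRatioResult(np.nan, 0, False, available=False)
    try:
        ff = AllChem.UFFGetMoleculeForceField(m, confId=0)
        e_input = ff.CalcEnergy()
        ref = Chem.Mol(m)
        ref.RemoveAllConformers()
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed)
        conf_ids = AllChem.EmbedMultipleConfs(ref, numConfs=int(n_conformers),
                                              params=params)
        energies = []
        for cid in conf_ids:
            energies.append(
                AllChem.UFFGetMoleculeForceField(ref, confId=cid).CalcEnergy()
            )
    except (ValueError, RuntimeError):
        return EnergyRatioResult(np.nan, 0, False, available=False)
    if not energies or np.mean(energies) <= 1e-9:
        # no embedding, or a reference energy scale too small to divide by
        return EnergyRatioResult(np.nan, len(energies), False, available=False)
    ratio = float(e_input / np.mean(energies))
    return EnergyRatioResult(
        ratio=ratio,
        n_reference_conformers=len(energies),
        flag_unlikely=ratio > ENERGY_RATIO_CUTOFF,
    )


def evaluate_set(
    mols: list[MoleculeRecord],
    table: BondTable | None = None,
    reference_smiles: set[str] | None = None,
) -> StabilityReport:
    """Full metric stack over a generated set (fractions, not percent)."""
    table = table or load_bond_table()
    stab = atom_and_molecule_stability(mols, table)
    val_pct, uniq_pct = validity_uniqueness(mols, table)
    novel_frac = None
    if reference_smiles is not None:
        smiles = [canonical_smiles(m, table) for m in mols]
        novel_frac = novelty([s for s in smiles if s is not None],
                             reference_smiles) / 100.0
    return StabilityReport(
        atom_stable_frac=stab.atom_stable_frac,
        mol_stable_frac=stab.mol_stable_frac,
        valid_frac=val_pct / 100.0,
        unique_frac=uniq_pct / 100.0,
        novel_frac=novel_frac,
        n_molecules=len(mols),
    )
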