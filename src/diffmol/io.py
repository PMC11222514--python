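"""Molecular file formats and dataset bundles.

XYZ blocks (count line, comment line, ``element x y z`` rows, 6-decimal
angstroms) are parsed directly; SDF V2000 goes through RDKit so charges and
bond blocks follow the standard chemistry toolchain.  Dataset bundles carry
the molecule list, named splits, the empirical size distribution p(N), and
per-property normalisation statistics (mean and median absolute deviation)
computed from the training split.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .molecules import MoleculeRecord
from .sampling import SizeDistribution

__all__ = [
    "ParseError",
    "DatasetBundle",
    "read_xyz",
    "write_xyz",
    "read_sdf",
    "write_sdf",
    "load_processed_dataset",
]


class ParseError(ValueError):
    """Malformed molecular file; message carries the offending line number."""


@dataclass
class DatasetBundle:
    """Molecules plus splits, size prior and property normalisers."""

    molecules: list[MoleculeRecord]
    splits: dict[str, list[int]]
    size_dist: SizeDistribution
    property_stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def subset(self, split: str) -> list[MoleculeRecord]:
        return [self.molecules[i] for i in self.splits[split]]

    @classmethod
    def from_molecules(cls, mols: list[MoleculeRecord],
                       fractions=(0.8, 0.1, 0.1),
                       rng: np.random.Generator | None = None) -> "DatasetBundle":
        rng = np.random.default_rng(0) if rng is None else rng
        n = len(mols)
        order = rng.permutation(n)
        n_train = int(round(fractions[0] * n))
        n_valid = int(round(fractions[1] * n))
        splits = {
            "train": sorted(order[:n_train].tolist()),
            "valid": sorted(order[n_train:n_train + n_valid].tolist()),
            "test": sorted(order[n_train + n_valid:].tolist()),
        }
        train = [mols[i] for i in splits["train"]]
        size_dist = SizeDistribution.from_sizes([m.N for m in train])
        stats: dict[str, tuple[float, float]] = {}
        if train and train[0].properties:
            for name in train[0].properties:
                vals = np.array([m.properties[name] for m in train])
                mad = float(np.median(np.abs(vals - np.median(vals))))
                stats[name] = (float(vals.mean()), mad if mad > 1e-12 else 1.0)
        return cls(molecules=mols, splits=splits, size_dist=size_dist,
                   property_stats=stats)


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path) -> list[MoleculeRecord]:
    """Read a (multi-)molecule XYZ file."""
    mols = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected an atom count, got "
                             f"{lines[i]!r}") from None
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise ParseError(f"line {i + 1}: count {n} exceeds remaining rows")
        elements, coords = [], []
        for k, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise ParseError(f"line {i + 3 + k}: expected 'element x y z'")
            elements.append(parts[0])
            try:
                coords.append([float(v) for v in parts[1:4]])
            except ValueError:
                raise ParseError(
                    f"line {i + 3 + k}: non-numeric coordinate in {row!r}"
                ) from None
        mols.append(MoleculeRecord(elements=elements, coords=np.array(coords)))
        i += 2 + n
    return mols


def write_xyz(mols: list[MoleculeRecord], path, comment: str = "") -> None:
    """Write molecules as concatenated XYZ blocks (6-decimal angstroms)."""
    with open(path, "w") as fh:
        for mol in mols:
            fh.write(f"{mol.N}\n{comment}\n")
            for el, (x, y, z) in zip(mol.elements, mol.coords):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# SDF (V2000)
# ---------------------------------------------------------------------------

def read_sdf(path) -> list[MoleculeRecord]:
    """Read an SDF V2000 file; element symbols, formal charges, coordinates."""
    with open(path) as fh:
        text = fh.read()
    for ln, line in enumerate(text.splitlines(), start=1):
        if "V3000" in line:
            raise ParseError(f"line {ln}: V3000 blocks are not supported "
                             "(V2000 only)")
    supplier = Chem.SDMolSupplier(os.fspath(path), sanitize=False,
                                  removeHs=False)
    mols = []
    for k, m in enumerate(supplier):
        if m is None:
            raise ParseError(f"molecule block {k + 1}: malformed SDF record")
        conf = m.GetConformer()
        mols.append(MoleculeRecord(
            elements=[a.GetSymbol() for a in m.GetAtoms()],
            coords=np.array([list(conf.GetAtomPosition(i))
                             for i in range(m.GetNumAtoms())]),
            charges=np.array([a.GetFormalCharge() for a in m.GetAtoms()]),
        ))
    return mols


def write_sdf(mols: list[MoleculeRecord], path, bonds: bool = False) -> None:
    """Write molecules as SDF V2000; ``bonds`` adds the inferred bond block."""
    writer = Chem.SDWriter(os.fspath(path))
    writer.SetKekulize(False)
    try:
        for mol in mols:
            if bonds:
                from .metrics import to_rdkit

                m = to_rdkit(mol, sanitize=False)
            else:
                rw = Chem.RWMol()
                for el, q in zip(mol.elements, mol.charges):
                    atom = Chem.Atom(el)
                    atom.SetFormalCharge(int(q))
                    atom.SetNoImplicit(True)
                    rw.AddAtom(atom)
                conf = Chem.Conformer(mol.N)
                for i, xyz in enumerate(mol.coords):
                    conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
                m = rw.GetMol()
                m.AddConformer(conf)
            m.UpdatePropertyCache(strict=False)
            writer.write(m)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Processed reference datasets
# ---------------------------------------------------------------------------

_EXPECTED_LAYOUT = """\
expected layout under {root}:
  {which}/train.npz  {which}/valid.npz  {which}/test.npz
each npz with arrays:
  num_atoms (M,)          atom count per molecule
  charges   (M, max_n)    atomic numbers, zero-padded
  positions (M, max_n, 3) coordinates in angstrom, zero-padded
optional per-molecule scalar property arrays (e.g. alpha, mu, Cv)."""

_PERIODIC = Chem.GetPeriodicTable()
_SPLIT_NAMES = ("train", "valid", "test")


def load_processed_dataset(root, which: str = "qm9") -> DatasetBundle:
    """Load a postprocessed reference dataset (hydrogens imputed) from disk.

    ``which`` selects the subdirectory ("qm9" or "geom_drugs").  Downloading
    is out of scope; the loader validates the on-disk layout and raises a
    descriptive error when the archives are absent or corrupt.
    """
    root = Path(root)
    base = root / which
    paths = {s: base / f"{s}.npz" for s in _SPLIT_NAMES}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(
            "processed dataset files missing: " + ", ".join(missing) + "\n"
            + _EXPECTED_LAYOUT.format(root=root, which=which)
        )
    molecules: list[MoleculeRecord] = []
    splits: dict[str, list[int]] = {}
    prop_arrays: dict[str, list[np.ndarray]] = {}
    for split in _SPLIT_NAMES:
        with np.load(paths[split]) as data:
            required = {"num_atoms", "charges", "positions"}
            if not required.issubset(data.files):
                raise ValueError(
                    f"{paths[split]}: missing arrays "
                    f"{sorted(required - set(data.files))}\n"
                    + _EXPECTED_LAYOUT.format(root=root, which=which)
                )
            num_atoms = data["num_atoms"].astype(int)
            charges = data["charges"]
            positions = data["positions"]
            extras = [k for k in data.files if k not in required]
            start = len(molecules)
            for i, n in enumerate(num_atoms):
                z = charges[i][:n]
                mol = MoleculeRecord(
                    elements=[_PERIODIC.GetElementSymbol(int(zi)) for zi in z],
                    coords=positions[i][:n],
                )
                for k in extras:
                    if data[k].shape[:1] == num_atoms.shape:
                        mol.properties[k] = float(data[k][i])
                molecules.append(mol)
            splits[split] = list(range(start, len(molecules)))
            for k in extras:
                prop_arrays.setdefault(k, [])
                if split == "train" and data[k].shape[:1] == num_atoms.shape:
                    prop_arrays[k].append(np.asarray(data[k], dtype=float))
    train_sizes = [molecules[i].N for i in splits["train"]]
    stats = {}
    for k, arrs in prop_arrays.items():
        if arrs:
            vals = np.concatenate(arrs)
            mad = float(np.median(np.abs(vals - np.median(vals))))
            stats[k] = (float(vals.mean()), mad if mad > 1e-12 else 1.0)
    return DatasetBundle(
        molecules=molecules,
        splits=splits,
        size_dist=SizeDistribution.from_sizes(train_sizes),
        property_stats=stats,
    )
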