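"""The molecule-quality metric stack on hand-built fixtures.

Shows distance-based bond inference, atom/molecule stability, validity and
uniqueness via sanitisation, novelty against a reference set, and the UFF
energy-ratio statistic that flags unlikely 3D conformations.
"""

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

import diffmol as dm

methane = dm.MoleculeRecord(
    elements=list(dm.methane_template().elements),
    coords=dm.methane_template().coords)
water = dm.MoleculeRecord(
    elements=list(dm.water_template().elements),
    coords=dm.water_template().coords)

orders = dm.infer_bonds(methane)
print(f"methane inferred bond orders (C row): {orders[0].tolist()} "
      "(four single C-H bonds)")

rep = dm.evaluate_set([methane, water, water], reference_smiles={"C"})
print(f"set of [methane, water, water]: AS {100*rep.atom_stable_frac:.0f}%, "
      f"MS {100*rep.mol_stable_frac:.0f}%, valid {100*rep.valid_frac:.0f}%, "
      f"valid&unique {100*rep.unique_frac:.1f}%, "
      f"novel {100*rep.novel_frac:.0f}% (methane is in the reference set)")

# energy ratio: a relaxed embedding scores ~1, a stretched copy is flagged
ethanol = Chem.AddHs(Chem.MolFromSmiles("CCO"))
params = AllChem.ETKDGv3()
params.randomSeed = 5
AllChem.EmbedMolecule(ethanol, params)
conf = ethanol.GetConformer()
rec = dm.MoleculeRecord(
    elements=[a.GetSymbol() for a in ethanol.GetAtoms()],
    coords=np.array([list(conf.GetAtomPosition(i))
                     for i in range(ethanol.GetNumAtoms())]))
ok = dm.energy_ratio(rec, n_conformers=30, seed=1)
bad = dm.energy_ratio(
    dm.MoleculeRecord(elements=rec.elements, coords=rec.coords * 1.5),
    n_conformers=20, seed=1, orders=dm.infer_bonds(rec))
print(f"\nethanol energy ratio (self-embedded): {ok.ratio:.2f} "
      f"-> flagged: {ok.flag_unlikely}")
print(f"ethanol with all bonds stretched 1.5x: {bad.ratio:.1f} "
      f"-> flagged: {bad.flag_unlikely} (ratios above 7 mark unlikely "
      "conformations)")
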