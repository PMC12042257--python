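"""Render amino acids and peptides as SMILES, and graft a covalent adduct.

Every protein sequence has an exact atomic structure; this example prints
it for a few residues and a short peptide, then attaches an acrylonitrile-
derived fragment to a cysteine side chain the way a covalent drug would.
"""

from atomspan import AdductSpec, graft_adduct, peptide_smiles, residue_smiles
from atomspan.chem import heavy_atom_count, mol_formula

for code in "GAC":
    smi = residue_smiles(code)
    print(f"residue {code}: {smi}  ({mol_formula(smi)})")

pep = peptide_smiles("GAC")
print(f"\npeptide GAC: {pep}  ({mol_formula(pep)})")
print("  - the tripeptide formula equals the three residues minus 2 x H2O")

adduct = AdductSpec("[*]CC#N", name="cyanoethyl")
mod = graft_adduct("C", adduct)
print(f"\ncysteine + {adduct.smiles_with_dummy} -> {mod.product_smiles}")
print(f"  - heavy atoms: {heavy_atom_count(residue_smiles('C'))} (Cys) + "
      f"{adduct.heavy_atoms_without_dummy()} (adduct) = "
      f"{heavy_atom_count(mod.product_smiles)} (grafted residue)")
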