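"""Deterministic amino-acid / peptide / adduct chemistry on SMILES strings.

Every protein sequence has an exact atomic rendering: each residue is a
small molecule, and a peptide is the condensation product of its residues
(one amide bond, one water lost per bond).  This module provides that
rendering, plus covalent-adduct grafting: replacing the attachment dummy
atom of an electrophile fragment with a single bond to a residue's
reactive side-chain atom, yielding the non-natural residue that a covalent
drug leaves behind on its target.

All SMILES emitted here are RDKit-canonical.  L-configuration stereocenters
are included by default and can be stripped with ``include_stereo=False``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

__all__ = [
    "CANONICAL_CODES",
    "REACTIVE_RESIDUES",
    "GRAFTABLE_CODES",
    "AdductSpec",
    "ModifiedResidue",
    "residue_smiles",
    "peptide_smiles",
    "span_fragment_smiles",
    "graft_adduct",
    "canonical_smiles",
    "mol_formula",
    "heavy_atom_count",
]

CANONICAL_CODES = "ACDEFGHIKLMNPQRSTVWY"

# Side chains as written into the backbone template N[C@@H](R)C(=O)-.
# The atom-map label :1 marks the reactive side-chain atom used for
# covalent grafting (Cys Sg, Lys Nz, Ser/Thr Og, Tyr Oh, His Ne2,
# Asp/Glu carboxyl O, Arg Nh, Trp Ne1, Met Sd).  Maps are stripped from
# all emitted SMILES.
_SIDE_CHAINS = {
    "A": "C",
    "R": "CCCNC(=N)[NH2:1]",
    "N": "CC(N)=O",
    "D": "CC(=O)[OH:1]",
    "C": "C[SH:1]",
    "E": "CCC(=O)[OH:1]",
    "Q": "CCC(N)=O",
    "H": "Cc1c[nH:1]cn1",
    "I": "[C@@H](C)CC",
    "L": "CC(C)C",
    "K": "CCCC[NH2:1]",
    "M": "CC[S:1]C",
    "F": "Cc1ccccc1",
    "S": "C[OH:1]",
    "T": "[C@@H]([OH:1])C",
    "W": "Cc1c[nH:1]c2ccccc12",
    "Y": "Cc1ccc([OH:1])cc1",
    "V": "C(C)C",
}

#: Residues with a defined reactive side-chain attachment atom.
REACTIVE_RESIDUES = frozenset("CKSTYHDERWM")

#: Residues whose reactive atom carries a hydrogen in the free residue and
#: can therefore accept a singly-bonded adduct.  Methionine's thioether
#: sulfur has a defined attachment atom but no hydrogen to give up, so
#: grafting it raises a valence error.
GRAFTABLE_CODES = frozenset("CKSTYHDERW")


def _backbone(code: str) -> str:
    """Backbone fragment of one residue, N->C, ending at the carbonyl."""
    if code == "G":
        return "NCC(=O)"
    if code == "P":
        return "N1CCC[C@H]1C(=O)"
    return f"N[C@@H]({_SIDE_CHAINS[code]})C(=O)"


def _check_code(code: str) -> None:
    if not (isinstance(code, str) and len(code) == 1 and code in CANONICAL_CODES):
        raise ValueError(f"unknown amino-acid code: {code!r}")


def _strip_stereo(smiles: str) -> str:
    return re.sub(r"@+", "", smiles)


def _finalize(raw: str, include_stereo: bool) -> str:
    if not include_stereo:
        raw = _strip_stereo(raw)
    mol = Chem.MolFromSmiles(raw)
    if mol is None:  # pragma: no cover - templates are fixed and valid
        raise ValueError(f"internal template produced invalid SMILES: {raw}")
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def canonical_smiles(smiles: str) -> str:
    """RDKit-canonical form of ``smiles``; raises ``ValueError`` if invalid."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def mol_formula(smiles: str) -> str:
    """Molecular formula (Hill order) of a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return CalcMolFormula(mol)


def heavy_atom_count(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return mol.GetNumHeavyAtoms()


def residue_smiles(code: str, include_stereo: bool = True) -> str:
    """Canonical SMILES of the free amino acid for a one-letter code."""
    _check_code(code)
    return _finalize(_backbone(code) + "O", include_stereo)


def peptide_smiles(sequence: str, include_stereo: bool = True) -> str:
    """Canonical SMILES of the linear peptide with free termini.

    The peptide is formed by condensation: residue backbones are chained
    N->C through amide bonds, losing one water per bond.
    """
    if not sequence:
        raise ValueError("empty sequence")
    for code in sequence:
        _check_code(code)
    raw = "".join(_backbone(c) for c in sequence) + "O"
    return _finalize(raw, include_stereo)


def span_fragment_smiles(
    sequence: str, mode: str = "condensed", include_stereo: bool = True
) -> str:
    """SMILES rendering of a masked residue span.

    ``condensed`` renders the span as one peptide-bonded fragment;
    ``per_residue`` renders each residue's free amino acid joined by the
    '.' disconnection symbol, preserving N->C order.
    """
    if mode == "condensed":
        return peptide_smiles(sequence, include_stereo)
    if mode == "per_residue":
        if not sequence:
            raise ValueError("empty sequence")
        return ".".join(residue_smiles(c, include_stereo) for c in sequence)
    raise ValueError(f"unknown fragment mode: {mode!r}")


@dataclass(frozen=True)
class AdductSpec:
    """A covalent-adduct fragment with one attachment dummy atom.

    The dummy atom ('*' or '[*]') marks where the fragment bonds to the
    residue's reactive atom.  Only singly-bonded, single-attachment adducts
    are representable; anything else is rejected at validation.
    """

    smiles_with_dummy: str
    name: str = ""

    def mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles_with_dummy)
        if mol is None:
            raise ValueError(f"invalid adduct SMILES: {self.smiles_with_dummy!r}")
        return mol

    def validate(self) -> None:
        mol = self.mol()
        dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise ValueError(
                f"adduct must contain exactly one dummy atom, found {len(dummies)}: "
                f"{self.smiles_with_dummy!r}"
            )
        dummy = dummies[0]
        bonds = dummy.GetBonds()
        if len(bonds) != 1 or bonds[0].GetBondType() != Chem.BondType.SINGLE:
            raise ValueError(
                "adduct dummy atom must participate in exactly one single bond: "
                f"{self.smiles_with_dummy!r}"
            )

    def heavy_atoms_without_dummy(self) -> int:
        mol = self.mol()
        return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


@dataclass(frozen=True)
class ModifiedResidue:
    """A residue carrying a covalently grafted adduct."""

    base_code: str
    adduct: AdductSpec
    product_smiles: str


def _residue_mol_with_reactive_atom(code: str, include_stereo: bool):
    """Parse the free-residue template keeping the reactive-atom map."""
    raw = _backbone(code) + "O"
    if not include_stereo:
        raw = _strip_stereo(raw)
    mol = Chem.MolFromSmiles(raw)
    reactive = None
    for atom in mol.GetAtoms():
        if atom.GetAtomMapNum() == 1:
            reactive = atom.GetIdx()
        atom.SetAtomMapNum(0)
    return mol, reactive


def graft_adduct(
    code: str, adduct: AdductSpec, include_stereo: bool = True
) -> ModifiedResidue:
    """Attach an adduct to a residue's reactive side-chain atom.

    The dummy atom is deleted, its single neighbour is joined to the
    reactive atom by a new single bond, and one hydrogen leaves the
    reactive atom to keep its valence.  The product is sanitized and
    canonicalized; heavy atoms are conserved exactly.
    """
    _check_code(code)
    if code not in REACTIVE_RESIDUES:
        raise ValueError(f"residue {code!r} has no reactive side-chain atom defined")
    adduct.validate()

    residue, reactive_idx = _residue_mol_with_reactive_atom(code, include_stereo)
    reactive_atom = residue.GetAtomWithIdx(reactive_idx)
    if reactive_atom.GetTotalNumHs() < 1:
        raise ValueError(
            f"reactive atom of residue {code!r} has no hydrogen available for grafting"
        )

    adduct_mol = adduct.mol()
    combo = Chem.RWMol(Chem.CombineMols(residue, adduct_mol))
    offset = residue.GetNumAtoms()
    dummy_idx = next(
        a.GetIdx() for a in combo.GetAtoms() if a.GetAtomicNum() == 0
    )
    neighbor_idx = combo.GetAtomWithIdx(dummy_idx).GetNeighbors()[0].GetIdx()
    combo.AddBond(reactive_idx, neighbor_idx, Chem.BondType.SINGLE)
    combo.RemoveAtom(dummy_idx)

    target = combo.GetAtomWithIdx(reactive_idx if reactive_idx < dummy_idx else reactive_idx)
    if target.GetNumExplicitHs() > 0:
        target.SetNumExplicitHs(target.GetNumExplicitHs() - 1)

    try:
        Chem.SanitizeMol(combo)
    except Exception as exc:  # rdkit raises its own exception hierarchy
        raise ValueError(f"grafting {adduct.smiles_with_dummy!r} onto {code!r} "
                         f"gives an invalid valence: {exc}") from exc
    product = Chem.MolToSmiles(combo)
    return ModifiedResidue(base_code=code, adduct=adduct, product_smiles=product)
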