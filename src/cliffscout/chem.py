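"""Shared RDKit helpers: parsing, standardization, canonical SMILES.

All structure handling in the package goes through these functions so that
every module sees the same canonical form of a compound (largest organic
fragment, neutralized where unambiguous, stereo-aware canonical SMILES).
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

# RDKit is chatty about kekulization/valence on malformed inputs; curation
# reports those failures itself with reason codes.
RDLogger.DisableLog("rdApp.*")

_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed or standardized."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparseable SMILES: {smiles!r}")
    return mol


def standardize(smiles: str) -> str:
    """Canonical SMILES of the largest organic fragment, neutralized.

    Salt/solvent components are stripped by keeping the largest fragment;
    charges are neutralized where this is unambiguous (protonation state
    changes only).  Pair matching requires a single parent structure, so a
    multi-component input never survives standardization as such.
    """
    mol = mol_from_smiles(smiles)
    mol = _LARGEST_FRAGMENT.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesError(f"no atoms left after standardization: {smiles!r}")
    return Chem.MolToSmiles(mol)


@lru_cache(maxsize=200_000)
def canonical(smiles: str) -> str:
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def strip_stereo(smiles: str) -> str:
    """Canonical SMILES with all stereochemistry removed."""
    mol = mol_from_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def heavy_atoms(smiles: str) -> int:
    """Number of heavy (non-H, non-dummy) atoms in a SMILES fragment."""
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesError(f"unparseable fragment SMILES: {smiles!r}")
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def molecular_formula(smiles: str) -> str:
    return CalcMolFormula(mol_from_smiles(smiles))


def molecular_weight(smiles: str) -> float:
    return Descriptors.MolWt(mol_from_smiles(smiles))
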