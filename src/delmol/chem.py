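"""Molecule wrapper and canonicalization helpers.

All SMILES handling in the package goes through :func:`canonical_smiles` so
that uniqueness, novelty and vocabulary membership agree on a single dialect:
RDKit's default canonical aromatic SMILES, stereochemistry preserved, no
kekulization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger

# RDKit is chatty about every rejected SMILES; invalid input is an expected,
# handled condition throughout this package.
RDLogger.DisableLog("rdApp.*")


class InvalidMoleculeError(ValueError):
    """Raised when an operation requires a chemically valid molecule."""


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES, or None if the string does not parse/sanitize."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


@dataclass
class Molecule:
    """A molecule held as canonical SMILES plus its parsed RDKit graph.

    ``valid`` is False when the input SMILES failed RDKit sanitization; in
    that case ``graph`` is None and ``smiles`` keeps the raw input string so
    the failure can be reported.
    """

    smiles: str
    graph: Chem.Mol | None = field(default=None, repr=False)
    valid: bool = True

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return cls(smiles=smiles, graph=None, valid=False)
        return cls(smiles=Chem.MolToSmiles(mol), graph=mol, valid=True)

    def require_valid(self) -> Chem.Mol:
        if not self.valid or self.graph is None:
            raise InvalidMoleculeError(f"invalid molecule: {self.smiles!r}")
        return self.graph

    @property
    def num_heavy_atoms(self) -> int:
        return self.require_valid().GetNumHeavyAtoms()

    @property
    def num_rings(self) -> int:
        return Chem.GetSSSR(self.require_valid())

    def __hash__(self) -> int:
        return hash(self.smiles)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Molecule) and other.smiles == self.smiles


def as_molecule(obj: "Molecule | str") -> Molecule:
    if isinstance(obj, Molecule):
        return obj
    return Molecule.from_smiles(obj)
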