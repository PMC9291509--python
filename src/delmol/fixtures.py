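"""Seeded synthetic drug-like SMILES libraries.

Molecules are assembled as scaffold–linker–scaffold combinations (two ring
systems joined through an amide, ether, sulfonamide, amine or direct
biaryl linkage), optionally decorated, which guarantees at least one
retrosynthetically breakable ring-entry bond and therefore >= 2 BRICS
fragments per molecule.  The library stands in for a small drug-like
screening collection during testing; it does not claim the property
distribution of any real vendor catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import Molecule
from .fragmentation import fragment_count

__all__ = ["FixtureSpec", "generate_fixtures"]

# ring systems; [1*] marks the attachment to the linker's left side
_DEFAULT_SCAFFOLDS = [
    "[1*]c1ccccc1",
    "[1*]c1ccc(F)cc1",
    "[1*]c1ccc(Cl)cc1",
    "[1*]c1ccc(C)cc1",
    "[1*]c1ccc(OC)cc1",
    "[1*]c1ccccn1",
    "[1*]c1ccncc1",
    "[1*]c1cccnc1C",
    "[1*]c1ncccn1",
    "[1*]c1cccs1",
    "[1*]c1ccco1",
    "[1*]c1ccc2ccccc2c1",
    "[1*]C1CCCCC1",
    "[1*]C1CCNCC1",
    "[1*]C1CCOCC1",
    "[1*]c1ccc(C(F)(F)F)cc1",
    "[1*]c1ccc(N)cc1",
    "[1*]c1ccc(O)cc1",
]

# linkers; [1*] joins scaffold A, [2*] joins scaffold B
_DEFAULT_LINKERS = [
    "[1*]C(=O)N[2*]",
    "[1*]NC(=O)C[2*]",
    "[1*]O[2*]",
    "[1*]OCC[2*]",
    "[1*]S(=O)(=O)N[2*]",
    "[1*]CNC(=O)[2*]",
    "[1*]N(C)C(=O)[2*]",
    "[1*]CC[2*]",
]


@dataclass
class FixtureSpec:
    n_molecules: int = 200
    scaffolds: list[str] = field(default_factory=lambda: list(_DEFAULT_SCAFFOLDS))
    linkers: list[str] = field(default_factory=lambda: list(_DEFAULT_LINKERS))
    seed: int = 0


def _zip_parts(*parts: str) -> Molecule | None:
    mols = [Chem.MolFromSmiles(p) for p in parts]
    if any(m is None for m in mols):
        return None
    combined = mols[0]
    for m in mols[1:]:
        combined = Chem.CombineMols(combined, m)
    rw = Chem.RWMol(combined)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(atom.GetIsotope())
            atom.SetIsotope(0)
    try:
        out = Chem.molzip(rw.GetMol())
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Molecule.from_smiles(Chem.MolToSmiles(out))


def generate_fixtures(spec: FixtureSpec) -> list[Molecule]:
    """Deterministic list of ``n_molecules`` unique multi-fragment molecules.

    Raises ValueError when the combinatorial space cannot supply the
    requested count.
    """
    if not spec.scaffolds or not spec.linkers:
        raise ValueError("scaffold and linker sets must be non-empty")
    rng = np.random.default_rng(spec.seed)
    combos = [(a, l, b)
              for a in range(len(spec.scaffolds))
              for l in range(len(spec.linkers))
              for b in range(len(spec.scaffolds))]
    rng.shuffle(combos)

    out: list[Molecule] = []
    seen: set[str] = set()
    for a, l, b in combos:
        if len(out) >= spec.n_molecules:
            break
        left = spec.scaffolds[a]
        # scaffold B must expose the linker's [2*] label
        right = spec.scaffolds[b].replace("[1*]", "[2*]")
        mol = _zip_parts(left, spec.linkers[l], right)
        if mol is None or not mol.valid or mol.smiles in seen:
            continue
        if fragment_count(mol) < 2:
            continue
        seen.add(mol.smiles)
        out.append(mol)
    if len(out) < spec.n_molecules:
        raise ValueError(
            f"could only build {len(out)} of {spec.n_molecules} requested molecules")
    return out
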