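"""Optimization objectives: SAS, logP and binding affinity (BAS).

All three objectives are minimized: lower synthetic accessibility means an
easier synthesis, lower logP is preferred by the evolutionary search (a
drug-likeness *range* on logP is applied later, at screening time), and a
more negative docking score means stronger predicted binding.

``compute_bas`` shells out to an AutoDock-Vina-compatible engine (see
:mod:`delmol.screening`); ``surrogate_bas`` is a deterministic, documented
stand-in with a realistic score range so the evolutionary loop can be run
and tested end to end on a desktop.  It is not an approximation of docking.
"""

from __future__ import annotations

import hashlib
import logging
import math
import os
import sys
from dataclasses import dataclass, field

from rdkit.Chem import Crippen, RDConfig

from .chem import InvalidMoleculeError, Molecule, as_molecule

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module, path injected above)

logger = logging.getLogger(__name__)

__all__ = [
    "ObjectiveVector",
    "PropertyRecord",
    "compute_sas",
    "compute_logp",
    "surrogate_bas",
    "evaluate_objectives",
]


@dataclass(frozen=True)
class ObjectiveVector:
    """(SAS, logP, BAS) — smaller is better on every coordinate."""

    sas: float
    logp: float
    bas: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sas, self.logp, self.bas)

    def is_finite(self) -> bool:
        return all(map(math.isfinite, self.as_tuple()))


@dataclass
class PropertyRecord:
    smiles: str
    objectives: ObjectiveVector
    extra: dict[str, float] = field(default_factory=dict)


def compute_sas(mol: Molecule | str) -> float:
    """Ertl–Schuffenhauer synthetic accessibility score (~1 easy .. 10 hard)."""
    return float(sascorer.calculateScore(as_molecule(mol).require_valid()))


def compute_logp(mol: Molecule | str) -> float:
    """Crippen atom-contribution octanol–water partition coefficient."""
    return float(Crippen.MolLogP(as_molecule(mol).require_valid()))


def _stable_unit_hash(text: str, seed: int) -> float:
    """Deterministic pseudo-random value in [0, 1) from (text, seed)."""
    digest = hashlib.sha256(f"{seed}:{text}".encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


def surrogate_bas(mol: Molecule | str, seed: int = 0) -> float:
    """Deterministic docking-score stand-in in roughly [-12, -2] kcal/mol.

    score = -(1.2 * ring_count + 0.8 * sqrt(heavy_atoms) + 0.5 * h)
    where h in [0, 1) is a stable hash of (canonical SMILES, seed), clipped
    to [-12, -2].  Strictly decreasing in ring count (the hash offset spans
    less than the 1.2 per-ring step), smooth in size, and bit-reproducible.
    """
    mol = as_molecule(mol)
    graph = mol.require_valid()
    rings = graph.GetRingInfo().NumRings()
    heavy = graph.GetNumHeavyAtoms()
    raw = -(1.2 * rings + 0.8 * math.sqrt(heavy)
            + 0.5 * _stable_unit_hash(mol.smiles, seed))
    return float(min(-2.0, max(-12.0, raw)))


def evaluate_objectives(mols, scorer, **scorer_kwargs) -> list[PropertyRecord]:
    """Score a batch of molecules; invalid inputs are dropped with a log line.

    ``scorer`` supplies the BAS coordinate (``surrogate_bas`` or a docking
    adapter); SAS and logP always come from the toolkit implementations.
    Order of the valid inputs is preserved.
    """
    records: list[PropertyRecord] = []
    for m in mols:
        m = as_molecule(m)
        if not m.valid:
            logger.warning("skipping invalid molecule %r", m.smiles)
            continue
        try:
            bas = float(scorer(m, **scorer_kwargs))
        except Exception as exc:
            logger.warning("BAS scorer failed for %s (%s); assigning +inf", m.smiles, exc)
            bas = math.inf
        records.append(PropertyRecord(
            smiles=m.smiles,
            objectives=ObjectiveVector(sas=compute_sas(m),
                                       logp=compute_logp(m), bas=bas),
            extra={"heavy_atoms": float(m.num_heavy_atoms)},
        ))
    return records
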