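"""Docking adapter and first-front virtual screening.

The docking engine is any AutoDock-Vina-compatible executable (QVina
recommended); ligands are 3D-embedded with RDKit and converted to PDBQT
with Open Babel.  Screening applies inclusive property windows to the
rank-1 (non-dominated) members of a population: SAS <= 3,
-0.4 <= logP <= 5.6, and BAS below a threshold calibrated as the worst
(maximum) docking score among known ligands of the target.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import Molecule, as_molecule
from .objectives import PropertyRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DockingError",
    "DockingConfig",
    "ScreeningCriteria",
    "prepare_ligand",
    "compute_bas",
    "dock_one",
    "screen_first_front",
    "rank_by_bas",
    "calibrate_bas_threshold",
]


class DockingError(RuntimeError):
    """Engine, conversion or preparation failure; carries the engine log."""


@dataclass
class DockingConfig:
    receptor_path: str
    box_center: tuple[float, float, float] = (9.879, -13.774, 7.012)
    box_size: tuple[float, float, float] = (60.0, 60.0, 60.0)
    engine: str = "qvina"
    engine_seed: int = 0
    exhaustiveness: int = 8
    timeout_s: float = 600.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.box_size):
            raise ValueError("box_size must be positive in every dimension")


@dataclass
class ScreeningCriteria:
    """Inclusive screening windows (defaults follow the CA9 study)."""

    sas_max: float = 3.0
    logp_min: float = -0.4
    logp_max: float = 5.6
    bas_max: float = -6.6

    def __post_init__(self) -> None:
        if self.logp_min > self.logp_max:
            raise ValueError("logp_min must not exceed logp_max")

    def passes(self, record: PropertyRecord) -> bool:
        o = record.objectives
        return (o.sas <= self.sas_max
                and self.logp_min <= o.logp <= self.logp_max
                and o.bas <= self.bas_max)


def prepare_ligand(mol: Molecule | str, out_path, conformer_seed: int = 0) -> Path:
    """Embed a 3D conformer and write an engine-ready PDBQT ligand file."""
    mol = as_molecule(mol)
    graph = Chem.AddHs(mol.require_valid())
    params = AllChem.ETKDGv3()
    params.randomSeed = conformer_seed
    if AllChem.EmbedMolecule(graph, params) != 0:
        raise DockingError(f"3D embedding failed for {mol.smiles}")
    AllChem.MMFFOptimizeMolecule(graph)
    out_path = Path(out_path)
    sdf_path = out_path.with_suffix(".sdf")
    writer = Chem.SDWriter(str(sdf_path))
    writer.write(graph)
    writer.close()
    obabel = shutil.which("obabel")
    if obabel is None:
        raise DockingError("obabel not found on PATH for PDBQT conversion")
    proc = subprocess.run(
        [obabel, str(sdf_path), "-O", str(out_path), "--partialcharge", "gasteiger"],
        capture_output=True, text=True)
    if proc.returncode != 0 or not out_path.exists():
        raise DockingError(f"obabel conversion failed: {proc.stderr}")
    return out_path


_AFFINITY_ROW = re.compile(r"^\s*1\s+(-?\d+\.\d+)", re.MULTILINE)
_RESULT_REMARK = re.compile(r"REMARK VINA RESULT:\s+(-?\d+\.\d+)")


def parse_engine_output(stdout: str, pose_text: str = "") -> float:
    """Best-mode affinity from a vina-style result table or pose remarks."""
    m = _AFFINITY_ROW.search(stdout)
    if m:
        return float(m.group(1))
    m = _RESULT_REMARK.search(pose_text or stdout)
    if m:
        return float(m.group(1))
    raise DockingError(f"could not parse affinity from engine output:\n{stdout[-2000:]}")


def compute_bas(mol: Molecule | str, cfg: DockingConfig,
                conformer_seed: int = 0) -> float:
    """Dock one molecule and return the best (lowest) pose score."""
    mol = as_molecule(mol)
    if not Path(cfg.receptor_path).exists():
        raise DockingError(f"receptor file not found: {cfg.receptor_path}")
    engine = shutil.which(cfg.engine)
    if engine is None:
        raise DockingError(f"docking engine {cfg.engine!r} not found on PATH")
    with tempfile.TemporaryDirectory(prefix="delmol_dock_") as tmp:
        ligand = prepare_ligand(mol, Path(tmp) / "ligand.pdbqt", conformer_seed)
        out_pose = Path(tmp) / "out.pdbqt"
        cmd = [engine,
               "--receptor", str(cfg.receptor_path),
               "--ligand", str(ligand),
               "--center_x", str(cfg.box_center[0]),
               "--center_y", str(cfg.box_center[1]),
               "--center_z", str(cfg.box_center[2]),
               "--size_x", str(cfg.box_size[0]),
               "--size_y", str(cfg.box_size[1]),
               "--size_z", str(cfg.box_size[2]),
               "--seed", str(cfg.engine_seed),
               "--exhaustiveness", str(cfg.exhaustiveness),
               "--out", str(out_pose)]
        try:
            proc = subprocess.run(cmd, capture_output=True, text=True,
                                  timeout=cfg.timeout_s)
        except subprocess.TimeoutExpired as exc:
            raise DockingError(f"docking timed out after {cfg.timeout_s}s") from exc
        if proc.returncode != 0:
            raise DockingError(f"engine exited {proc.returncode}:\n{proc.stderr}")
        pose_text = out_pose.read_text() if out_pose.exists() else ""
        return parse_engine_output(proc.stdout, pose_text)


def dock_one(mol: Molecule | str, cfg: DockingConfig) -> float:
    """Alias of :func:`compute_bas` for the screening workflow."""
    return compute_bas(mol, cfg)


def screen_first_front(population, criteria: ScreeningCriteria) -> list[PropertyRecord]:
    """Rank-1 members satisfying every (inclusive) screening window."""
    if any(m.rank is None for m in population.members):
        raise ValueError("population must be ranked before screening")
    return [m.record() for m in population.front(1) if criteria.passes(m.record())]


def rank_by_bas(records: list[PropertyRecord]) -> list[PropertyRecord]:
    """Sort best (most negative) binding score first; ties by SMILES."""
    return sorted(records, key=lambda r: (r.objectives.bas, r.smiles))


def calibrate_bas_threshold(ligand_scores: list[float]) -> float:
    """Screening upper bound = worst (maximum) score among known ligands."""
    if not ligand_scores:
        raise ValueError("need at least one reference ligand score")
    return float(max(ligand_scores))
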