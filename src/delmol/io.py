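"""File formats and run configuration.

SMILES files are plain text (one molecule per line, optional tab-separated
id, ``#`` comments skipped).  Fragment sequences serialize to JSON lines.
Run configuration is YAML (JSON is valid YAML) validated strictly against
a schema whose defaults are the study's hyperparameter table.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .chem import Molecule
from .evolution import DELConfig
from .fragmentation import FragmentSequence
from .generative import ModelConfig

logger = logging.getLogger(__name__)

__all__ = [
    "read_smiles",
    "write_smiles",
    "write_fragments_jsonl",
    "read_fragments_jsonl",
    "RunConfig",
    "load_config",
]


def read_smiles(path) -> list[Molecule]:
    """Read a SMILES file; malformed lines are logged and skipped."""
    path = Path(path)
    mols: list[Molecule] = []
    n_skipped = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles = line.split("\t")[0].split()[0]
        mol = Molecule.from_smiles(smiles)
        if not mol.valid:
            n_skipped += 1
            logger.warning("%s:%d: skipping malformed SMILES %r", path, lineno, smiles)
            continue
        mols.append(mol)
    if n_skipped:
        logger.info("%s: skipped %d malformed lines", path, n_skipped)
    return mols


def write_smiles(mols, path) -> None:
    Path(path).write_text(
        "".join(f"{m.smiles if isinstance(m, Molecule) else m}\n" for m in mols))


def write_fragments_jsonl(sequences: list[FragmentSequence], path) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(json.dumps({"source": seq.source, "fragments": seq.fragments})
                     + "\n")


def read_fragments_jsonl(path) -> list[dict]:
    return [json.loads(line) for line in Path(path).read_text().splitlines() if line]


class _DELSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    generations: int = 10
    population_size: int = 20000
    initial_epochs: int = 20
    subsequent_epochs: int = 10
    annealing_rate: float = 0.8
    tournament_p: float = 0.95
    mutation_rate: float = 0.01
    mutation_sigma_scale: float = 0.1
    crossover_swap_p: float = 0.5
    elite_fraction: float = 0.5
    finetune_fraction: float = 0.2

    @field_validator("tournament_p")
    @classmethod
    def _check_tournament(cls, v: float) -> float:
        if not (0.0 < v <= 1.0):
            raise ValueError("tournament_p must be in (0, 1]")
        return v

    @field_validator("mutation_rate")
    @classmethod
    def _check_rate(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        return v


class _ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid", protected_namespaces=())
    kind: str = "jtvae"
    embedding_size: int = 128
    hidden_size: int = 450
    latent_size: int = 64
    recurrent_layers: int = 1
    learning_rate: float = 0.0001
    batch_size: int = 32
    beta: float = 0.1
    alpha: float = 0.1
    tiny: bool = False

    @field_validator("kind")
    @classmethod
    def _check_kind(cls, v: str) -> str:
        if v not in ("jtvae", "fragvae"):
            raise ValueError("model kind must be 'jtvae' or 'fragvae'")
        return v


class _DockingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    surrogate: bool = True
    engine: str = "qvina"
    receptor_path: str | None = None
    box_center: tuple[float, float, float] = (9.879, -13.774, 7.012)
    box_size: tuple[float, float, float] = (60.0, 60.0, 60.0)
    engine_seed: int = 0
    exhaustiveness: int = 8


class RunConfig(BaseModel):
    """Validated run configuration; defaults are the study settings."""

    model_config = ConfigDict(extra="forbid", protected_namespaces=())
    del_: _DELSection = Field(default_factory=_DELSection, alias="del")
    model: _ModelSection = Field(default_factory=_ModelSection)
    docking: _DockingSection = Field(default_factory=_DockingSection)
    dataset: str | None = None
    output: str | None = None
    seed: int = 0

    def del_config(self) -> DELConfig:
        d = self.del_.model_dump()
        return DELConfig(seed=self.seed, **d)

    def model_cfg(self) -> ModelConfig:
        m = self.model
        if m.tiny:
            return ModelConfig.tiny(learning_rate=m.learning_rate,
                                    batch_size=m.batch_size,
                                    beta=m.beta, alpha=m.alpha)
        return ModelConfig(embedding_size=m.embedding_size,
                           hidden_size=m.hidden_size,
                           latent_size=m.latent_size,
                           recurrent_layers=m.recurrent_layers,
                           learning_rate=m.learning_rate,
                           batch_size=m.batch_size, beta=m.beta, alpha=m.alpha)


def load_config(path=None, text: str | None = None) -> RunConfig:
    """Load a YAML/JSON run configuration; unknown keys are fatal."""
    if text is None:
        text = Path(path).read_text() if path else "{}"
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)
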