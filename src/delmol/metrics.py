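"""Population-quality metrics.

Three SMILES-level ratios (validity, novelty, uniqueness), the exact
1-Wasserstein distance between empirical property distributions, and the
hypervolume indicator of a Pareto front under minimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import wasserstein_distance

from .chem import Molecule, as_molecule
from .objectives import ObjectiveVector

__all__ = [
    "UndefinedMetricError",
    "InvalidReferenceError",
    "validity_ratio",
    "novelty_ratio",
    "uniqueness_ratio",
    "wasserstein1",
    "hypervolume",
    "reference_point",
    "generation_report",
]


class UndefinedMetricError(ValueError):
    """A ratio metric was requested on an empty population."""


class InvalidReferenceError(ValueError):
    """A front point falls outside the box bounded by the reference point."""


def _valid_smiles(mols) -> tuple[list[str], int]:
    """Canonical SMILES of the valid entries, plus the total count."""
    total = 0
    valid = []
    for m in mols:
        total += 1
        m = as_molecule(m)
        if m.valid:
            valid.append(m.smiles)
    return valid, total


def validity_ratio(mols) -> float:
    """Fraction of inputs that are chemically valid."""
    valid, total = _valid_smiles(mols)
    if total == 0:
        raise UndefinedMetricError("validity of an empty population is undefined")
    return len(valid) / total


def uniqueness_ratio(mols) -> float:
    """Fraction of valid molecules that are not duplicated (canonical SMILES)."""
    valid, _ = _valid_smiles(mols)
    if not valid:
        raise UndefinedMetricError("uniqueness needs at least one valid molecule")
    return len(set(valid)) / len(valid)


def novelty_ratio(mols, training_set) -> float:
    """Fraction of the valid-and-unique molecules absent from the training set."""
    valid, _ = _valid_smiles(mols)
    if not valid:
        raise UndefinedMetricError("novelty needs at least one valid molecule")
    unique = set(valid)
    train = {as_molecule(t).smiles for t in training_set}
    return len(unique - train) / len(unique)


def wasserstein1(a, b) -> float:
    """Exact 1-Wasserstein distance between two empirical samples on R.

    Equals the integral of |F_a - F_b| over the line; for equal sample
    sizes this is the mean absolute difference of the sorted samples.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise UndefinedMetricError("W1 needs two non-empty samples")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("W1 requires finite samples")
    return float(wasserstein_distance(a, b))


def _as_points(front) -> np.ndarray:
    pts = np.array([p.as_tuple() if isinstance(p, ObjectiveVector) else tuple(p)
                    for p in front], dtype=float)
    if pts.ndim != 2:
        raise ValueError("front must be a list of equal-length objective vectors")
    return pts


def hypervolume(front, ref) -> float:
    """Lebesgue measure of the union of boxes [point, ref] (minimization).

    Exact for any dimension via recursive slicing on the first coordinate;
    dominated points are absorbed by the union.  Every front point must
    weakly dominate the reference point.
    """
    ref = np.asarray(ref.as_tuple() if isinstance(ref, ObjectiveVector) else tuple(ref),
                     dtype=float)
    if len(front) == 0:
        return 0.0
    pts = _as_points(front)
    if pts.shape[1] != ref.shape[0]:
        raise ValueError("reference point dimension mismatch")
    if (pts > ref[None, :]).any():
        raise InvalidReferenceError("a front point lies beyond the reference point")
    return _hv_recursive(pts, ref)


def _pareto_min(pts: np.ndarray) -> np.ndarray:
    """Non-dominated subset under minimization (small n, quadratic scan)."""
    keep = []
    for i, p in enumerate(pts):
        dominated = False
        for j, q in enumerate(pts):
            if j != i and (q <= p).all() and (q < p).any():
                dominated = True
                break
            if j < i and (q == p).all():  # drop exact duplicates
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return pts[keep]


def _hv_recursive(pts: np.ndarray, ref: np.ndarray) -> float:
    d = pts.shape[1]
    if d == 1:
        return float(ref[0] - pts[:, 0].min())
    if d == 2:
        pareto = _pareto_min(pts)
        order = np.argsort(pareto[:, 0])
        pareto = pareto[order]
        xs = np.append(pareto[1:, 0], ref[0])
        return float(np.sum((xs - pareto[:, 0]) * (ref[1] - pareto[:, 1])))
    xs = np.unique(pts[:, 0])
    total = 0.0
    for k, x in enumerate(xs):
        upper = xs[k + 1] if k + 1 < len(xs) else ref[0]
        slab = pts[pts[:, 0] <= x][:, 1:]
        total += (upper - x) * _hv_recursive(slab, ref[1:])
    return float(total)


def reference_point(fronts, margin: float = 1.1) -> tuple[float, ...]:
    """Fixed worst-corner reference for a run: componentwise max x margin.

    The margin is applied multiplicatively away from zero (negative
    coordinates shift upward), so every front point keeps a non-empty box.
    """
    pts = _as_points(fronts)
    worst = pts.max(axis=0)
    out = []
    for w in worst:
        out.append(w * margin if w > 0 else (w / margin if w < 0 else 0.1))
    return tuple(float(v) for v in out)


@dataclass
class GenerationReport:
    generation: int
    validity: float
    novelty: float
    uniqueness: float
    w1_sas: float
    w1_logp: float
    w1_bas: float
    hypervolume: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def generation_report(generation: int, population_records, front1,
                      initial_records, training_smiles, ref,
                      n_decoded: int | None = None,
                      n_valid_decoded: int | None = None) -> GenerationReport:
    """One metrics row for a generation.

    ``population_records`` and ``initial_records`` are PropertyRecord lists;
    ``front1`` the rank-1 objective vectors.  Validity can be overridden
    with raw decode counts (valid/attempted) when they are known — the
    population itself only stores the valid survivors.
    """
    pop_smiles = [r.smiles for r in population_records]
    if n_decoded and n_decoded > 0:
        validity = (n_valid_decoded if n_valid_decoded is not None
                    else len(pop_smiles)) / n_decoded
    else:
        validity = validity_ratio(pop_smiles)
    col = lambda recs, name: [getattr(r.objectives, name) for r in recs
                              if math.isfinite(getattr(r.objectives, name))]
    front_in_box = [p for p in front1
                    if all(c <= r for c, r in zip(
                        (p.as_tuple() if isinstance(p, ObjectiveVector) else tuple(p)),
                        ref))]
    return GenerationReport(
        generation=generation,
        validity=validity,
        novelty=novelty_ratio(pop_smiles, training_smiles),
        uniqueness=uniqueness_ratio(pop_smiles),
        w1_sas=wasserstein1(col(population_records, "sas"), col(initial_records, "sas")),
        w1_logp=wasserstein1(col(population_records, "logp"), col(initial_records, "logp")),
        w1_bas=wasserstein1(col(population_records, "bas"), col(initial_records, "bas")),
        hypervolume=hypervolume(front_in_box, ref),
    )
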