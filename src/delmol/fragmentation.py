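"""Fragment-based molecular representations.

Two complementary decompositions are provided:

* **BRICS fragment sequences** — a molecule's SMILES is scanned left to
  right and cleaved at retrosynthetically breakable (BRICS) bonds through
  which the scan *enters a ring system*.  This produces a short sequence of
  ring-system fragments with their acyclic linkers attached, each carrying
  dummy-atom attachment points, and the sequence can be reassembled exactly
  (leaves to root, right to left).
* **Junction trees** — the molecular graph is covered by clusters (simple
  rings, bridged ring systems, non-ring bonds, junction atoms) and the
  cluster graph is contracted to its maximum spanning tree.

Both feed the generative models; the BRICS sequence is the token stream of
the sequence VAE and the junction-tree clusters form the vocabulary of the
tree-structured model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import BRICS

from .chem import InvalidMoleculeError, Molecule, as_molecule

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSequence",
    "JunctionTree",
    "Cluster",
    "ClusterVocabulary",
    "AssemblyError",
    "brics_fragment",
    "reassemble",
    "assemble_tokens",
    "fragment_count",
    "scan_cleavage_bonds",
    "tree_decompose",
    "build_cluster_vocabulary",
    "preprocess_dataset",
]


class AssemblyError(ValueError):
    """Fragments cannot be rejoined into a single sane molecule."""


# ---------------------------------------------------------------------------
# BRICS sequence fragmentation
# ---------------------------------------------------------------------------


@dataclass
class FragmentSequence:
    """Ordered fragments of a molecule, left-to-right scan order.

    ``fragments`` carry bare ``*`` attachment markers (display/interchange
    form).  ``tokens`` are the same fragments with directional attachment
    maps — the dummy linking back toward the root carries atom map 1, the
    dummies linking forward to child fragments carry maps 2, 3, ... in scan
    order — which makes a token sequence unambiguous to reassemble.
    ``labeled`` pairs the two ends of every cleaved bond by isotope number
    and is used for exact round-trip reassembly.
    """

    source: str
    fragments: list[str]
    tokens: list[str] = field(default_factory=list)
    labeled: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fragments)


def scan_cleavage_bonds(mol: Chem.Mol) -> list[tuple[int, int]]:
    """Bonds cleaved by the left-to-right scan, as (earlier, later) pairs.

    A BRICS-breakable bond is cleaved exactly when the scan enters a ring
    through it, i.e. when its later-scanned atom (atom indices follow the
    SMILES string) belongs to a ring.  Ordered by position of the later
    atom, which is the order the scan encounters them.
    """
    out = []
    for (i, j), _types in BRICS.FindBRICSBonds(mol):
        a, b = (i, j) if i < j else (j, i)
        if mol.GetAtomWithIdx(b).IsInRing():
            out.append((a, b))
    return sorted(set(out), key=lambda ab: (ab[1], ab[0]))


def _strip_to_bare(smiles: str) -> str:
    """Canonical SMILES with all dummy labels removed (bare ``*``)."""
    m = Chem.MolFromSmiles(smiles)
    for atom in m.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
            atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(m)


def brics_fragment(mol: Molecule | str) -> FragmentSequence:
    """Cleave a molecule into its left-to-right BRICS fragment sequence."""
    mol = as_molecule(mol)
    graph = mol.require_valid()
    n_atoms = graph.GetNumAtoms()
    bonds = scan_cleavage_bonds(graph)
    if not bonds:
        return FragmentSequence(
            source=mol.smiles,
            fragments=[mol.smiles],
            tokens=[mol.smiles],
            labeled=[mol.smiles],
        )

    bond_ids = [graph.GetBondBetweenAtoms(a, b).GetIdx() for a, b in bonds]
    cut = Chem.FragmentOnBonds(
        graph, bond_ids, dummyLabels=[(k + 1, k + 1) for k in range(len(bonds))]
    )
    piece_indices: list[list[int]] = []
    pieces = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True,
                              fragsMolAtomMapping=piece_indices)

    # piece k owns original atoms {i < n_atoms}; order pieces by first atom
    order = sorted(range(len(pieces)),
                   key=lambda k: min(i for i in piece_indices[k] if i < n_atoms))
    atom_home = {}
    for k, idxs in enumerate(piece_indices):
        for i in idxs:
            if i < n_atoms:
                atom_home[i] = k

    labeled, tokens, bare = [], [], []
    for k in order:
        piece = Chem.Mol(pieces[k])
        labeled.append(Chem.MolToSmiles(piece))
        # directional maps: isotope c+1 on the b-side (child piece) is the
        # backward link (map 1); on the a-side it links forward to a child
        forward = []  # (child entry atom index, dummy); entry order = scan order
        for atom in piece.GetAtoms():
            if atom.GetAtomicNum() != 0:
                continue
            cut_idx = atom.GetIsotope() - 1
            a, b = bonds[cut_idx]
            atom.SetIsotope(0)
            if atom_home[b] == k:
                atom.SetAtomMapNum(1)
            else:
                forward.append((b, atom))
        for rank, (_, atom) in enumerate(sorted(forward, key=lambda t: t[0])):
            atom.SetAtomMapNum(2 + rank)
        tokens.append(Chem.MolToSmiles(piece))
        bare.append(_strip_to_bare(tokens[-1]))

    return FragmentSequence(source=mol.smiles, fragments=bare,
                            tokens=tokens, labeled=labeled)


def fragment_count(mol: Molecule | str) -> int:
    """Number of fragments the scan produces (cleaved bonds + 1)."""
    mol = as_molecule(mol)
    return len(scan_cleavage_bonds(mol.require_valid())) + 1


def reassemble(frags: FragmentSequence) -> Molecule:
    """Rejoin a fragment sequence into its parent molecule.

    When the sequence came from :func:`brics_fragment` the isotope-paired
    form is available and the round trip is exact.  Otherwise the
    directional token form is assembled right to left.
    """
    if frags.labeled and len(frags.labeled) == len(frags.fragments):
        mols = [Chem.MolFromSmiles(s) for s in frags.labeled]
        if all(m is not None for m in mols):
            if len(mols) == 1:
                return Molecule.from_smiles(frags.labeled[0])
            combined = mols[0]
            for m in mols[1:]:
                combined = Chem.CombineMols(combined, m)
            for atom in combined.GetAtoms():
                if atom.GetAtomicNum() == 0:
                    atom.SetAtomMapNum(atom.GetIsotope())
                    atom.SetIsotope(0)
            try:
                out = Chem.molzip(combined)
                Chem.SanitizeMol(out)
            except Exception as exc:  # pragma: no cover - chemically impossible for own cuts
                raise AssemblyError(str(exc)) from exc
            return Molecule.from_smiles(Chem.MolToSmiles(out))
    return assemble_tokens(frags.tokens or frags.fragments)


def _dummy_atoms(mol: Chem.Mol) -> list[Chem.Atom]:
    return [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]


def _join_backward(parent: Chem.Mol, dummy_map: int, child: Chem.Mol) -> Chem.Mol:
    """Bond the parent's forward dummy ``dummy_map`` to the child's map-1 dummy."""
    child_back = [a for a in _dummy_atoms(child) if a.GetAtomMapNum() == 1]
    if len(child_back) != 1:
        raise AssemblyError("child fragment must expose exactly one backward '*'")
    offset = parent.GetNumAtoms()
    combo = Chem.RWMol(Chem.CombineMols(parent, child))
    d1 = next(a.GetIdx() for a in combo.GetAtoms()
              if a.GetAtomicNum() == 0 and a.GetAtomMapNum() == dummy_map
              and a.GetIdx() < offset)
    d2 = next(a.GetIdx() for a in combo.GetAtoms()
              if a.GetAtomicNum() == 0 and a.GetAtomMapNum() == 1
              and a.GetIdx() >= offset)
    n1 = combo.GetAtomWithIdx(d1).GetNeighbors()[0].GetIdx()
    n2 = combo.GetAtomWithIdx(d2).GetNeighbors()[0].GetIdx()
    combo.AddBond(n1, n2, Chem.BondType.SINGLE)
    for idx in sorted((d1, d2), reverse=True):
        combo.RemoveAtom(idx)
    out = combo.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:
        raise AssemblyError(f"attachment rejected by sanitization: {exc}") from exc
    return out


def assemble_tokens(tokens: list[str]) -> Molecule:
    """Assemble directional fragment tokens right to left (leaves to root).

    Each token's forward dummies (maps >= 2) bind the subtrees of the
    fragments that follow it; a stack inverts the depth-first scan order.
    Raises :class:`AssemblyError` on arity mismatch or chemically
    incompatible attachments.
    """
    if not tokens:
        raise AssemblyError("empty fragment sequence")
    parsed = []
    for t in tokens:
        m = Chem.MolFromSmiles(t)
        if m is None:
            raise AssemblyError(f"unparseable fragment {t!r}")
        parsed.append(m)
    if len(parsed) == 1 and not _dummy_atoms(parsed[0]):
        return Molecule.from_smiles(tokens[0])

    stack: list[Chem.Mol] = []
    for mol in reversed(parsed):
        fwd_maps = sorted(a.GetAtomMapNum() for a in _dummy_atoms(mol)
                          if a.GetAtomMapNum() >= 2)
        current = mol
        # right-to-left processing leaves the earliest-scanned subtree on
        # top of the stack, so forward maps are consumed in ascending order
        for map_num in fwd_maps:
            if not stack:
                raise AssemblyError("dangling forward attachment point")
            current = _join_backward(current, map_num, stack.pop())
        stack.append(current)
    if len(stack) != 1:
        raise AssemblyError(f"{len(stack)} disconnected fragment subtrees remain")
    root = stack[0]
    leftovers = _dummy_atoms(root)
    if leftovers:
        raise AssemblyError("unmatched attachment points remain after assembly")
    return Molecule.from_smiles(Chem.MolToSmiles(root))


# ---------------------------------------------------------------------------
# Junction-tree decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cluster:
    atoms: frozenset[int]
    label: str  # ring | bridged-ring | bond | atom

    def sorted_atoms(self) -> list[int]:
        return sorted(self.atoms)


@dataclass
class JunctionTree:
    smiles: str
    nodes: list[Cluster]
    edges: list[tuple[int, int]]
    is_tree: bool

    def cluster_smiles(self, mol: Chem.Mol) -> list[str]:
        return [cluster_smiles(mol, c.sorted_atoms()) for c in self.nodes]


def cluster_smiles(mol: Chem.Mol, atoms: list[int]) -> str:
    """Canonical label SMILES for an atom cluster of ``mol``.

    The parent is kekulized first so partial aromatic systems export as
    sane Kekulé fragments; labels are canonicalized where they re-parse.
    """
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    smi = Chem.MolFragmentToSmiles(kek, atomsToUse=list(atoms), kekuleSmiles=True)
    back = Chem.MolFromSmiles(smi)
    return Chem.MolToSmiles(back) if back is not None else smi


def _union_find_mst(n_nodes: int, edges: list[tuple[int, int, int]]) -> list[tuple[int, int]]:
    """Kruskal maximum spanning forest; ties broken on (u, v)."""
    parent = list(range(n_nodes))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen = []
    for u, v, _w in sorted(edges, key=lambda e: (-e[2], e[0], e[1])):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            chosen.append((u, v))
    return chosen


def tree_decompose(mol: Molecule | str) -> JunctionTree:
    """Cover the molecular graph with clusters and contract to a tree.

    Clusters are the smallest set of smallest rings (rings sharing >= 3
    atoms merged into bridged systems), every non-ring bond, and singleton
    clusters for atoms at the junction of >= 3 clusters.  Edges between
    intersecting clusters are weighted by shared-atom count (junction-atom
    edges are forced into the tree) and reduced to a maximum spanning tree.
    """
    mol = as_molecule(mol)
    graph = mol.require_valid()
    n = graph.GetNumAtoms()

    rings = [frozenset(r) for r in Chem.GetSymmSSSR(graph)]
    # merge rings sharing >= 3 atoms until fixpoint
    merged: list[tuple[frozenset[int], bool]] = [(r, False) for r in rings]
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                if len(merged[i][0] & merged[j][0]) >= 3:
                    fused = merged[i][0] | merged[j][0]
                    merged = [m for k, m in enumerate(merged) if k not in (i, j)]
                    merged.append((fused, True))
                    changed = True
                    break
            if changed:
                break

    clusters: list[Cluster] = [
        Cluster(atoms, "bridged-ring" if bridged else "ring")
        for atoms, bridged in merged
    ]
    for bond in graph.GetBonds():
        if not bond.IsInRing():
            clusters.append(Cluster(
                frozenset((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())), "bond"))
    if n == 1:
        clusters.append(Cluster(frozenset({0}), "atom"))

    # deterministic ordering of clusters by (min atom, size, label)
    clusters.sort(key=lambda c: (min(c.atoms), len(c.atoms), c.label))

    membership: dict[int, list[int]] = {}
    for ci, c in enumerate(clusters):
        for a in c.atoms:
            membership.setdefault(a, []).append(ci)

    # atoms shared by >= 3 clusters become their own junction clusters
    junction_atoms = [a for a, owners in sorted(membership.items()) if len(owners) >= 3]
    for a in junction_atoms:
        clusters.append(Cluster(frozenset({a}), "atom"))
        membership[a].append(len(clusters) - 1)

    edges: list[tuple[int, int, int]] = []
    seen = set()
    for _a, owners in sorted(membership.items()):
        for x in range(len(owners)):
            for y in range(x + 1, len(owners)):
                u, v = sorted((owners[x], owners[y]))
                if (u, v) in seen:
                    continue
                seen.add((u, v))
                shared = len(clusters[u].atoms & clusters[v].atoms)
                junction = clusters[u].label == "atom" or clusters[v].label == "atom"
                # junction-atom links dominate so the tree routes through them
                edges.append((u, v, 100 if junction else shared))

    tree_edges = _union_find_mst(len(clusters), edges)
    is_tree = len(tree_edges) == len(clusters) - 1
    return JunctionTree(smiles=mol.smiles, nodes=clusters,
                        edges=sorted(tree_edges), is_tree=is_tree)


@dataclass
class ClusterVocabulary:
    entries: dict[str, int]
    counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, smiles: str) -> bool:
        return smiles in self.entries


def build_cluster_vocabulary(mols: list[Molecule | str]) -> ClusterVocabulary:
    """Collate every junction-tree cluster of the input into a vocabulary.

    Ids are dense 0..N-1, ordered by (occurrence count desc, SMILES lex).
    """
    if not mols:
        raise ValueError("cannot build a cluster vocabulary from an empty dataset")
    counts: dict[str, int] = {}
    for m in mols:
        m = as_molecule(m)
        jt = tree_decompose(m)
        for smi in jt.cluster_smiles(m.require_valid()):
            counts[smi] = counts.get(smi, 0) + 1
    ordered = sorted(counts, key=lambda s: (-counts[s], s))
    return ClusterVocabulary(entries={s: i for i, s in enumerate(ordered)},
                             counts=counts)


# ---------------------------------------------------------------------------
# Dataset preprocessing
# ---------------------------------------------------------------------------


def preprocess_dataset(mols: list[Molecule | str]) -> list[Molecule]:
    """Deduplicate and keep only molecules that cleave into >= 2 fragments.

    Unparseable entries are dropped with a log line; first-occurrence order
    is preserved.  Idempotent.
    """
    seen: set[str] = set()
    kept: list[Molecule] = []
    n_invalid = n_dup = n_small = 0
    for m in mols:
        m = as_molecule(m)
        if not m.valid:
            n_invalid += 1
            logger.warning("dropping unparseable SMILES %r", m.smiles)
            continue
        if m.smiles in seen:
            n_dup += 1
            continue
        seen.add(m.smiles)
        if fragment_count(m) < 2:
            n_small += 1
            continue
        kept.append(m)
    if n_invalid or n_dup or n_small:
        logger.info("preprocess: dropped %d invalid, %d duplicate, %d single-fragment",
                    n_invalid, n_dup, n_small)
    return kept
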