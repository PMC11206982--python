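"""Typed-edge graphs for the structure modality.

Drugs become atom-level graphs with one relation per chemical bond order
(single / double / triple / aromatic); proteins become residue-level
relational graphs with seven edge types: sequential offsets -2, -1, +1,
+2 within a chain, radius edges, k-nearest-neighbor edges and self
loops.  Both are consumed by relational message-passing encoders.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from rdkit import Chem

from .protein_io import ResidueCloud

__all__ = [
    "BOND_RELATIONS", "PROTEIN_RELATIONS", "MoleculeGraph",
    "ProteinRelGraph", "smiles_to_graph", "build_protein_graph",
    "graph_to_json", "graph_from_json", "ATOM_FEATURE_DIM",
]

BOND_RELATIONS = ("single", "double", "triple", "aromatic")
_BOND_TO_REL = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}

PROTEIN_RELATIONS = ("seq-2", "seq-1", "seq+1", "seq+2", "radius", "knn", "self")

_ELEMENTS = ("C", "N", "O", "S", "F", "P", "Cl", "Br", "I")  # + "other" slot
_MAX_DEGREE = 6
#: element one-hot (+other), degree one-hot, formal charge, aromatic flag
ATOM_FEATURE_DIM = len(_ELEMENTS) + 1 + (_MAX_DEGREE + 1) + 2


@dataclass
class MoleculeGraph:
    """Heavy-atom molecular graph with bond-order edge relations."""

    node_feats: np.ndarray              # (a, f)
    edges: list[tuple[int, int, int]]   # directed (src, dst, relation)
    n_relations: int = len(BOND_RELATIONS)

    def __post_init__(self):
        self.node_feats = np.atleast_2d(np.asarray(self.node_feats, dtype=float))
        a = self.node_feats.shape[0]
        seen = set(self.edges)
        for (i, j, r) in self.edges:
            if not (0 <= i < a and 0 <= j < a):
                raise ValueError("edge index out of range")
            if not 0 <= r < self.n_relations:
                raise ValueError("bond relation out of range")
            if (j, i, r) not in seen:
                raise ValueError("molecular edges must be symmetric")

    @property
    def n_atoms(self) -> int:
        return self.node_feats.shape[0]


@dataclass
class ProteinRelGraph:
    """Residue-level graph with the 7 GearNet-style edge relations."""

    node_feats: np.ndarray              # (n, g)
    edges: list[tuple[int, int, int]]   # directed (src, dst, relation)
    coords: np.ndarray                  # (n, 3) Å
    n_relations: int = len(PROTEIN_RELATIONS)

    def __post_init__(self):
        self.node_feats = np.atleast_2d(np.asarray(self.node_feats, dtype=float))
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)

    @property
    def n_nodes(self) -> int:
        return self.node_feats.shape[0]


# ---------------------------------------------------------------------------
# Drug graphs
# ---------------------------------------------------------------------------

def _atom_features(atom: Chem.Atom) -> np.ndarray:
    f = np.zeros(ATOM_FEATURE_DIM)
    sym = atom.GetSymbol()
    f[_ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)] = 1.0
    deg = min(atom.GetDegree(), _MAX_DEGREE)
    f[len(_ELEMENTS) + 1 + deg] = 1.0
    f[-2] = float(atom.GetFormalCharge())
    f[-1] = float(atom.GetIsAromatic())
    return f


def smiles_to_graph(smiles: str) -> MoleculeGraph:
    """Heavy-atom graph from a SMILES string (hydrogens implicit).

    Node features: element one-hot (9 common + other), degree one-hot,
    formal charge, aromatic flag.  Each bond yields two directed edges
    with its bond-order relation.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    feats = np.array([_atom_features(a) for a in mol.GetAtoms()])
    edges = []
    for bond in mol.GetBonds():
        rel = _BOND_TO_REL.get(bond.GetBondType())
        if rel is None:
            raise ValueError(
                f"unsupported bond type {bond.GetBondType()} in {smiles!r}"
            )
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges += [(i, j, rel), (j, i, rel)]
    return MoleculeGraph(feats, edges)


# ---------------------------------------------------------------------------
# Protein graphs
# ---------------------------------------------------------------------------

def build_protein_graph(cloud: ResidueCloud, feats: np.ndarray | None = None,
                        radius_cut: float = 10.0, k: int = 10) -> ProteinRelGraph:
    """Residue relational graph with 7 edge types.

    Sequential edges connect residues at author-numbering offsets ±1, ±2
    within the same chain; radius edges connect CA pairs within
    ``radius_cut`` Å excluding pairs already sequential; knn edges run
    j→i for the k nearest neighbors j of every residue i; self loops are
    the 7th relation.  ``feats`` defaults to residue-type one-hot.
    """
    n = len(cloud)
    if n < 3:
        raise ValueError("protein graph needs at least 3 residues")
    if feats is None:
        feats = residue_onehot(cloud)
    feats = np.atleast_2d(np.asarray(feats, dtype=float))
    if feats.shape[0] != n:
        raise ValueError("node feature rows must equal residue count")

    edges: list[tuple[int, int, int]] = []
    key = {(c, int(s)): i
           for i, (c, s) in enumerate(zip(cloud.chain_ids, cloud.seq_index))}
    seq_pairs = set()
    offsets = {-2: 0, -1: 1, 1: 2, 2: 3}
    for i, (c, s) in enumerate(zip(cloud.chain_ids, cloud.seq_index)):
        for off, rel in offsets.items():
            j = key.get((c, int(s) + off))
            if j is not None:
                edges.append((j, i, rel))   # sender at offset `off` from i
                seq_pairs.add((j, i))

    tree = cKDTree(cloud.coords)
    for i, j in tree.query_pairs(radius_cut):
        for (a, b) in ((i, j), (j, i)):
            if (a, b) not in seq_pairs:
                edges.append((a, b, 4))

    kk = min(k, n - 1)
    _, nbrs = tree.query(cloud.coords, k=kk + 1)
    for i in range(n):
        taken = 0
        for j in nbrs[i]:           # self may be absent under ties
            if j != i and taken < kk:
                edges.append((int(j), i, 5))
                taken += 1

    edges += [(i, i, 6) for i in range(n)]
    return ProteinRelGraph(feats, edges, cloud.coords)


def residue_onehot(cloud: ResidueCloud) -> np.ndarray:
    from .geodesic import _AA_INDEX
    onehot = np.zeros((len(cloud), 20))
    for i, name in enumerate(cloud.residue_names):
        if name.upper() in _AA_INDEX:
            onehot[i, _AA_INDEX[name.upper()]] = 1.0
    return onehot


# ---------------------------------------------------------------------------
# Edge-list JSON serialization
# ---------------------------------------------------------------------------

def graph_to_json(graph: MoleculeGraph | ProteinRelGraph,
                  path: str | os.PathLike) -> None:
    payload = {
        "kind": type(graph).__name__,
        "node_feats": graph.node_feats.tolist(),
        "edges": [list(e) for e in graph.edges],
    }
    if isinstance(graph, ProteinRelGraph):
        payload["coords"] = graph.coords.tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def graph_from_json(path: str | os.PathLike):
    with open(path) as fh:
        payload = json.load(fh)
    edges = [tuple(e) for e in payload["edges"]]
    if payload["kind"] == "MoleculeGraph":
        return MoleculeGraph(np.array(payload["node_feats"]), edges)
    return ProteinRelGraph(np.array(payload["node_feats"]), edges,
                           np.array(payload["coords"]))
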