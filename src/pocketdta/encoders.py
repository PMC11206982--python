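"""Modality encoders and concatenation fusion for affinity prediction.

Five representations feed the predictor: drug sequence (pretrained
language-model embedding via a pluggable provider), drug structure
(relational message passing over the 4 bond types), protein sequence
(provider), protein structure (relational message passing over the 7
residue-graph relations, pooled over the predicted pocket), and protein
surface (pooled quasi-geodesic convolution features).  Fusion is plain
concatenation in that fixed order; any non-empty subset of modalities
can be ablated away.
"""

from __future__ import annotations

import hashlib
import os
import warnings
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, gather_rows, segment_sum
from .geodesic import PocketPrediction, SurfaceFeatures
from .graphs import MoleculeGraph, ProteinRelGraph
from .surface import SurfaceCloud

__all__ = [
    "MODALITIES", "EmbeddingProvider", "HashEmbeddingProvider",
    "TableEmbeddingProvider", "FusedRepresentation",
    "init_relational_params", "init_predictor_params",
    "encode_drug", "encode_protein", "pool_surface", "predict_affinity",
]

MODALITIES = ("drug_seq", "drug_str", "prot_seq", "prot_str", "prot_surf")


# ---------------------------------------------------------------------------
# Embedding providers (sequence modality)
# ---------------------------------------------------------------------------

class EmbeddingProvider:
    """Deterministic string -> fixed-width vector lookup.

    Real pretrained language-model vectors (e.g. ESM-style protein or
    chemistry transformers) are loaded with
    :class:`TableEmbeddingProvider`; tests and offline runs use the
    seeded :class:`HashEmbeddingProvider`.
    """

    name: str
    dim: int

    def embed(self, key: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class HashEmbeddingProvider(EmbeddingProvider):
    """Seeded random projection of character n-grams.

    Every n-gram of the key deterministically seeds a random direction;
    the embedding is the normalized sum.  Identical keys always map to
    identical vectors; distinct keys are almost surely non-collinear.
    """

    def __init__(self, name: str = "hash-stub", dim: int = 64,
                 seed: int = 0, ngram: int = 3):
        self.name, self.dim, self.seed, self.ngram = name, dim, seed, ngram
        self._cache: dict[str, np.ndarray] = {}

    def _ngram_vector(self, gram: str) -> np.ndarray:
        digest = hashlib.blake2b(
            f"{self.name}|{self.seed}|{gram}".encode(), digest_size=8
        ).digest()
        sub = int.from_bytes(digest, "little") % (2 ** 31)
        return np.random.default_rng(sub).normal(size=self.dim)

    def embed(self, key: str) -> np.ndarray:
        if key in self._cache:
            return self._cache[key]
        padded = f"^{key}$"
        grams = [padded[i:i + self.ngram]
                 for i in range(max(1, len(padded) - self.ngram + 1))]
        vec = np.sum([self._ngram_vector(g) for g in grams], axis=0)
        vec = vec / np.linalg.norm(vec)
        self._cache[key] = vec
        return vec


class TableEmbeddingProvider(EmbeddingProvider):
    """Embeddings from a TSV file: ``key \\t v1 \\t ... \\t vd``."""

    def __init__(self, path: str | os.PathLike, name: str = "table"):
        self.name = name
        self._table: dict[str, np.ndarray] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    continue
                self._table[parts[0]] = np.array([float(v) for v in parts[1:]])
        if not self._table:
            raise ValueError(f"no embeddings found in {path}")
        dims = {v.size for v in self._table.values()}
        if len(dims) != 1:
            raise ValueError("inconsistent embedding widths in table")
        self.dim = dims.pop()

    def embed(self, key: str) -> np.ndarray:
        try:
            return self._table[key]
        except KeyError:
            raise KeyError(f"no embedding stored for key {key!r}") from None


# ---------------------------------------------------------------------------
# Relational message passing (drug RGCN / protein structure encoder)
# ---------------------------------------------------------------------------

def init_relational_params(in_dim: int, hidden: int, n_layers: int,
                           n_relations: int, rng: np.random.Generator) -> dict:
    """Per-relation weights + self-transform + bias for each layer."""
    params: dict[str, Tensor] = {"_meta": Tensor([in_dim, hidden, n_layers,
                                                  n_relations])}
    for layer in range(n_layers):
        fin = in_dim if layer == 0 else hidden
        scale = 1.0 / np.sqrt(fin)
        for rel in range(n_relations):
            params[f"layer{layer}.rel{rel}.W"] = Tensor(
                rng.normal(0, scale, (fin, hidden)), requires_grad=True)
        params[f"layer{layer}.self.W"] = Tensor(
            rng.normal(0, scale, (fin, hidden)), requires_grad=True)
        params[f"layer{layer}.b"] = Tensor(np.zeros(hidden), requires_grad=True)
    return params


def _relational_forward(feats: Tensor, edges, n_nodes: int, n_relations: int,
                        params: dict) -> Tensor:
    """Stacked relational layers: h' = act(self(h) + sum_r sum_{j->i in r}
    W_r h_j + b); ReLU between layers, linear final layer."""
    n_layers = int(params["_meta"].data[2])
    by_rel: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for rel in range(n_relations):
        sel = [(s, d) for (s, d, r) in edges if r == rel]
        if sel:
            arr = np.array(sel, dtype=np.intp)
            by_rel[rel] = (arr[:, 0], arr[:, 1])
    h = feats
    for layer in range(n_layers):
        out = h @ params[f"layer{layer}.self.W"] + params[f"layer{layer}.b"]
        for rel, (src, dst) in by_rel.items():
            msg = gather_rows(h, src) @ params[f"layer{layer}.rel{rel}.W"]
            out = out + segment_sum(msg, dst, n_nodes)
        h = out.relu() if layer < n_layers - 1 else out
    return h


def encode_drug(graph: MoleculeGraph, params: dict) -> Tensor:
    """Drug vector: relational message passing over bond types, then
    mean pooling over atoms."""
    if graph.n_atoms == 0:
        raise ValueError("empty molecular graph")
    h = _relational_forward(Tensor(graph.node_feats), graph.edges,
                            graph.n_atoms, graph.n_relations, params)
    return h.mean(axis=0)


def encode_protein(graph: ProteinRelGraph, params: dict,
                   pocket_mask: np.ndarray | None = None) -> Tensor:
    """Protein structure vector: relational message passing over the 7
    residue relations, mean-pooled over the pocket subset when one is
    supplied (falls back to all residues, with a warning, if empty)."""
    if graph.n_nodes == 0:
        raise ValueError("empty protein graph")
    h = _relational_forward(Tensor(graph.node_feats), graph.edges,
                            graph.n_nodes, graph.n_relations, params)
    if pocket_mask is not None:
        pocket_mask = np.asarray(pocket_mask, dtype=bool)
        if not pocket_mask.any():
            warnings.warn("empty pocket subset; pooling over all residues",
                          stacklevel=2)
            pocket_mask = None
    if pocket_mask is None:
        return h.mean(axis=0)
    idx = np.flatnonzero(pocket_mask)
    return gather_rows(h, idx).mean(axis=0)


# ---------------------------------------------------------------------------
# Surface pooling
# ---------------------------------------------------------------------------

def pool_surface(surface: SurfaceCloud, feats: SurfaceFeatures | Tensor,
                 pocket: PocketPrediction, threshold: float = 0.5):
    """Mean surface feature over points owned by predicted-pocket residues.

    Points whose owner residue has probability >= ``threshold`` are
    averaged; with no qualifying point the mean runs over all points.
    """
    values = feats if isinstance(feats, Tensor) else Tensor(feats.values)
    if values.shape[0] != len(surface):
        raise ValueError("features are not aligned to the surface")
    probs = pocket.residue_probs[surface.owner_residue]
    mask = probs >= threshold
    if not mask.any():
        return values.mean(axis=0)
    return gather_rows(values, np.flatnonzero(mask)).mean(axis=0)


# ---------------------------------------------------------------------------
# Fusion + predictor
# ---------------------------------------------------------------------------

@dataclass
class FusedRepresentation:
    """Named modality vectors fused by concatenation in fixed order."""

    drug_seq: Tensor | None = None
    drug_str: Tensor | None = None
    prot_seq: Tensor | None = None
    prot_str: Tensor | None = None
    prot_surf: Tensor | None = None

    def components(self) -> list[tuple[str, Tensor]]:
        out = [(m, getattr(self, m)) for m in MODALITIES
               if getattr(self, m) is not None]
        if not out:
            raise ValueError("at least one modality must be present")
        return out

    @property
    def fused(self) -> Tensor:
        return concat([t for _, t in self.components()], axis=0)

    @property
    def width(self) -> int:
        return sum(t.shape[0] for _, t in self.components())


def init_predictor_params(in_dim: int, hidden: tuple[int, int, int],
                          rng: np.random.Generator) -> dict:
    """Feed-forward affinity head: 3 hidden layers + scalar output."""
    params: dict[str, Tensor] = {}
    dims = [in_dim, *hidden, 1]
    for layer, (fin, fout) in enumerate(zip(dims[:-1], dims[1:])):
        params[f"fc{layer}.W"] = Tensor(
            rng.normal(0, 1.0 / np.sqrt(fin), (fin, fout)), requires_grad=True)
        params[f"fc{layer}.b"] = Tensor(np.zeros(fout), requires_grad=True)
    return params


def predict_affinity(fused: FusedRepresentation, params: dict,
                     activation: str = "relu") -> Tensor:
    """Scalar affinity on the dataset's native scale (pKd etc.)."""
    x = fused.fused.reshape(1, -1)
    if x.shape[1] != params["fc0.W"].shape[0]:
        raise ValueError(
            f"fused width {x.shape[1]} does not match predictor input "
            f"{params['fc0.W'].shape[0]}"
        )
    n_layers = len([k for k in params if k.endswith(".W")])
    for layer in range(n_layers):
        x = x @ params[f"fc{layer}.W"] + params[f"fc{layer}.b"]
        if layer < n_layers - 1 and activation == "relu":
            x = x.relu()
    return x.reshape(())
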