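"""Quasi-geodesic convolution on surface point clouds and pocket detection.

Surface distance between two sampled points is approximated without a
mesh by scaling the Euclidean distance with the normal alignment,

    d_ij = ||x_i - x_j|| * (2 - <n_i, n_j>),

which penalises pairs whose normals disagree (points on opposite sides
of a thin region are "far" along the surface even when close in space).
Features propagate through convolution blocks

    f_i' = sum_j w(d_ij) * MLP(p_ij) (.) f_j ,

with a Gaussian window w and a learned function of the local tangent
coordinates p_ij, applied (by default) as an element-wise gate on f_j.
A stack of such blocks followed by a linear head and owner-residue mean
pooling yields per-residue pocket probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._autodiff import Tensor, concat, gather_rows, segment_sum
from .protein_io import RESIDUE_RADII, PocketLabels, ResidueCloud
from .surface import SurfaceCloud

__all__ = [
    "ConvConfig", "SurfaceFeatures", "PocketPrediction", "PodGeometry",
    "quasi_geodesic_distance", "local_frame_features", "conv_block",
    "surface_conv_geometry", "init_pod_params", "pod_forward",
    "detect_pockets", "bce_loss", "count_parameters",
]

_AA_ORDER = sorted(RESIDUE_RADII)
_AA_INDEX = {aa: i for i, aa in enumerate(_AA_ORDER)}
_CLIP = 1e-7


@dataclass
class ConvConfig:
    """Hyperparameters of the quasi-geodesic convolution stack."""

    n_blocks: int = 3
    hidden_dim: int = 16
    window_sigma: float = 6.0      # Å, Gaussian window bandwidth
    neighbor_cutoff: float = 12.0  # Å, quasi-geodesic neighborhood radius
    mlp_action: str = "gate"       # "gate" (elementwise) or "scalar"
    mlp_layers: int = 3            # fixed depth of the pair MLP

    def __post_init__(self):
        if self.window_sigma <= 0:
            raise ValueError("window_sigma must be positive")
        if self.neighbor_cutoff < self.window_sigma:
            raise ValueError("neighbor_cutoff must be >= window_sigma")
        if self.mlp_action not in ("gate", "scalar"):
            raise ValueError(f"unknown mlp_action {self.mlp_action!r}")


@dataclass
class SurfaceFeatures:
    """N×d feature matrix aligned to a :class:`SurfaceCloud`."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ValueError("surface features must be finite")

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class PocketPrediction:
    """Per-residue pocket probabilities and the raw per-point logits."""

    residue_probs: np.ndarray  # (n,), in [0, 1]; buried residues get 0
    point_logits: np.ndarray   # (N,)

    def __post_init__(self):
        self.residue_probs = np.asarray(self.residue_probs, dtype=float).ravel()
        self.point_logits = np.asarray(self.point_logits, dtype=float).ravel()
        if ((self.residue_probs < 0) | (self.residue_probs > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def _check_unit(*normals):
    for n in normals:
        n = np.asarray(n, dtype=float)
        if np.max(np.abs(np.linalg.norm(np.atleast_2d(n), axis=-1) - 1.0)) > 1e-4:
            raise ValueError("normals must be unit length (normalize first)")


def quasi_geodesic_distance(xi, xj, ni, nj) -> float:
    """Euclidean distance scaled by (2 - <n_i, n_j>); in [d, 3d]."""
    _check_unit(ni, nj)
    xi, xj = np.asarray(xi, float), np.asarray(xj, float)
    ni, nj = np.asarray(ni, float), np.asarray(nj, float)
    return float(np.linalg.norm(xi - xj) * (2.0 - ni @ nj))


def local_frame_features(xi, xj, ni, nj) -> np.ndarray:
    """Relative position of x_j in the tangent frame at x_i, plus <n_i,n_j>.

    The first tangent axis is the Gram–Schmidt projection of the
    displacement against n_i (canonical and rotation invariant); when the
    tangential displacement vanishes, the least-aligned coordinate axis
    is used instead (the tangential components are ~0 there for any
    choice of frame).  Returns (t1, t2, normal component, <n_i, n_j>).
    """
    _check_unit(ni, nj)
    xi, xj = np.asarray(xi, float), np.asarray(xj, float)
    ni, nj = np.asarray(ni, float), np.asarray(nj, float)
    delta = xj - xi
    normal_comp = delta @ ni
    tangential = delta - normal_comp * ni
    tnorm = np.linalg.norm(tangential)
    if tnorm > 1e-9:
        t1 = tangential / tnorm
    else:
        axis = np.zeros(3)
        axis[np.argmin(np.abs(ni))] = 1.0
        t1 = axis - (axis @ ni) * ni
        t1 /= np.linalg.norm(t1)
    t2 = np.cross(ni, t1)
    return np.array([delta @ t1, delta @ t2, normal_comp, ni @ nj])


def _pair_features(points: np.ndarray, normals: np.ndarray,
                   i_idx: np.ndarray, j_idx: np.ndarray):
    """Vectorized d_ij and p_ij over an explicit pair list."""
    xi, xj = points[i_idx], points[j_idx]
    ni, nj = normals[i_idx], normals[j_idx]
    delta = xj - xi
    eucl = np.linalg.norm(delta, axis=1)
    ndot = np.einsum("ij,ij->i", ni, nj)
    d = eucl * (2.0 - ndot)
    normal_comp = np.einsum("ij,ij->i", delta, ni)
    tangential = delta - normal_comp[:, None] * ni
    tnorm = np.linalg.norm(tangential, axis=1)
    # frame axis 1: tangential displacement; degenerate pairs contribute ~0
    safe = np.maximum(tnorm, 1e-12)
    t1 = tangential / safe[:, None]
    t2 = np.cross(ni, t1)
    p = np.stack([np.einsum("ij,ij->i", delta, t1),
                  np.einsum("ij,ij->i", delta, t2),
                  normal_comp, ndot], axis=1)
    p[tnorm <= 1e-9, 0:2] = 0.0
    return d, p


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

@dataclass
class PodGeometry:
    """Precomputed, parameter-free geometry of one surface (reusable
    across convolution blocks and training steps)."""

    pair_i: np.ndarray     # (E,) receiver indices
    pair_j: np.ndarray     # (E,) sender indices (self pairs included)
    window: np.ndarray     # (E,) Gaussian window weights w(d_ij)
    frames: np.ndarray     # (E, 4) local frame features p_ij
    onehot: np.ndarray     # (N, 20) owner-residue type one-hot
    sdf: np.ndarray        # (N,)
    curvature: np.ndarray  # (N,) mean <n_i, n_j> over the neighborhood
    owner: np.ndarray      # (N,) owner residue index
    n_residues: int
    window_sum: np.ndarray = None  # (N,) sum of w over each neighborhood


def _surface_pairs(points: np.ndarray, normals: np.ndarray,
                   config: ConvConfig):
    """Pair list within the quasi-geodesic cutoff (self pairs included).

    Since d_ij >= Euclidean distance, candidates are gathered with a
    KD-tree at the Euclidean cutoff and then filtered on d_ij.
    """
    n_pts = points.shape[0]
    tree = cKDTree(points)
    pairs = tree.query_pairs(config.neighbor_cutoff, output_type="ndarray")
    if pairs.size:
        i_idx = np.concatenate([pairs[:, 0], pairs[:, 1], np.arange(n_pts)])
        j_idx = np.concatenate([pairs[:, 1], pairs[:, 0], np.arange(n_pts)])
    else:
        i_idx = j_idx = np.arange(n_pts)
    d, p = _pair_features(points, normals, i_idx, j_idx)
    keep = d <= config.neighbor_cutoff
    i_idx, j_idx, d, p = i_idx[keep], j_idx[keep], d[keep], p[keep]
    order = np.lexsort((j_idx, i_idx))
    i_idx, j_idx, d, p = i_idx[order], j_idx[order], d[order], p[order]
    w = np.exp(-d ** 2 / (2.0 * config.window_sigma ** 2))
    return i_idx, j_idx, w, p


def surface_conv_geometry(surface: SurfaceCloud, cloud: ResidueCloud,
                          config: ConvConfig) -> PodGeometry:
    """Neighbor pairs within the quasi-geodesic cutoff + per-point inputs."""
    n_pts = len(surface)
    i_idx, j_idx, w, p = _surface_pairs(surface.points, surface.normals, config)

    counts = np.bincount(i_idx, minlength=n_pts).astype(float)
    curv = np.bincount(i_idx, weights=p[:, 3], minlength=n_pts) / np.maximum(counts, 1)

    onehot = np.zeros((n_pts, 20))
    for row, res_idx in enumerate(surface.owner_residue):
        aa = cloud.residue_names[res_idx].upper()
        if aa in _AA_INDEX:
            onehot[row, _AA_INDEX[aa]] = 1.0
    wsum = np.bincount(i_idx, weights=w, minlength=n_pts)
    return PodGeometry(i_idx, j_idx, w, p, onehot, surface.sdf_values,
                       curv, surface.owner_residue, len(cloud),
                       np.maximum(wsum, 1e-12))


def _pair_mlp(p: Tensor, params: dict, prefix: str) -> Tensor:
    h = (p @ params[f"{prefix}.W1"] + params[f"{prefix}.b1"]).relu()
    h = (h @ params[f"{prefix}.W2"] + params[f"{prefix}.b2"]).relu()
    return h @ params[f"{prefix}.W3"] + params[f"{prefix}.b3"]


def _conv_aggregate(geom: PodGeometry, feats: Tensor, params: dict,
                    prefix: str, n_points: int) -> Tensor:
    """Window-normalized convolution used inside the detector stack.

    The raw sum of Formula-style messages grows with the neighborhood
    size; dividing by sum_j w(d_ij) keeps activations O(1) across blocks
    without changing the one-block operation up to a fixed per-point
    scale."""
    gate = _pair_mlp(Tensor(geom.frames), params, prefix)
    sent = gather_rows(feats, geom.pair_j)
    msg = Tensor(geom.window[:, None]) * (gate * sent)
    agg = segment_sum(msg, geom.pair_i, n_points)
    return agg * Tensor(1.0 / geom.window_sum[:, None])


def conv_block(cloud: SurfaceCloud, feats: SurfaceFeatures, params: dict,
               config: ConvConfig) -> SurfaceFeatures:
    """One quasi-geodesic convolution: f_i' = sum_j w(d_ij) MLP(p_ij) (.) f_j.

    ``params`` holds the pair-MLP weights W1..b3 (keys without prefix).
    Width is preserved in "gate" mode; "scalar" mode broadcasts a single
    learned weight per pair.
    """
    if feats.values.shape[0] != len(cloud):
        raise ValueError("features are not aligned to the surface cloud")
    exp_width = feats.d if config.mlp_action == "gate" else 1
    w3 = params["W3"].data if isinstance(params["W3"], Tensor) else params["W3"]
    if w3.shape[1] != exp_width:
        raise ValueError(
            f"pair-MLP output width {w3.shape[1]} does not match "
            f"feature width {exp_width}"
        )
    n_pts = len(cloud)
    i_idx, j_idx, w, p = _surface_pairs(cloud.points, cloud.normals, config)
    pparams = {f"x.{k}": v if isinstance(v, Tensor) else Tensor(v)
               for k, v in params.items()}
    gate = _pair_mlp(Tensor(p), pparams, "x").data
    msg = w[:, None] * gate * feats.values[j_idx]
    out = np.zeros((n_pts, feats.d))
    np.add.at(out, i_idx, msg)
    return SurfaceFeatures(out)


# ---------------------------------------------------------------------------
# Pocket detection network
# ---------------------------------------------------------------------------

def init_pod_params(config: ConvConfig, rng: np.random.Generator) -> dict:
    """Seeded parameter dict for the pocket-detection network.

    Keys: ``proj.*`` (residue one-hot projection), ``in.*`` (input mix of
    projected one-hot + SDF + curvature), ``blockL.*`` (pair MLPs),
    ``postL.*`` (inter-block linear), ``head.*`` (point logit head).
    The head is the only part updated in fine-tune multi-task mode.
    """
    h = config.hidden_dim

    def lin(fin, fout):
        return (Tensor(rng.normal(0, 1 / np.sqrt(fin), (fin, fout)),
                       requires_grad=True),
                Tensor(np.zeros(fout), requires_grad=True))

    params: dict[str, Tensor] = {}
    params["proj.W"], params["proj.b"] = lin(20, h)
    params["in.W"], params["in.b"] = lin(h + 2, h)
    gate_width = h if config.mlp_action == "gate" else 1
    for layer in range(config.n_blocks):
        params[f"block{layer}.W1"], params[f"block{layer}.b1"] = lin(4, h)
        params[f"block{layer}.W2"], params[f"block{layer}.b2"] = lin(h, h)
        params[f"block{layer}.W3"], params[f"block{layer}.b3"] = lin(h, gate_width)
        params[f"post{layer}.W"], params[f"post{layer}.b"] = lin(h, h)
    params["head.W"], params["head.b"] = lin(h, 1)
    return params


def pod_backbone_keys(config: ConvConfig) -> list[str]:
    return [k for k in init_pod_params(config, np.random.default_rng(0))
            if not k.startswith("head.")]


def count_parameters(params: dict) -> int:
    return int(sum(np.asarray(t.data).size for t in params.values()))


def pod_forward(geom: PodGeometry, params: dict, config: ConvConfig):
    """Differentiable pocket-detector forward pass.

    Returns (point_features, point_logits, owning_residues, residue_probs)
    where ``residue_probs`` is a Tensor over the owning residues only
    (buried residues are non-pocket by construction).
    """
    n_pts = geom.onehot.shape[0]
    x = Tensor(geom.onehot) @ params["proj.W"] + params["proj.b"]
    x = concat([x, Tensor(geom.sdf[:, None]), Tensor(geom.curvature[:, None])],
               axis=1)
    x = (x @ params["in.W"] + params["in.b"]).relu()
    for layer in range(config.n_blocks):
        agg = _conv_aggregate(geom, x, params, f"block{layer}", n_pts)
        x = (agg @ params[f"post{layer}.W"] + params[f"post{layer}.b"]).relu()
    logits = (x @ params["head.W"] + params["head.b"]).reshape(n_pts)

    owning = np.unique(geom.owner)
    compact = np.searchsorted(owning, geom.owner)
    counts = np.bincount(compact).astype(float)
    residue_logits = segment_sum(logits.reshape(n_pts, 1), compact,
                                 owning.size).reshape(owning.size) \
        * Tensor(1.0 / counts)
    residue_probs = residue_logits.sigmoid()
    return x, logits, owning, residue_probs


def detect_pockets(cloud: ResidueCloud, surface: SurfaceCloud, params: dict,
                   config: ConvConfig) -> PocketPrediction:
    """Classify every residue as pocket/non-pocket from its surface points.

    Point logits are mean-pooled over owner-residue groups and squashed
    with a sigmoid; residues owning no surface point are treated as
    buried and receive probability 0.
    """
    if surface.owner_residue.max(initial=-1) >= len(cloud):
        raise ValueError("surface does not belong to this residue cloud")
    geom = surface_conv_geometry(surface, cloud, config)
    _, logits, owning, probs = pod_forward(geom, params, config)
    residue_probs = np.zeros(len(cloud))
    residue_probs[owning] = probs.data
    return PocketPrediction(residue_probs, logits.data)


# ---------------------------------------------------------------------------
# Binary cross-entropy
# ---------------------------------------------------------------------------

def bce_loss(labels: PocketLabels | np.ndarray, probs: np.ndarray) -> float:
    """Mean binary cross-entropy over residues, probs clipped to
    [1e-7, 1 - 1e-7]."""
    y = labels.labels if isinstance(labels, PocketLabels) else np.asarray(labels)
    p = np.clip(np.asarray(probs, dtype=float), _CLIP, 1.0 - _CLIP)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def bce_loss_t(y: np.ndarray, probs: Tensor) -> Tensor:
    """Tensor-valued BCE used inside the training loop."""
    if y.shape[0] != probs.shape[0]:
        raise ValueError("labels and probabilities differ in length")
    p = probs.clip(_CLIP, 1.0 - _CLIP)
    yv = Tensor(np.asarray(y, dtype=float))
    return -(yv * p.log() + (1.0 - yv) * (1.0 - p).log()).mean()
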