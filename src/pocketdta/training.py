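"""Joint pocket-classification + affinity-regression training.

The full model couples the surface-based pocket detector with the
multimodal affinity predictor and optimizes

    L_all = L_mse + beta * L_bce        (beta = 0.5)

over drug-target pairs.  Two regimes are supported: ``normal`` training
updates everything end-to-end; ``fine_tune`` freezes the surface/conv
backbone (assumed pretrained, e.g. with :func:`pretrain_pod`) and
updates only the encoders, the predictor, and — in multi-task mode —
the pocket head.  Evaluation uses the standard affinity-regression and
pocket-classification metric suite (RMSE, MSE, MAE, CI, Spearman,
Pearson, r_m^2, AUROC, AUPRC).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from ._autodiff import AdamW, Tensor
from .encoders import (MODALITIES, EmbeddingProvider, FusedRepresentation,
                       HashEmbeddingProvider, encode_drug, encode_protein,
                       init_predictor_params, init_relational_params,
                       pool_surface, predict_affinity)
from .geodesic import (ConvConfig, PocketPrediction, _CLIP, init_pod_params,
                       pod_forward, surface_conv_geometry)
from .graphs import (ATOM_FEATURE_DIM, build_protein_graph, residue_onehot,
                     smiles_to_graph)
from .protein_io import PocketLabels, ResidueCloud
from .surface import SamplerConfig, sample_surface

__all__ = [
    "PairRecord", "JointLossReport", "MetricsReport", "TrainConfig",
    "JointModel", "mse_loss", "joint_loss", "concordance_index",
    "rm2_metric", "auroc_score", "auprc_score", "classification_metrics",
    "metrics_report",
    "train", "pretrain_pod", "evaluate", "save_checkpoint", "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Records and reports
# ---------------------------------------------------------------------------

@dataclass
class PairRecord:
    """One drug-target pair: SMILES, protein identifier, affinity, split."""

    drug: str
    protein: str
    affinity: float
    split: str = "train"

    def __post_init__(self):
        if not np.isfinite(self.affinity):
            raise ValueError("affinity must be finite")
        if self.split not in ("train", "valid", "test"):
            raise ValueError(f"unknown split {self.split!r}")


@dataclass
class JointLossReport:
    """MSE, BCE and combined loss of one training step."""

    mse: float
    bce: float
    beta: float
    total: float = field(init=False)

    def __post_init__(self):
        if self.mse < 0 or self.bce < 0:
            raise ValueError("loss components must be non-negative")
        self.total = self.mse + self.beta * self.bce


@dataclass
class MetricsReport:
    rmse: float
    mse: float
    mae: float
    ci: float
    spearman: float
    pearson: float
    rm2: float
    auroc: float = float("nan")
    auprc: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def mse_loss(pred, truth) -> float:
    pred, truth = np.asarray(pred, float).ravel(), np.asarray(truth, float).ravel()
    if pred.size != truth.size:
        raise ValueError("prediction/truth length mismatch")
    if pred.size == 0:
        raise ValueError("mse undefined for empty input")
    return float(np.mean((pred - truth) ** 2))


def joint_loss(mse: float, bce: float, beta: float = 0.5) -> JointLossReport:
    """Combined objective L_all = L_mse + beta * L_bce."""
    return JointLossReport(mse=float(mse), bce=float(bce), beta=float(beta))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def concordance_index(pred, truth) -> float:
    """Fraction of comparable pairs ranked concordantly (pred ties = 1/2)."""
    pred, truth = np.asarray(pred, float).ravel(), np.asarray(truth, float).ravel()
    if pred.size < 2:
        raise ValueError("concordance index needs at least 2 samples")
    dt = truth[:, None] - truth[None, :]
    dp = pred[:, None] - pred[None, :]
    comparable = dt > 0                       # each unordered pair counted once
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("concordance index undefined: all truths equal")
    concordant = (dp[comparable] > 0).sum() + 0.5 * (dp[comparable] == 0).sum()
    return float(concordant / n_comp)


def rm2_metric(pred, truth) -> float:
    """External-validation metric r_m^2 = r^2 * (1 - sqrt(|r^2 - r0^2|)).

    ``r^2`` is the squared Pearson correlation and ``r0^2`` its
    through-origin counterpart (regression of truth on prediction with
    zero intercept), following the DTA-literature convention; clipped to
    [0, 1].
    """
    x = np.asarray(pred, float).ravel()    # predictions
    y = np.asarray(truth, float).ravel()   # observations
    if x.size < 3:
        raise ValueError("r_m^2 needs at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("r_m^2 undefined for constant inputs")
    r2 = stats.pearsonr(x, y)[0] ** 2
    k = float(x @ y) / float(x @ x)
    ss_res0 = float(np.sum((y - k * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r02 = 1.0 - ss_res0 / ss_tot
    return float(np.clip(r2 * (1.0 - np.sqrt(abs(r2 - r02))), 0.0, 1.0))


def auroc_score(labels, probs) -> float:
    """AUROC as the Mann–Whitney rank statistic; errors on single-class."""
    labels = np.asarray(labels).ravel()
    if np.unique(labels).size < 2:
        raise ValueError("AUROC undefined with a single class present")
    return float(roc_auc_score(labels, np.asarray(probs, float).ravel()))


def auprc_score(labels, probs) -> float:
    """Step-interpolated area under the precision–recall curve.

    Single-class labels fall back to the prevalence baseline, with a
    warning.
    """
    labels = np.asarray(labels).ravel()
    if np.unique(labels).size < 2:
        warnings.warn("single-class labels: auprc = prevalence baseline",
                      stacklevel=2)
        return float(labels.mean())
    return float(average_precision_score(labels, np.asarray(probs, float).ravel()))


def classification_metrics(labels, probs) -> tuple[float, float]:
    """(AUROC, AUPRC) for pocket classification."""
    return auroc_score(labels, probs), auprc_score(labels, probs)


def metrics_report(pred, truth, pocket_labels=None,
                   pocket_probs=None) -> MetricsReport:
    """Full affinity metric suite, plus pocket AUROC/AUPRC if labels given."""
    pred, truth = np.asarray(pred, float).ravel(), np.asarray(truth, float).ravel()
    mse = mse_loss(pred, truth)
    sp = stats.spearmanr(pred, truth)[0] if np.ptp(pred) > 0 else 0.0
    pr = stats.pearsonr(pred, truth)[0] if np.ptp(pred) > 0 else 0.0
    try:
        rm2 = rm2_metric(pred, truth)
    except ValueError:
        rm2 = float("nan")
    try:
        ci = concordance_index(pred, truth)
    except ValueError:
        ci = float("nan")
    auroc = auprc = float("nan")
    if pocket_labels is not None and pocket_probs is not None:
        try:
            auroc, auprc = classification_metrics(pocket_labels, pocket_probs)
        except ValueError:
            pass
    return MetricsReport(rmse=float(np.sqrt(mse)), mse=mse,
                         mae=float(np.mean(np.abs(pred - truth))),
                         ci=ci, spearman=float(sp), pearson=float(pr),
                         rm2=rm2, auroc=auroc, auprc=auprc)


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyperparameters of the joint training loop."""

    lr: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 32
    epochs: int = 30
    beta: float = 0.5
    patience: int = 10              # early stopping on validation L_all
    encoder_hidden: int = 128       # RGCN / protein-encoder width
    encoder_layers: int = 2
    predictor_hidden: tuple = (128, 64, 32)
    provider_dim: int = 64
    pocket_threshold: float = 0.5
    radius_cut: float = 10.0
    knn_k: int = 10
    modalities: tuple = MODALITIES
    conv: ConvConfig = field(default_factory=ConvConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)


@dataclass
class _ProteinBundle:
    """Per-protein precomputed inputs shared across pairs and epochs."""

    cloud: ResidueCloud
    labels: np.ndarray | None
    surface: object
    geom: object
    graph: object
    seq_vec: np.ndarray
    frozen_feats: np.ndarray | None = None  # backbone output cache (fine-tune)


@dataclass
class _DrugBundle:
    graph: object
    seq_vec: np.ndarray


class JointModel:
    """Pocket detector + multimodal encoders + affinity predictor."""

    def __init__(self, config: TrainConfig, seed: int = 0,
                 drug_provider: EmbeddingProvider | None = None,
                 prot_provider: EmbeddingProvider | None = None):
        self.config = config
        rng = np.random.default_rng(seed)
        self.drug_provider = drug_provider or HashEmbeddingProvider(
            "molformer-stub", config.provider_dim, seed=seed)
        self.prot_provider = prot_provider or HashEmbeddingProvider(
            "esm-stub", config.provider_dim, seed=seed + 1)
        cc = config.conv
        self.params = {
            "pod": init_pod_params(cc, rng),
            "drug": init_relational_params(ATOM_FEATURE_DIM,
                                           config.encoder_hidden,
                                           config.encoder_layers, 4, rng),
            "prot": init_relational_params(20, config.encoder_hidden,
                                           config.encoder_layers, 7, rng),
            "pred": init_predictor_params(self._fused_width(),
                                          tuple(config.predictor_hidden), rng),
        }

    def _fused_width(self) -> int:
        c = self.config
        widths = {"drug_seq": c.provider_dim, "drug_str": c.encoder_hidden,
                  "prot_seq": c.provider_dim, "prot_str": c.encoder_hidden,
                  "prot_surf": c.conv.hidden_dim}
        return sum(widths[m] for m in c.modalities)

    # -- bundles ---------------------------------------------------------
    def prepare_protein(self, cloud: ResidueCloud,
                        labels: PocketLabels | np.ndarray | None,
                        seed: int = 0) -> _ProteinBundle:
        surface = sample_surface(cloud, self.config.sampler, seed=seed)
        geom = surface_conv_geometry(surface, cloud, self.config.conv)
        graph = build_protein_graph(cloud, residue_onehot(cloud),
                                    self.config.radius_cut, self.config.knn_k)
        y = None
        if labels is not None:
            y = labels.labels if isinstance(labels, PocketLabels) else np.asarray(labels)
        return _ProteinBundle(cloud, y, surface, geom, graph,
                              self.prot_provider.embed(cloud.sequence_key()))

    def prepare_drug(self, smiles: str) -> _DrugBundle:
        return _DrugBundle(smiles_to_graph(smiles),
                           self.drug_provider.embed(smiles))

    # -- forward ---------------------------------------------------------
    def _pod_head(self, geom, point_feats: Tensor):
        from ._autodiff import segment_sum
        n_pts = geom.onehot.shape[0]
        logits = (point_feats @ self.params["pod"]["head.W"]
                  + self.params["pod"]["head.b"]).reshape(n_pts)
        owning = np.unique(geom.owner)
        compact = np.searchsorted(owning, geom.owner)
        counts = np.bincount(compact).astype(float)
        res_logits = segment_sum(logits.reshape(n_pts, 1), compact,
                                 owning.size).reshape(owning.size) \
            * Tensor(1.0 / counts)
        return logits, owning, res_logits.sigmoid()

    def protein_forward(self, bundle: _ProteinBundle, frozen: bool = False):
        """POD + protein-side modality tensors for one protein."""
        cc = self.config.conv
        if frozen and bundle.frozen_feats is not None:
            feats = Tensor(bundle.frozen_feats)
            _, owning, probs = self._pod_head(bundle.geom, feats)
        else:
            feats, _, owning, probs = pod_forward(bundle.geom,
                                                  self.params["pod"], cc)
        full_probs = np.zeros(len(bundle.cloud))
        full_probs[owning] = probs.data
        prediction = PocketPrediction(full_probs, np.zeros(len(bundle.surface)))
        mask = full_probs >= self.config.pocket_threshold
        out = {"point_feats": feats, "owning": owning, "probs": probs,
               "full_probs": full_probs, "mask": mask}
        if "prot_str" in self.config.modalities:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out["prot_str"] = encode_protein(bundle.graph,
                                                 self.params["prot"],
                                                 mask if mask.any() else None)
        if "prot_surf" in self.config.modalities:
            out["prot_surf"] = pool_surface(bundle.surface, feats, prediction,
                                            self.config.pocket_threshold)
        if "prot_seq" in self.config.modalities:
            out["prot_seq"] = Tensor(bundle.seq_vec)
        return out

    def pair_forward(self, prot_out: dict, dbundle: _DrugBundle) -> Tensor:
        mods = self.config.modalities
        rep = FusedRepresentation(
            drug_seq=Tensor(dbundle.seq_vec) if "drug_seq" in mods else None,
            drug_str=encode_drug(dbundle.graph, self.params["drug"])
            if "drug_str" in mods else None,
            prot_seq=prot_out.get("prot_seq"),
            prot_str=prot_out.get("prot_str"),
            prot_surf=prot_out.get("prot_surf"),
        )
        return predict_affinity(rep, self.params["pred"])

    def bce_full(self, bundle: _ProteinBundle, owning: np.ndarray,
                 probs: Tensor) -> Tensor:
        """Mean BCE over all residues; buried residues (prob 0, clipped)
        contribute a constant."""
        y = bundle.labels
        n = len(bundle.cloud)
        own_y = Tensor(y[owning].astype(float))
        p = probs.clip(_CLIP, 1.0 - _CLIP)
        own_term = -(own_y * p.log() + (1.0 - own_y) * (1.0 - p).log()).sum()
        buried = np.setdiff1d(np.arange(n), owning)
        yb = y[buried]
        const = -(yb * np.log(_CLIP) + (1 - yb) * np.log(1 - _CLIP)).sum()
        return (own_term + float(const)) * (1.0 / n)

    # -- parameter bookkeeping ------------------------------------------
    def trainable(self, mode: str, task: str):
        sel = []
        for group, params in self.params.items():
            for key, t in params.items():
                if not t.requires_grad:
                    continue
                if group == "pod" and mode == "fine_tune":
                    if key.startswith("head.") and task == "multi":
                        sel.append(t)
                    continue
                sel.append(t)
        return sel

    def state_dict(self) -> dict:
        return {f"{g}/{k}": t.data.copy() for g, d in self.params.items()
                for k, t in d.items()}

    def load_state_dict(self, state: dict):
        for g, d in self.params.items():
            for k, t in d.items():
                t.data = state[f"{g}/{k}"].copy()

    def cache_backbone(self, bundles: dict):
        """Precompute frozen backbone point features (fine-tune speedup)."""
        for b in bundles.values():
            feats, _, _, _ = pod_forward(b.geom, self.params["pod"],
                                         self.config.conv)
            b.frozen_feats = feats.data


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def pretrain_pod(proteins: dict, config: TrainConfig, epochs: int = 60,
                 lr: float = 1e-2, seed: int = 0,
                 init: dict | None = None) -> dict:
    """Train the pocket detector alone with BCE (backbone pretraining).

    ``proteins`` maps id -> (ResidueCloud, PocketLabels).  Returns the
    trained POD parameter dict.
    """
    rng = np.random.default_rng(seed)
    params = init if init is not None else init_pod_params(config.conv, rng)
    model = JointModel.__new__(JointModel)       # lightweight: POD only
    model.config = config
    model.params = {"pod": params}
    bundles = {}
    for i, (pid, (cloud, labels)) in enumerate(sorted(proteins.items())):
        y = labels.labels if isinstance(labels, PocketLabels) else np.asarray(labels)
        surface = sample_surface(cloud, config.sampler, seed=seed + i)
        geom = surface_conv_geometry(surface, cloud, config.conv)
        bundles[pid] = _ProteinBundle(cloud, y, surface, geom, None,
                                      np.zeros(1))
    opt = AdamW([t for t in params.values() if t.requires_grad],
                lr=lr, weight_decay=0.0)
    for _ in range(epochs):
        opt.zero_grad()
        losses = []
        for pid in sorted(bundles):
            b = bundles[pid]
            _, _, owning, probs = pod_forward(b.geom, params, config.conv)
            losses.append(model.bce_full(b, owning, probs))
        total = losses[0]
        for ls in losses[1:]:
            total = total + ls
        total = total * (1.0 / len(losses))
        total.backward()
        opt.step()
    return params


def train(dataset: list, proteins: dict, mode: str = "fine_tune",
          task: str = "multi", config: TrainConfig | None = None,
          seed: int = 0, init_pod: dict | None = None):
    """Joint (or affinity-only) training over drug-target pair records.

    ``proteins`` maps protein id -> (ResidueCloud, PocketLabels or None).
    ``mode``: "fine_tune" freezes the surface/conv backbone (use
    ``init_pod`` to supply pretrained POD parameters); "normal" trains
    end-to-end.  ``task``: "single" optimizes L_mse only; "multi"
    optimizes L_mse + beta * L_bce.  Returns (model, history) where
    history carries per-step :class:`JointLossReport` objects, per-epoch
    validation reports, and the best (restored) checkpoint.
    """
    if mode not in ("fine_tune", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    if task not in ("single", "multi"):
        raise ValueError(f"unknown task {task!r}")
    config = config or TrainConfig()
    records = [r for r in dataset if r.split == "train"]
    if not records:
        raise ValueError("empty train split")

    model = JointModel(config, seed=seed)
    if init_pod is not None:
        for k, t in model.params["pod"].items():
            t.data = (init_pod[k].data if isinstance(init_pod[k], Tensor)
                      else np.asarray(init_pod[k])).copy()

    rng = np.random.default_rng(seed + 1)
    pbundles = {}
    for i, (pid, (cloud, labels)) in enumerate(sorted(proteins.items())):
        pbundles[pid] = model.prepare_protein(cloud, labels, seed=seed + i)
    dbundles = {}
    for r in dataset:
        if r.drug not in dbundles:
            dbundles[r.drug] = model.prepare_drug(r.drug)

    if task == "multi" and not any(
            pbundles[r.protein].labels is not None for r in records):
        raise ValueError("task='multi' needs pocket labels in the train split")

    frozen = mode == "fine_tune"
    if frozen:
        model.cache_backbone(pbundles)
    opt = AdamW(model.trainable(mode, task), lr=config.lr,
                weight_decay=config.weight_decay)

    valid = [r for r in dataset if r.split == "valid"]
    step_reports: list[JointLossReport] = []
    epoch_reports = []
    best_state, best_val, best_epoch, bad = model.state_dict(), np.inf, -1, 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(records))
        for start in range(0, len(records), config.batch_size):
            batch = [records[i] for i in order[start:start + config.batch_size]]
            opt.zero_grad()
            prot_cache = {r.protein: None for r in batch}
            for pid in prot_cache:
                prot_cache[pid] = model.protein_forward(pbundles[pid], frozen)
            sq_terms, bce_terms = [], []
            for r in batch:
                po = prot_cache[r.protein]
                pred = model.pair_forward(po, dbundles[r.drug])
                sq_terms.append((pred - r.affinity) ** 2)
                if task == "multi" and pbundles[r.protein].labels is not None:
                    bce_terms.append(model.bce_full(
                        pbundles[r.protein], po["owning"], po["probs"]))
            mse_t = _mean(sq_terms)
            loss = mse_t
            bce_val = 0.0
            if task == "multi" and bce_terms:
                bce_t = _mean(bce_terms)
                loss = mse_t + config.beta * bce_t
                bce_val = float(bce_t.data)
            loss.backward()
            opt.step()
            step_reports.append(joint_loss(float(mse_t.data), bce_val,
                                           config.beta))
        val_total, val_report = _validate(model, valid or records, pbundles,
                                          dbundles, task, config, frozen)
        epoch_reports.append(val_report)
        if val_total < best_val - 1e-12:
            best_val, best_state, best_epoch, bad = (val_total,
                                                     model.state_dict(),
                                                     epoch, 0)
        else:
            bad += 1
            if bad > config.patience:
                break
    model.load_state_dict(best_state)
    history = {"steps": step_reports, "epochs": epoch_reports,
               "best_epoch": best_epoch, "best_val_loss": best_val,
               "checkpoint": best_state,
               "protein_bundles": pbundles, "drug_bundles": dbundles}
    return model, history


def _mean(tensors):
    total = tensors[0]
    for t in tensors[1:]:
        total = total + t
    return total * (1.0 / len(tensors))


def _validate(model, records, pbundles, dbundles, task, config, frozen):
    preds, truths = [], []
    bces = []
    prot_cache = {}
    for r in records:
        if r.protein not in prot_cache:
            prot_cache[r.protein] = model.protein_forward(pbundles[r.protein],
                                                          frozen)
        po = prot_cache[r.protein]
        preds.append(float(model.pair_forward(po, dbundles[r.drug]).data))
        truths.append(r.affinity)
        if task == "multi" and pbundles[r.protein].labels is not None:
            bces.append(float(model.bce_full(pbundles[r.protein],
                                             po["owning"], po["probs"]).data))
    mse = mse_loss(preds, truths)
    bce = float(np.mean(bces)) if bces else 0.0
    total = mse + (config.beta * bce if task == "multi" else 0.0)
    labels, probs = _pocket_arrays(records, pbundles, prot_cache)
    return total, metrics_report(preds, truths, labels, probs)


def _pocket_arrays(records, pbundles, prot_cache):
    labels, probs = [], []
    for pid in sorted({r.protein for r in records}):
        b = pbundles[pid]
        if b.labels is None or pid not in prot_cache:
            continue
        labels.append(b.labels)
        probs.append(prot_cache[pid]["full_probs"])
    if not labels:
        return None, None
    return np.concatenate(labels), np.concatenate(probs)


def evaluate(model: JointModel, dataset: list, split: str = "test",
             history: dict | None = None) -> MetricsReport:
    """Metric suite on one split, using the bundles built during training."""
    if history is None:
        raise ValueError("pass the history returned by train()")
    records = [r for r in dataset if r.split == split]
    if not records:
        raise ValueError(f"no records in split {split!r}")
    frozen = False
    _, report = _validate(model, records, history["protein_bundles"],
                          history["drug_bundles"], "multi", model.config,
                          frozen)
    return report


# ---------------------------------------------------------------------------
# Checkpoints: npz container with a JSON header
# ---------------------------------------------------------------------------

def save_checkpoint(path, state: dict, meta: dict | None = None):
    header = json.dumps(meta or {})
    np.savez(path, __meta__=np.frombuffer(header.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode()) if "__meta__" in data else {}
        state = {k: data[k] for k in data.files if k != "__meta__"}
    return state, meta
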