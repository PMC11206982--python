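# Methods

## Surface model

The protein surface is defined implicitly as the `r`-level set of a
smooth distance function (SDF) over the residue cloud: with alpha-carbon
positions `a_k` and per-residue-type radii `σ_k`,

```
SDF(x) = −σ(x) · log Σ_k exp(−‖x − a_k‖ / σ_k)
```

computed with a numerically stable log-sum-exp (the maximum exponent is
subtracted). For a single residue the expression collapses to the
Euclidean distance, so the level set is a sphere of radius `r`; for many
residues the log-sum-exp acts as a soft minimum, smoothly merging the
per-residue balls into one envelope. The radii `σ_k` are empirical mean
radii per residue type (GLY 1.46 Å … TRP 2.38 Å); residue-level rather
than atom-level sampling cuts the point budget by roughly the average
number of atoms per residue.

**The smoothing function σ(x).** Two modes are implemented.
`softmax_weighted` (default) sets `σ(x) = Σ_k w_k σ_k` with
`w_k = softmax(−‖x − a_k‖/σ_k)`, so the local smoothing length follows
whichever residues dominate the soft minimum; `constant` uses the mean
of all `σ_k`. Both collapse to the same value when all radii are equal,
which is what the closed-form tests exploit. Gradients are analytic in
both modes (the softmax mode includes the product-rule term from
`∇σ(x)`), verified against finite differences.

**Level-set sampling.** Each residue seeds `n_per_residue = 20` points
uniformly in a ball of radius `2σ_k` (guaranteeing coverage near every
residue); all points descend the quadratic residual energy
`E = ½ Σ_i (SDF(x_i) − r)²` with plain gradient steps
(`step_size = 0.5`, `max_iters = 50`). Because `‖∇SDF‖ ≈ 1` for a
distance-like function, the residual contracts by roughly half per
iteration and the energy trace is monotonically non-increasing at the
default step. Points that fail to reach `|SDF − r| ≤ tol` (`tol =
0.1 Å`) are discarded. Survivors are grid-clustered (cubic cells of
`grid_cell = 1.0 Å`, axis-aligned, anchored at the cloud's minimum
corner): one representative per occupied cell — the cell mean,
re-projected by one extra descent step. Normals are the normalized
analytic SDF gradient; each point is owned by its nearest residue.

Defaults for the point budget, iteration count and cell size are design
choices exposed in `SamplerConfig`: they give sub-residue resolution
(~750 points for a 50-residue chain) while the single-residue analytic
case converges exactly.

**Equivariance.** Descent and filtering are exactly equivariant under
rigid motions (the SDF depends only on pairwise distances). The
clustering grid is translation-equivariant (the anchor moves with the
cloud) but only approximately rotation-equivariant, since cell
boundaries rotate with nothing to anchor them; seed-to-seed variability
is bounded instead by a symmetric Chamfer distance ≤ 2·`grid_cell`.

## Quasi-geodesic convolution and pocket detection

Surface distance is approximated without a mesh as
`d_ij = ‖x_i − x_j‖ · (2 − ⟨n̂_i, n̂_j⟩)` ∈ [d_euclid, 3·d_euclid]:
pairs whose normals disagree (e.g. opposite faces of a thin lobe) are
pushed apart. Neighborhoods are all pairs with `d_ij ≤ 12 Å`, windowed
by a Gaussian `w(d) = exp(−d²/2σ_w²)` with `σ_w = 6 Å` — standard
practice for this convolution family, and a hard cap on cost.

**Local frames.** The pair feature `p_ij` is 4-dimensional: the
displacement `x_j − x_i` expressed in an orthonormal tangent frame at
`x_i`, plus `⟨n̂_i, n̂_j⟩`. The first tangent axis is the Gram–Schmidt
projection of the displacement itself against `n_i`. This makes `p_ij`
exactly invariant under rigid motions (every entry is a norm or inner
product of data vectors); a frame tied to world coordinate axes would
not be. When the tangential displacement vanishes the least-aligned
coordinate axis is used as a fallback — there the tangential components
are ~0 for any frame choice, so invariance is preserved.

**Convolution.** One block computes
`f_i′ = Σ_j w(d_ij) · MLP(p_ij) ⊙ f_j` with a shared 3-layer pair-MLP
whose output gates `f_j` element-wise (a `scalar` variant is exposed;
the gate keeps the parameter count tiny — the full detector is ~3.3 k
parameters, independent of protein size). Inside the stacked detector
each block's aggregation is additionally divided by `Σ_j w(d_ij)`
(a window-weighted mean): the raw sum grows with neighborhood size and
saturates downstream sigmoids after a few blocks; the normalization is
a fixed per-point scale that keeps activations O(1). The standalone
`conv_block` operation is the pure sum.

**Detector.** Initial per-point features are the owner residue's
20-type one-hot (learned projection to `hidden_dim = 16`), the SDF
value, and a curvature proxy (mean normal alignment over the
neighborhood). Three conv blocks with linear+ReLU mixes between them
feed a linear head producing point logits; logits are mean-pooled per
owning residue and squashed to pocket probabilities. Residues owning no
surface point are treated as buried and assigned probability 0 — a
deliberate contract with a visible cost (see Limitations).

## Graphs and encoders

Drugs: heavy-atom graphs from SMILES (rdkit), relations = bond order
(single/double/triple/aromatic); node features are element one-hot,
degree one-hot, formal charge and aromatic flag. Proteins: residue
graphs with 7 relations — sequential offsets −2, −1, +1, +2 within a
chain, radius edges (CA pairs ≤ 10 Å, excluding already-sequential
pairs), k-nearest-neighbor edges (k = 10) and self loops. Both encoders
are relational message passing with one weight matrix per relation plus
a self-transform, ReLU between layers (2 layers, width 128 by default),
mean-pooled — the protein encoder pools over the residues whose
predicted pocket probability ≥ 0.5, falling back to all residues when
that set is empty. The surface modality is the mean of the detector's
point features over points owned by predicted-pocket residues.

Sequence embeddings come through a provider interface: real pretrained
language-model vectors can be loaded from TSV; the shipped default is a
deterministic seeded hash projection of character n-grams (unit-norm,
distinct keys almost surely non-collinear), so nothing in the test path
downloads models or needs a GPU. Fusion is concatenation in a fixed
modality order; any non-empty subset of the five modalities can be
ablated and the predictor width adjusts.

## Joint training

`L_all = L_mse + β·L_bce`, `β = 0.5`. BCE runs over all residues of
each protein in the batch (probabilities clipped to [1e-7, 1−1e-7];
buried residues contribute a constant). The optimizer is AdamW
(lr 1e-3, decoupled weight decay 1e-2), early stopping on validation
`L_all` with patience 10, best checkpoint restored. In `fine_tune`
mode the surface/conv backbone is frozen — its point features are
cached once per protein, which makes fine-tuning ~20× cheaper than
normal mode — and the pocket head additionally updates when
`task = multi`. With `β = 0` the multi-task trace coincides exactly
with single-task training under matched seeds.

Gradient flow note: the pocket→affinity coupling is differentiable
through the pooled surface features; the pocket *mask* used for
structure-encoder pooling is a hard threshold (≥ 0.5) and therefore
non-differentiable — the head learns from the BCE term, which is why
the single-task normal regime leaves the pocket head untouched.

CI uses the standard all-pairs definition (ties in prediction count ½);
r_m² = r²·(1 − √|r² − r0²|) with r0² the through-origin counterpart,
the convention of the DTA literature; AUROC/AUPRC are the rank
statistic and step-interpolated PR area (scikit-learn).

## Synthetic data

The generator emulates the structure of pocket-annotated affinity
benchmarks at desk scale: self-avoiding random-walk backbones with
consecutive-CA spacing 3.8 ± 0.1 Å (clash distance 3 Å), residue types
uniform over the 20 codes, pockets = residues within 8 Å of a randomly
chosen surface-exposed residue with the pocket fraction resampled into
the sparse [1%, 15%] regime of real annotations, and affinities

```
y = w · hydrophobic_fraction(pocket) + v · heavy_atoms/20 + ε
```

with `w = 4`, `v = 2`, `ε ~ N(0, 0.1²)` and the hydrophobic set
{ALA, VAL, LEU, ILE, PHE, MET, TRP}. Constants are recorded in a
manifest, so the signal is exactly recoverable at zero noise and a
linear probe on the true features reaches R² > 0.9 at noise 0.1. The
benchmark uses 6 proteins × 50 residues and 200 pairs with a seeded
70/15/15 split — small enough to train on one CPU in minutes, large
enough that beating the best constant predictor requires using both the
protein and the drug signal.

What passing these tests does **not** show: the walks are not folded
proteins (no secondary structure, unrealistic burial statistics), the
affinity function is linear and noise-free in structure, and with 6
proteins the pocket task is solvable by memorizing per-protein residue
contexts — which is precisely what makes it a *separable* recovery
task, not evidence of cross-protein generalization.

## Training protocol of the recovery benchmark

Fine-tune mode presumes a pretrained backbone, so the benchmark
protocol first trains the detector alone with BCE on the 6 proteins
(200 full-batch epochs, AdamW lr 1e-2, no weight decay), then runs
multi-task fine-tuning with the defaults above (30 epochs, batch 32).
Observed at seed 0: pooled pocket AUROC 0.971, test RMSE 0.147 against
0.974 for the best constant predictor.

## Numerical choices and degenerate inputs

- Log-sum-exp everywhere an exponential sum appears; sigmoids use the
  sign-split stable form.
- Distances clamped at 1e-12 before division (query exactly on a CA).
- Probabilities clipped to [1e-7, 1−1e-7] before logs, bounding BCE by
  −log(1e-7).
- Unknown residue codes (MSE, UNK, …) get the median table radius
  1.99 Å with a warning; altloc duplicates keep the highest-occupancy
  CA (ties: first) with a warning; residues without CA are skipped and
  counted.
- Zero surviving surface points raises with advice (tol/max_iters);
  empty graphs, empty train splits, constant metric inputs and
  single-class AUROC raise rather than returning silent defaults
  (single-class AUPRC returns the prevalence baseline with a warning).
- All randomness flows from integer seeds through
  `numpy.random.default_rng`; repeated runs are bitwise identical.

## Limitations

- Buried pocket residues (no owned surface points) are forced to
  probability 0; on the synthetic benchmark this caps AUROC on proteins
  whose pocket includes an interior residue (one of the 6 benchmark
  proteins loses ~0.16 AUROC exactly this way).
- Pocket gating of the structure encoder is a hard threshold; no
  gradient flows through pocket *selection*, only through pocket
  *classification* and the surface features.
- The autodiff engine is minimal by design (no broadcasting matmul, no
  convolution primitives); model widths are chosen for CPU-scale
  problems.
- Grid clustering breaks exact rotation equivariance of the sampled
  point set (documented above); all learned operators are nevertheless
  rigid-motion invariant because they consume only distances, frames
  and inner products.
- mmCIF input, hetero-atom ligand parsing, conformer generation and
  attention-based fusion are out of scope.
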