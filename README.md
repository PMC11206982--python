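# pocketdta

Joint **binding-pocket detection** and **drug–target affinity (DTA)
prediction** from residue-level protein surface point clouds.

Finding where a ligand binds and how strongly it binds are usually
treated as separate steps of a drug-discovery pipeline. `pocketdta`
implements both in one differentiable stack, so pocket detection runs
*online* inside the affinity model instead of as an offline
preprocessing tool:

1. **Surface sampling.** The protein surface is the `r`-level set of a
   smooth distance function over the cloud of alpha carbons
   `{a_1..a_A}` with per-residue-type radii `σ_k`:

   `SDF(x) = −σ(x) · log Σ_k exp(−‖x − a_k‖ / σ_k)`

   Points are placed on `{x : SDF(x) = r}` (default `r = 1.05 Å`) by
   gradient descent on `E = ½ Σ_i (SDF(x_i) − r)²`, then grid-clustered
   for uniform density. Normals come from the analytic SDF gradient —
   no mesh is ever built.
2. **Quasi-geodesic convolution.** Surface distance is approximated as
   `d_ij = ‖x_i − x_j‖ · (2 − ⟨n̂_i, n̂_j⟩)`, and features propagate by
   `f_i′ = Σ_j w(d_ij) · MLP(p_ij) ⊙ f_j` with a Gaussian window `w`
   and learned functions of local tangent coordinates `p_ij`. Pooling
   point logits per owning residue gives pocket probabilities `p_j`.
3. **Multimodal fusion.** Five representations are concatenated:
   drug sequence (pluggable language-model embedding provider), drug
   structure (relational message passing over the 4 bond types),
   protein sequence (provider), protein structure (relational message
   passing over 7 residue-graph relations, pooled over the predicted
   pocket) and protein surface (pooled convolution features). A
   feed-forward head regresses the affinity (pKd-like scale).
4. **Joint training.** `L_all = L_mse + β·L_bce` with `β = 0.5`,
   optimized with AdamW. *Fine-tune* mode freezes the (pretrained)
   surface/conv backbone and updates only the encoders, the predictor
   and — in multi-task mode — the pocket head; *normal* mode trains
   end-to-end. Metrics: RMSE, MSE, MAE, concordance index, Spearman,
   Pearson, r_m², AUROC, AUPRC.

All neural components run on a small numpy reverse-mode autodiff engine
shipped with the package; no GPU or deep-learning framework is needed.
A seeded synthetic-fixture generator (random-walk backbones, proximity
pockets, affinities from a known function of pocket composition) makes
every stage testable offline.

## Worked example

```python
import numpy as np
from pocketdta import (SamplerConfig, ConvConfig, sample_surface,
                       detect_pockets, init_pod_params)
from pocketdta.fixtures import FixtureConfig, make_protein

cloud, labels = make_protein(FixtureConfig(), seed=0)   # 50 residues
surf = sample_surface(cloud, SamplerConfig(), seed=0)
print(len(surf), round(surf.sdf_values.mean(), 4))
# 751 1.0478   <- points on the 1.05 Å level set (tol 0.1 Å)

cfg = ConvConfig()
params = init_pod_params(cfg, np.random.default_rng(0))
pred = detect_pockets(cloud, surf, params, cfg)
print(pred.residue_probs.shape)                          # (50,)
```

`751` surface points converge onto the level set (mean SDF `1.0478 Å`
against the configured radius `1.05 Å`); an untrained detector then
produces one pocket probability per residue.

The full joint protocol on the synthetic benchmark (6 proteins,
200 pairs, noise sd 0.1) — pretrain the pocket backbone with BCE
(200 epochs), then multi-task fine-tune (seed 0) — prints on the test
split:

```
rmse 0.147  ci 0.952  spearman 0.982  auroc 0.971  auprc 0.974
```

i.e. the model recovers the affinity-generating signal (best constant
predictor: RMSE 0.974) while classifying pocket residues nearly
perfectly. `tests/test_acceptance.py` runs exactly this protocol.

The same functionality is exposed on the command line:

```bash
pocketdta make-fixtures --out fix/ --seed 0
pocketdta train --pairs fix/pairs.tsv --structures fix/ \
    --mode fine_tune --task multi --out model.npz
pocketdta evaluate --pairs fix/pairs.tsv --structures fix/ \
    --checkpoint model.npz --out metrics.json
```

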