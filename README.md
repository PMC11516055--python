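# dynabind

Binding affinity between a protein and a small-molecule ligand is set by the
thermodynamic ensemble of the complex, not by a single crystal pose. `dynabind`
is a toolkit for affinity scoring that takes this seriously: it converts
protein–ligand structures — crystal poses or molecular-dynamics snapshots —
into rigid-motion-invariant graphs, scores them with a graph transformer whose
attention is biased by Gaussian-basis encodings of interatomic distances and
bond angles, and fuses the result with knowledge-based interaction
fingerprints. Around the model it provides the full working context a
computational chemist needs: MD-trajectory stability analytics (ligand
RMSD/RMSF, stability classes, per-residue interaction fractions), the
CASF-style scoring/ranking metric suite, and the post-docking rescoring
filters used in virtual screening. A synthetic-fixture generator emulates
every input, so nothing here requires external downloads.

## The model

A complex becomes a graph `G = (V, E)`: one coordinate-free virtual node,
every ligand heavy atom, and the protein heavy atoms within `d_p = 5 Å` of
the ligand (the pocket). Edges are covalent bonds plus all non-covalent pairs
within `d_s = 5 Å`. Scalars attached to pairs — the distance `r_ij`, the
summed bond angle `Σ_k ∠ijk` at a bonded pair, and per-edge scores averaged
along one shortest path — enter multi-head attention as additive biases:

```
A_ij = (h_i W_Q)(h_j W_K)ᵀ / √d_K + d(i,j) + a(i,j) + (1/P) Σ_p e_p w_pᵀ
```

where `d(i,j)` and `a(i,j)` expand their scalar through `K` learnable
Gaussian basis functions `GBF(x) = exp(−(x−μ_k)²/2σ_k²)`, modulated by the
endpoint atom types. Because every structural input is an invariant scalar,
the prediction is exactly invariant under rotation, translation, and atom
relabeling. After the encoder stack, the virtual node's representation is
concatenated with three fingerprint families — element-pair contact counts
(12 Å), typed-atom-environment pair counts (6 Å), and Gaussian-shell
distance-weighted pair features — and a linear head emits the predicted
`pK_i = −log₁₀ K_i`.

Training is two-stage: MSE pretraining on MD snapshot graphs, where every
frame of a trajectory shares the trajectory's affinity label, then MAE
finetuning on static structures (peak learning rate 1e-5, batch 16), both
with a group-wise 9:1 train/validation split, optional FLAG adversarial
augmentation of the node embeddings, and best-validation checkpointing. The
network and its training loop run on a small numpy reverse-mode autodiff
engine included in the package — no GPU or deep-learning framework needed.

## Worked example

```python
import numpy as np
from dynabind.synthgen import SynthConfig, make_labeled_dataset
from dynabind.train import Dynaformer, TrainConfig, split
from dynabind.model import ModelConfig
from dynabind.evalmetrics import pearson_r

# 200 toy complexes whose pKi is a known function of 4 Å contact counts
_, ds = make_labeled_dataset(200, SynthConfig(seed=42, n_frames=1))

model = Dynaformer(
    ds,
    ModelConfig(n_layers=2, hidden_dim=32, n_heads=4, K_gbf=16, seed=0),
    TrainConfig(stage="pretrain", epochs=60, batch_size=16, seed=0, peak_lr=3e-3),
)
res = model.fit()
print(res.summary())

_, val = split(ds, 0.9, "complex", 0)
preds = res.predict_items(val.items)
truth = np.array([it.label for it in val.items])
print(f"held-out Pearson r = {pearson_r(preds, truth):.3f}")
```

Output:

```
Dynaformer fit results
==============================================
stage:            pretrain (mse loss)
layers x hidden:  2 x 32 (4 heads)
parameters:       19601
train/val items:  180/20
epochs:           60
peak lr:          0.003
FLAG steps:       0
final train loss: 0.0408
best val loss:    0.1185
held-out Pearson r = 0.958
```

The held-out correlation of 0.958 means the model recovered the hidden
contact-count affinity function from graphs and fingerprints alone; the gap
between train (0.041 pKi²) and validation (0.119 pKi²) MSE is the usual mild
overfit of a small dataset.

Trajectory analytics work the same way from synthetic or parsed MD input:

```python
from dynabind.synthgen import make_complex, make_trajectory
from dynabind.traj_analysis import ligand_stability

cfg = SynthConfig(seed=7, mobility="intermediate")
traj = make_trajectory(make_complex(cfg), cfg)
res = ligand_stability(traj)
print(f"mean ligand RMSD {res.mean_rmsd:.2f} Å -> {res.stability_class}")
# mean ligand RMSD 4.78 Å -> intermediate
```

A `dynabind` CLI wraps the same functions (`dynabind ingest`, `featurize`,
`fingerprint`, `predict`, `evaluate`, `traj-analyze`, `screen`, `synth`);
run `dynabind --help`.

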