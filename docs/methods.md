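# Methods

This note records the modelling assumptions, parameter choices, numerical
conventions and known limitations of `dynabind`, in the order data flows
through the package.

## Data model and ingestion

A complex is one protein plus one ligand, reduced to heavy atoms; explicit
hydrogens in the input are folded into a per-heavy-atom hydrogen count that
later becomes a node feature. Ligand bonds are taken verbatim from the
SDF/MOL V2000 bond block — a ligand file without a bond block is rejected,
because typed-atom environments and covalent edges are undefined without
it. Protein covalent bonds are inferred from standard residue templates
(via biotite), falling back to a covalent-radius criterion
(`d < r_cov(i) + r_cov(j) + 0.4 Å`) for nonstandard residues. Waters and
ions do not survive ingestion: the toolkit models the protein–ligand pair
only. Coordinates are Å throughout; atom indices are 0-based; frame 0 of a
trajectory is the reference for deviation metrics unless a caller overrides
it. Trajectories are accepted as multi-model PDB or a plain-text
`frame atom x y z` table; binary MD formats are deliberately out of core
scope.

## Graph representation

* Pocket: protein atoms whose minimum distance to any ligand atom is
  ≤ `d_p` (default 5 Å; "within" is inclusive, configurable).
* Edges: covalent bonds among kept atoms, plus every remaining pair within
  `d_s` (default 5 Å) as non-covalent edges carrying their distance.
* Node features (element, degree, formal charge, hydrogen count,
  hybridization, aromaticity, ring membership, chirality, origin) are
  categorical codes following the common molecular graph benchmark
  vocabulary. Topological features are computed on the *full* molecules
  before pocket truncation so clipping the protein cannot change the
  perceived chemistry of boundary atoms.
* The virtual node is coordinate-free: code 0 in every embedding table,
  excluded from pathfinding, distances and angles. Its attention bias to
  every real node is a single learned scalar per head.
* Angle sums are defined over covalent adjacency only: for a bonded pair
  (i, j), the sum over other covalent neighbors k of j of the angle i-j-k,
  in degrees. Angles over all cutoff pairs would be O(n³) and dominated by
  uninformative near-collinear triples.
* Shortest paths: unweighted BFS over all edges, capped at `P_max`
  (default 5). Among equal-hop paths the geometrically shortest one
  (smallest cumulative r_ij) is selected, with lowest-index fallback on
  exact ties. An index-based tie-break alone would make the *selected* path
  — and therefore the model's path bias — depend on atom input order,
  breaking permutation invariance of the prediction; cumulative geometric
  length is invariant to both relabeling and rigid motion. Disconnected or
  beyond-`P_max` pairs contribute a zero path bias (zero is the neutral
  element of an additive bias).

## Fingerprints

Three families, all functions of distances and topology only (hence
rigid-motion- and order-invariant), computed per scored structure (each MD
snapshot gets its own):

* `rfscore`: counts of protein–ligand element pairs within 12 Å over
  {C,N,O,S} × {C,N,O,F,P,S,Cl,Br,I} (36 entries), following the published
  default of the element-pair-count family.
* `ecif`: typed-atom-pair counts within 6 Å, a type being (element,
  heavy-neighbor count, attached-H count, aromaticity, ring membership,
  explicit valence). The type vocabulary is data-driven and persisted as a
  schema (canonical sorted order); vectors are only comparable under one
  schema, and training pipelines build one schema over the whole dataset.
* `gbscore`: per element pair and Gaussian shell (μ, σ), the sum of
  exp(−(r−μ)²/2σ²) over pairs. Default shells: μ = 2…12 Å in steps of 2,
  σ = 1 Å (216 features) — centers spanning the contact-to-midrange band at
  the coordination-shell width. All cutoffs and shells are config-exposed.

Hydrogens enter only through the per-atom hydrogen counts; the published
variants differ on this point and the heavy-atom convention keeps one code
path for crystal and MD input.

## Network

Multi-head attention with additive structural biases; four encoder layers
of 512 hidden units is the reference configuration, with 8 heads and a
2×hidden FFN where the head count and FFN width are this package's own
defaults (only layers × hidden are fixed by the reference configuration).
Distance and angle scalars pass through an endpoint-conditioned affine
(x′ = (s_i+s_j)x + (t_i+t_j), one (s, t) pair per element category) before
the K Gaussian basis functions, then a K×heads projection — this keeps the
basis a scalar-input family while letting atom identities modulate it.
σ_k > 0 is enforced by softplus reparameterization. Basis centers
initialize linearly over [0, 5 Å] for distances and [0, 540°] for angle
sums (three tetrahedral angles ≈ 330°, three trigonal ≈ 360°, plus slack),
with widths equal to the spacing.

Attention logits divide by √d_K by default; a `denominator="linear"` switch
provides the d_K form for comparison. The path bias averages per-head edge
scores over the actual path length (`path_average="fixed"` divides by
`P_max` instead, which dilutes short paths). Layer order is post-norm:
MHA → residual + LayerNorm → FFN → residual + LayerNorm. The virtual node's
final representation, concatenated with the standardized fingerprint block,
feeds a linear head.

Fingerprint standardization: `fit()` computes mean/std of the concatenated
fingerprint block on the training split and stores them as non-trainable
buffers (persisted in checkpoints). The divisor is floored at 5% of the
mean feature std so rare, near-constant count features cannot explode on
out-of-split structures. Raw count scales (up to hundreds) otherwise
dominate the update geometry.

The whole network runs on a small reverse-mode autodiff engine over numpy
float64 (`dynabind.nn.autodiff`): broadcast-aware arithmetic, matmul,
softmax, layer norm, embedding gather with scatter-add backward. Everything
is single-threaded and deterministic: fixed seed ⇒ bit-identical
parameters, predictions and training runs. There is no dropout; FLAG plus
weight decay are the regularizers.

## Training protocol

Pretraining minimizes MSE over snapshot graphs; every frame of a trajectory
carries the trajectory's label and frame order is discarded (each snapshot
is an independent sample of the ensemble). Finetuning minimizes MAE on
static structures with peak learning rate 1e-5 and batch 16. Defaults not
fixed by the reference protocol: pretraining peak learning rate 2e-4,
warmup fraction 0.06, Adam with decoupled weight decay, linear
warmup-then-decay. The 9:1 split is group-wise by complex (snapshot-level
splitting would leak near-duplicate frames across the split; a
`split_unit="snapshot"` switch exists for comparison). The checkpoint with
the best validation loss is returned. A warm start (`fit(init_state=...)`)
copies every shape-compatible tensor, so a head trained against a different
fingerprint schema is re-initialized while the encoder transfers.

FLAG augmentation perturbs the summed node embeddings: starting from zero,
the loss gradient w.r.t. the perturbation is ascended `steps` times with
per-graph normalized steps of length `step_size` (perturbation norm ≤
steps × step_size), and the descent step uses the loss at the final
perturbation. `steps=0` is bit-exactly the plain loss; ascent iterations
clear any gradient they leak into the parameters.

## Trajectory analytics

Ligand RMSD is measured against the frame-0 (crystal) pose. By default
every frame is first least-squares superposed on the frame-0 pocket atoms
(Kabsch, via scipy), so global tumbling is not mistaken for ligand motion;
`align=False` gives the raw deviation. Mean ligand RMSD classifies the
trajectory: `< 3 Å` stable, `3–10 Å` intermediate, `> 10 Å` unstable. The
boundary values 3 and 10 belong to the intermediate class (the outer
classes are defined by strict inequalities). RMSF is the per-atom
fluctuation about the trajectory-mean position.

Interaction fractions report, per (interaction type, residue), the fraction
of frames with a detected contact. The geometric criteria are this
package's own (none are fixed by the reference analysis) and
config-exposed: hydrogen bond — donor (N/O with ≥ 1 H) to acceptor (N/O)
distance ≤ 3.5 Å and heavy-atom surrogate angle X–D···A ≥ 120°; π–π —
aromatic ring centroid distance ≤ 5.5 Å; hydrophobic — contact ≤ 4.0 Å
between apolar carbons (carbons with no N/O neighbor).

## Evaluation metrics

Scoring power pools all complexes: Pearson r, RMSE, and SD — the standard
deviation of residuals about the least-squares regression of measured on
predicted affinity (the benchmark convention; a constant prediction offset
inflates RMSE but not SD; the N−1 denominator follows that convention).
Ranking power is computed within each protein target and averaged with
equal target weight: Spearman ρ, tie-corrected Kendall τ
((C−D)/√((C+D+T)(C+D+U))), and the predictive index, which weights each
pair by its affinity difference. PI's discordant pairs score 0 by default;
a `discordant_value=-1` switch gives the variant used in the index's
original formulation. Prediction ties count as discordant. Targets where a
metric is undefined (all-tied values) are excluded from that metric's mean
with a warning.

## Screening stage

Affinity conversions: pKi = −log₁₀ Ki and ΔG = RT ln Ki (negative for
favorable binding) with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T defaulting to
303.15 K, the simulation temperature of the MD protocol the model is built
around. The printed form of the conversion in some sources flips the sign
of ΔG; this package keeps binding free energies negative.

Rescoring pools the union of the top 10% by predicted pKi (descending) and
the top 10% by docking energy (ascending), ties broken by molecule id,
then applies the filters; a `filter_first` switch swaps the order. Filter
bounds are strict, exactly as worded (`more than`, `exceeding`,
`larger than`): hbd > 5, hba > 10, ClogP > 5, rotatable bonds > 10,
PSA > 140 Å², and any ring of size 3, 4, 7 or more than 12 (smallest-ring
inventory). A molecule sitting exactly on a bound passes. Each removal
reports its first failing rule in a fixed rule order.

## Synthetic fixtures

The generator produces statistical stand-ins, not physics. Ligands are
random connected trees with valence-respecting elements (C/N/O), ~1.5 Å
bonds and clash checking; leftover valence becomes hydrogen count. Pocket
atoms (C/N/O/S, one residue each) sit 3–5 Å from a random ligand atom.
Trajectories emulate the three mobility regimes seen in MD ensembles:
stable = isotropic Gaussian jitter (default σ = 0.3 Å) about frame 0;
intermediate = jitter plus a saturating excursion to 6 Å (mean ligand RMSD
lands mid-band, 3–10 Å); unstable = jitter plus monotone drift
(0.5 Å/frame), carrying the ligand far out of the pocket. Protein atoms
only jitter. The default 100 frames per trajectory matches the snapshot
count of the emulated MD protocol.

Labeled datasets draw per-complex sizes from ranges (ligand 5–14, pocket
6–24 atoms), emulating the size heterogeneity of real complex collections,
and label each complex with pKi = 0.1 × (4 Å protein–ligand contact count)
+ 2.0 (+ optional Gaussian noise), clipped to [0, 14] — the slope maps
typical generated contact counts onto the pKi 2–9 band real affinity data
occupies. Labels are tied to contact counts rather than to any model
output, so recovery tests cannot be self-fulfilling. Every generator is a
pure function of its config (bit-reproducible).

What passing the synthetic suites does and does not show: they verify the
machinery — invariances, oracles, the optimizer's ability to recover a
known signal, the protocol guarantees — under toy geometry with no solvent,
no conformational strain, no binding-mode multiplicity, and a label
function far simpler than real thermodynamics. They say nothing about
accuracy on real crystal structures or MD ensembles, which requires the
external benchmark data and full-scale training.

## Problem sizes and numerical choices

Test and acceptance runs use reduced problem sizes chosen as this package's
own defaults for a laptop-class machine: tiny reference models (2 layers ×
32 hidden, 16 basis functions), 8-complex overfit probes, 200-complex
recovery datasets (60 epochs), 100-seed classification sweeps, 1000-vector
oracle sweeps. The full-size configuration (4 × 512) is exercised for
construction and forward contracts, not trained in the suites. Degenerate
inputs fail loudly: empty ligands, zero-length bond vectors, non-finite
activations (reported with layer index), all-tied metric inputs,
non-positive Ki. Gradient checks hold to ~1e-6 relative against central
differences across every parameter family.

## Known limitations

* No protonation, tautomer, or missing-residue handling; inputs are taken
  as prepared.
* Aromaticity and chirality come from the input file; there is no per-frame
  re-perception from geometry (protein atoms currently carry no chirality
  and template-level aromaticity only).
* The trained-weight release of the reference model is not reproduced; the
  package trains from scratch at whatever scale the caller affords.
* Attention-based pooling is weak at extensive (count-like) quantities; the
  fingerprint block carries that information instead, which is why the
  fusion matters.
* Single-threaded CPU only; a 4 × 512 model over thousands of snapshots
  wants hours, not minutes.
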