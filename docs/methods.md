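# Methods

`catrace` builds protein Cα backbone models from cryo-EM density maps,
optionally fused with a predicted-structure prior. The pipeline has five
stages: map preprocessing, voxel classification, Cα candidate extraction,
backbone tracing with sequence registration, and evaluation. A simulator
generates desk-scale synthetic fixtures so every stage can be exercised and
tested on one CPU.

## Map I/O and preprocessing (`map_io`)

Maps are read and written as MRC2014 (mode-2 float) through gemmi. On read,
axis order is normalized to the internal convention: `data[i, j, k]` indexes
`(z, y, x)`, regardless of the file's MAPC/MAPR/MAPS permutation. The world
origin comes from the ORIGIN header words, or from NSTART times the voxel
spacing when ORIGIN is all zero; voxel spacing falls back to CELL divided by
the sampling counts if gemmi reports a non-positive spacing.

Preprocessing resamples the map to 1 Å cubic voxels (cubic spline
interpolation) and normalizes intensities: subtract the median, clip at the
99.9th percentile, floor negatives at zero, and min-max scale to [0, 1].

For inference and training the volume is tiled into 48³-voxel cores with 8
voxels of zero-filled context per face, giving 64³ patches
(`partition_map`); predictions are reassembled from the cores only
(`stitch_volumes`), which makes the partition/stitch cycle an exact
identity.

## Structure codec (`struct_codec`)

World coordinates map to grid indices by round-half-up of
`(coord − origin) / voxel`, with `i` derived from z;
out-of-grid atoms are flagged, never clamped. A structure is encoded into a
24-channel occupancy volume: four backbone-atom channels (CA, N, C, O) and
20 amino-acid-type channels ordered alphabetically by three-letter code.

Ground-truth label masks use a 26-neighborhood shell scheme per task:
label 3 on the atom voxel, 2 on its first shell, 1 on the second shell, 0
elsewhere, for both the backbone task (all backbone atoms) and the Cα task;
the amino-acid mask stores `type_index + 1` on the same support with 0 as
background (21 classes).

## Network (`network`, `nn`)

The segmentation network is a 3D encoder–FPN with multi-task heads,
implemented on a compact numpy reverse-mode autodiff engine (`catrace.nn`)
with BLAS/FFT convolutions:

- **Stem**: four parallel density convolutions with kernel sizes 3/5/7/9
  whose outputs concatenate to 128 channels, followed by channel attention.
- **Prior branch**: the 24-channel prior encoding passes through a
  convolution and a sigmoid gate, then fuses with the density features; a
  missing prior behaves exactly as an all-zero encoding.
- **Encoder**: three stages of 128/256/512 channels, each a residual block
  of three 3³ convolutions with squeeze–excitation and dual
  (channel + spatial) attention, followed by a stride-2 transition.
- **FPN**: 1³ lateral convolutions to 64 channels, top-down upsampling with
  per-level 3³ smoothing, softmax-weighted scale mixing, and trilinear
  upsampling to full resolution, concatenating to 192 channels.
- **Heads**: cascaded 1³-convolution heads emitting 4 (backbone), 4 (Cα),
  and 21 (amino-acid) channels.

`logits_to_probabilities` converts head logits to per-voxel probabilities
by a softmax restricted to the {shell-2, atom} channel pair for the
backbone and Cα tasks, and a softmax over the 20 amino-acid types.
Checkpoints are npz archives with a JSON metadata channel-order record.

## Training (`trainer`)

The loss is a convex combination of three class-weighted softmax
cross-entropies, `L = λ_b L_b + λ_c L_c + λ_a L_a`, with λ scheduled from
(0.6, 0.3, 0.1) to (0.25, 0.4, 0.35) at epoch 25 (optional 5-epoch linear
ramp). Class weights are inverse-frequency normalized to mean 1 (uniform
weights are config-selectable). Optimization uses Adam (lr 1e-4), global
gradient-norm clipping at 1.0, and reduce-on-plateau decay against a 20%
validation split; the best-validation parameter state is checkpointed.

Augmentation applies intensity operations to the density only (Gaussian
noise, blur, multiplicative intensity scaling) and spatial operations
identically to density, prior, and labels (axis permutations, flips,
zero-filled integer shifts). Each sample's prior is dropped with
probability 0.4 per step so the network stays useful density-only.

## Cα candidates (`ca_cluster`)

Voxels with Cα probability above 0.3 are clustered by DBSCAN (eps 1.8 Å,
min_samples 1) on their world coordinates. Clusters whose mean backbone
probability falls below 50% of the best cluster's mean are discarded. Each
cluster becomes a candidate at its Cα-probability-weighted centroid with an
aggregated 20-way amino-acid profile; non-maximum suppression (2 Å radius,
by descending score) removes near-duplicates.

## Tracing (`tracer`)

1. **Graph**: candidates within 2–6 Å are linked; nodes above degree 2 drop
   their edge whose length is farthest from the ideal 3.8 Å Cα–Cα spacing.
2. **Scores**: `S[i, j, k]` is candidate k's profile probability for
   residue j of sequence i; connectivity propagation adds
   `Σ_h 0.5^h · ½ (max over exactly-h-hop neighbors of S at j−h and j+h)`
   for h up to 3, yielding `E`.
3. **Seed and extend**: cells in the top 1% of E (never below 0.5) seed
   fragments, extended bidirectionally along graph neighbors while the next
   score clears 0.2; with a prior, steps deviating more than 5 Å from the
   fragment-superposed prior are rejected. Consistent overlapping fragments
   merge.
4. **Assignment**: fragments are assigned greedily by score to chain
   instances (duplicate sequences become copies), preferring the instance
   with the best spatial coherence.
5. **Prior refinement**: each contiguous run tests registration shifts of
   ±2 and adopts the shift minimizing RMSD to the superposed prior if it
   costs at most 10% of the run's mean E.
6. **Gap filling**: gaps between anchors are filled by depth-first search
   for exact-length unassigned candidate paths maximizing summed E, pruned
   against the prior transform.
7. **Prior-guided completion**: placements deviating > 5 Å from the
   instance-superposed prior are evicted; termini are extended with the
   fragment step rule; residues still missing are placed at the nearest
   free candidate within 5 Å of the prior-projected position subject to
   the 2–6 Å consecutive-distance invariant. These steps recover residues
   lost to voxel-quantization artifacts in the degree-pruned graph and are
   no-ops without a prior.

The result is a CA-only model with explicit gap records, written as PDB.

## Metrics (`metrics`)

Predicted and true models are compared in the map frame (no superposition).
Matching is greedy one-to-one by ascending distance under a 3 Å cutoff.
Reported: Cα match (% of predicted residues matched), quality
(match × coverage, coverage = min(1, n_pred/n_true)), sequence match (% of
matched pairs with identical type), and an in-frame TM-score with
`d0 = max(1.24·∛(n_true−15) − 1.8, 0.5)` over an 8 Å pairing.

## Simulator (`simulator`)

Toy complexes are connected ideal-helix segments with clash rejection
(3.8 ± 0.1 Å consecutive spacing, ≥ 3.2 Å otherwise), idealized N/C/O
offsets, and uniform random sequences. Density is a per-atom isotropic
Gaussian with FWHM equal to the nominal resolution plus seeded noise,
rendered on a 1 Å grid and normalized. Predicted-structure surrogates
perturb contiguous chain thirds rigidly (seeded rotation + translation)
with per-atom jitter and optional domain dropout. Oracle prediction volumes
assign probability 0.95/0.3/0.01 to atom/shell/background voxels with an
optional seeded label-corruption rate, so clustering and tracing can be
tested without a trained network.

## Reproducibility

All randomness flows from one root seed through stable per-stage derived
seeds (`derive_seed`), recorded with the package version and configuration
in `provenance.json` next to the outputs. Re-running a pipeline with the
same inputs and seed reproduces every output byte-for-byte.
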