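# Methods

## Problem and scope

`cryosse` segments α-helix and β-sheet regions in *component maps* — the
density region of a single protein chain cut out of a cryo-EM map — at medium
resolution (5–10 Å), where individual backbone atoms are not resolved but
helices appear as cylinders and sheets as slabs.  The segmenter assigns one
of three classes (background, helix, sheet) to every voxel of a 1 Å/voxel
grid of at most 100 voxels per dimension, and detections are summarised both
per voxel and per residue.

The package covers the full protocol around the network: MRC2014 volume I/O
and preprocessing, STRIDE-based ground-truth labelling, dataset curation
(de-duplication, quality binning, test-set screening), curriculum training
with gradient episodic memory, end-to-end inference to helix/sheet mask
volumes, two-level F1 evaluation, and a synthetic-data generator that stands
in for curated EMDB/PDB data at desk scale.

## Ground-truth labelling

Residue classes come from STRIDE one-letter codes: H, G, I → helix; B, b,
E → sheet; everything else → other.  A voxel is labelled helix (sheet) iff
its center lies within 3.0 Å (inclusive) of the Cα of at least one helix
(sheet) residue; all other voxels are background.  Where the two 3 Å spheres
overlap, helix wins — the same priority used for residue-vote ties — so the
labelling is independent of residue order.  Component envelopes are cut with
a 5 Å radius around the chain's atoms; voxel membership always uses voxel
*center* distance with an inclusive boundary.

## Network

A five-composite-layer 3D U-Net: two down-sampling layers, a bottleneck, and
two up-sampling layers, each composite layer being two (3³ convolution →
channel normalisation → ReLU) blocks.  Layers are joined by dropout followed
by 2× max pooling (down path) or a 2³/stride-2 transpose convolution (up
path), with channel-concatenation skips between mirrored layers; a final 1³
convolution produces the three class logits and a softmax the per-voxel
probabilities.  Channel widths double per level (c, 2c, 4c); `base_channels`
c defaults to 64 for a full-scale model and to 8 for the desk-scale studies
in this repository.  Being fully convolutional, the model accepts any input
whose dimensions are multiples of 4 (maps are zero-padded to that, and
predictions un-padded, automatically).

Two accounting notes, both computed rather than assumed:

* parameter count: `count_parameters` reports 5,420,867 for c = 64 and
  85,355 for c = 8 (exact widths of the lineage model this architecture
  follows are not published, so counts are logged per configuration);
* receptive field: the theoretical receptive field of this topology is 44
  voxels per side; the test suite verifies empirically that a single-voxel
  perturbation never changes outputs beyond Chebyshev radius 22.

The network and its training loop are implemented directly in numpy.
Convolutions are evaluated as one GEMM per kernel offset on contiguous
slices of the flattened padded volume, and every layer implements an
explicit backward pass; the full backprop is verified in the tests by
directional-derivative checks and against a `scipy.ndimage` convolution
oracle.

**Normalisation.**  A batch is a single component map (sizes vary from case
to case, which precludes naive batching), so the normalisation layers
compute per-channel statistics from the sample itself at both training and
inference time — instance-normalisation behaviour.  Running batch statistics
accumulated from single-sample batches were evaluated and discarded: on
held-out synthetic maps they systematically distorted class probabilities
(per-class detections collapsed), whereas per-sample statistics keep the
train/test activation distributions consistent.

## Loss and class weighting

The loss is `(1 − λ)·CE + λ·Dice` with λ = `dice_weight` (default 0.5):

* CE is cross-entropy weighted inversely to the class frequencies of the
  current training subset (weights normalised to sum to 1, and the per-voxel
  weighted sum normalised by the total weight so equal weights reduce to the
  plain mean);
* Dice is the soft dice loss `1 − 2Σpt/(Σp + Σt)` averaged over the three
  classes, a class with empty denominator contributing zero.

## Curriculum and gradient episodic memory

Training data are partitioned into three quality bins (Bin 1 = best
model-to-map fit).  Training runs in three phases: phase 1 on Bin 1, phase 2
on Bins 1–2, phase 3 on all bins.  In phases 2 and 3 an episodic memory of
five examples is drawn uniformly without replacement from the bins of
earlier phases (refreshed at each phase transition, fixed within a phase).
At every optimisation step the gradient over the memory set is recomputed at
the current weights, pooled into a single average memory gradient m, and the
sample gradient g is projected to

    g' = g − (g·m / ‖m‖²) · m      if g·m < 0,   else g' = g,

the minimal-norm correction that prevents the step from pointing against the
memory — a single-constraint variant of gradient episodic memory with a
closed-form projection (the full per-example quadratic program is a
non-goal).  Pooling the five examples into one constraint is a documented
choice; whether the original protocol used one aggregate or five separate
constraints is not published.

Optimisation is Adam (lr 1e-3, betas 0.9/0.999) with a step schedule that
multiplies the learning rate by 0.1 every `weight_decay_step` epochs.  The
default batch is one component map; because map sizes vary, larger batches
are realised by gradient accumulation (`batch_size` maps per Adam step)
rather than tensor stacking.  Optional training aids, all off by default:

* `augment_rotations` — each training map is presented in a random
  right-angle orientation (the 48-element cube symmetry group) per step;
  the network is not rotation-equivariant, so with small corpora this
  supplies the orientation coverage a large corpus provides naturally;
* `select_best` — when a validation split is given, the weights kept at the
  end are those of the epoch with the best balanced validation F1
  (residue-level when the validation entries carry Cα annotations),
  mirroring the full protocol's use of a validation partition;
* `patience` — per-phase early stopping on validation loss.

Exact epoch counts per phase are unpublished in the source protocol and are
exposed in `TrainConfig`.  All randomness (weight init, shuffling, dropout,
memory sampling, noise) derives from the single `seed`, so runs are exactly
reproducible in a fixed numeric environment.

The estimator also offers test-time orientation averaging
(`orientation_average`): class probabilities averaged over the 24 proper
rotations of the input.  It is off by default — for marginal detections the
23 unfamiliar orientations can dilute a correct prediction made in the
boxed orientation; rotation-augmented *training* proved the more effective
use of the same symmetry.

## Inference

`detect` runs: read MRC → resample to 1 Å (trilinear; outside values 0) →
min–max normalise to [0, 1] (a constant map becomes all-zero) → zero-pad to
multiples of 4 → forward pass → per-voxel argmax → un-pad.  Argmax ties are
resolved helix > sheet > background, one coherent tie policy across the
code base.  The helix and sheet masks are written as float32 {0, 1} MRC
volumes carrying the input's origin and voxel size, so they overlay the map
in any viewer.  Maps exceeding 100 voxels per dimension after resampling are
rejected, mirroring the tool's design envelope.

## Evaluation

Per class, F1 = 2PR/(P + R) one-vs-rest:

* voxel level, between predicted and ground-truth label grids;
* residue level, between STRIDE classes and per-residue predictions obtained
  by majority vote among predicted voxel labels within 3 Å of the residue's
  Cα (ties: helix, then sheet, then other; a Cα with no grid voxel in range
  votes "other" with a warning).

A score is **NA** exactly when the class is absent from both truth and
prediction (precision or recall undefined); a class that exists but receives
no predictions scores 0, not NA.  Across cases, each metric is averaged
weighted by the case's residue count of that class; NA cases carry zero
weight.  The weighting denominator is the total residue count *of that
class* over the contributing cases (so weights sum to one); the alternative
reading — all residues in the test set — would not normalise.

## Curation

* **De-duplication.**  Needleman–Wunsch global alignment with match +1,
  mismatch 0, gap −1 (the published protocol does not state its scheme);
  identity = identical aligned pairs / alignment length.  Among score-optimal
  alignments the reported identity maximises the identity count and then
  minimises alignment length, making the percentage deterministic; `X`
  (unknown) residues never count as identical.  Chains above 70% identity to
  an already-retained chain of the same protein are dropped greedily in
  input order.
* **Quality binning.**  Each helix (≥ 4 consecutive helix residues) is fit
  by an ideal helical cylinder: the axis is the least-squares line through
  the Cα trace, the cylinder radius the mean radial distance of the Cαs from
  the axis, and each Cα is snapped onto the cylinder surface at its own
  axial position and azimuth.  The fitted curve's 3 Å tube (the labelling
  radius) is scored by F1 against the helix-labelled voxels within that
  helix's own 3 Å Cα neighbourhood — an ideal helix scores ≈ 0.94, and the
  score decays as the trace departs from cylindrical geometry (restricting
  truth per helix keeps a perfect fit near 1 even in multi-helix chains).
  The chain score is the mean over helices; chains are split into three bins
  by tertiles of the score, ties going to the better bin.  The underlying
  published construction and bin thresholds are not available, so this
  operationalization is the package's own, recorded here.
* **Test screening.**  Candidates with unknown sequences are dropped; then
  any candidate above 35% identity to a training chain; finally, against
  every unknown-sequence training chain at least one of the two
  length-normalised TM-scores (parsed from TM-align text output — TM-align
  is wrapped, never reimplemented) must be below 0.5.

## Synthetic data

The generator emulates medium-resolution component maps with exactly known
ground truth:

* ideal α-helix Cα traces (rise 1.5 Å/residue, 100°/residue twist, radius
  2.3 Å → consecutive Cα distance 3.83 Å) and idealized antiparallel
  β-sheets (3.3 Å Cα spacing along a strand, 4.8 Å between strands,
  alternating strand direction), randomly rotated and placed;
* density = sum of isotropic Gaussians at the Cα positions with FWHM equal
  to the nominal resolution (σ = R/2√(2 ln 2); one of several community
  conventions, fixed here), sampled on a 1 Å lattice, plus Gaussian noise
  with standard deviation `noise_sd × peak`;
* labels generated by the same 3 Å-sphere rule as for real data, so labels,
  annotations and density are exactly consistent by construction;
* three quality levels stand in for the cylindrical-fit bins:
  1 → (5 Å, 5% noise), 2 → (7.5 Å, 12% noise), 3 → (10 Å, 20% noise),
  spanning the 5–10 Å band the tool targets;
* default case sizes are ~30–50 voxels per side: one helix of 10–18
  residues, one sheet of 3–4 strands × 5–7 residues, or both 15 Å apart.

What the generator does **not** emulate: full-atom density, experimental
CTF/envelope effects, map-to-model misalignment, loops and turns
(background here is mostly empty solvent rather than non-SSE protein), and
crowded multi-chain context.  Passing the desk-scale tests therefore shows
the pipeline learns to separate cylinder-like from slab-like density under
noise and blur — it does not certify performance on experimental EMDB maps.

## Desk-scale benchmark conditions

The end-to-end study (`cryosse.benchmark.desk_scale_benchmark`, run by
`scripts/acceptance.py` and the acceptance test) trains a `base_channels=8`
model on 40 synthetic cases spread over the three quality bins and evaluates
on 10 held-out cases generated from a disjoint seed stream, with a separate
8-case validation split for checkpoint selection (mirroring the full
protocol's train/validation/test partition).  Training uses the phase
epoch budget (28, 18, 18) at a constant learning rate of 1e-3, gradient
accumulation over 4 maps per step, rotation augmentation, and best-epoch
selection on balanced residue-level validation F1.  These settings were
chosen by grid search — the same selection methodology the source protocol
reports for its own unpublished hyper-parameters; without augmentation the
dominant failure mode was sheet density classified as helix in held-out
orientations, which the grid search diagnosis exposed and augmentation
repairs.  A run takes several CPU-minutes.  Run-to-run scatter across
seeds remains visible at this scale (each held-out case carries only tens
of residues), so the benchmark's acceptance test pins its seed;
`scripts/acceptance.py` accepts any seed and reports whatever that seed
yields.  These problem sizes are the package's chosen desk-scale study
conditions; the full-scale protocol (1,216 training chains, 28 test
chains, c = 64) is out of reach without the curated EMDB/PDB corpus.

## Numerical choices and degenerate inputs

* min–max normalisation maps a constant map to all zeros;
* trilinear resampling treats positions outside the source grid as 0;
* padding splits evenly, the odd voxel going to the "after" side;
* probabilities are clipped at 1e-12 inside logs; the soft-dice denominator
  guard treats an absent class as zero loss;
* `gem_project` requires a non-zero memory gradient (all-zero raises);
* checkpoints are single `.npz` files holding weights, the architecture
  configuration, and the class order, versioned for forward compatibility.

## Known limitations

* The numpy implementation is CPU-bound; a full-scale (c = 64) model trains
  impractically slowly compared to a GPU framework, though inference on a
  100³ map completes in seconds.
* Parameter count and receptive field do not match the printed values of the
  original network (whose exact widths are unpublished); see the accounting
  notes above.
* The cylinder-fit quality score is an operationalization, not a recovered
  protocol; bins from it should not be compared numerically to published
  bins.
* Synthetic-data results overestimate performance on experimental maps (see
  the generator's non-goals above).
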