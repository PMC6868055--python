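# Methods

`kinetoforge` is a forward-modeling toolkit for budding-yeast fluorescence
microscopy: parametric 3D structural models generate point-emitter sets,
a Gaussian-PSF renderer turns them into simulated widefield z-stacks, a
fixed preprocessing chain produces 50x50 16-bit RGB images, and two
analysis tracks — a small CNN classifier and a PCA-importance + SVM
protocol — quantify whether model-parameter classes are distinguishable
in image space.

## Spindle / kinetochore model

The metaphase spindle is modeled as one or two half-spindles sharing an
axis (+x by convention, origin midway between the sister plus-end rings).
Each half-spindle has `n_microtubules` (default 16) kinetochore
microtubules (kMTs) whose plus ends sit evenly on a ring of diameter
`complex_diameter` (default 250 nm), each offset axially by an
independent U(-100, +100) nm stagger draw; minus ends lie
`spindle_length` (default 350 nm, the mean kMT length from electron
tomography) further out. For a full spindle the sister half is mirrored
through the midplane with independent stagger draws, its plus-end ring a
`midzone_gap` (default 400 nm) away — the gap stands in for the
metaphase kinetochore-kinetochore separation, which the mirrored
construction otherwise leaves undefined.

Protein placements:

* **Nuf2 (outer kinetochore)** — `n_per_mt` emitters per kMT at axial
  offsets U(0, `length`) nm from the plus end (default 50 nm), on the
  25 nm microtubule surface at uniform azimuth.
* **Spc29 (SPB)** — per half-spindle, `n_tubules` (16) sites on a ring of
  `structure_diameter` (150 nm) at the minus-end plane, each carrying
  `n_fluor_per_tubule` (20) emitters spread uniformly within `length`
  axially and a `tubule_diameter` disc radially. Uniform (rather than
  Gaussian) spread within these extents is an arbitrary but documented
  choice; at PSF scale the two are indistinguishable.
* **Inner-kinetochore protein (Cse4)** — per kMT, `n_arms` straight arms
  from the plus-end rim converge on a single point at straight-line
  distance `arm_length` (70 nm) from the plus-end center, displaced
  `radial_displacement` nm off the microtubule axis; the emitter sits at
  fraction `point_marked` along each arm. The displacement direction is
  radially *outward from the spindle axis* by default: the parameter
  models kinetochores being pulled radially off the spindle, so the ring
  of inner-kinetochore marks dilates deterministically with the
  displacement. A `displacement_azimuth="random"` variant draws a uniform
  azimuth about the kMT axis instead; note that it converts most of the
  class signal into azimuthal noise, and images generated that way are
  far harder to classify. Unbound arms orient uniformly within a cone of
  half-angle `angle_range` about the outward axis.

Rotation (`"none"`, fixed Euler angles, or `"random"`) applies to the
finished emitter set; the experiment drivers keep `"none"` so the spindle
is horizontal in every image, and orientation variety comes from the
dihedral augmentation instead. Plus-end stagger by an explicit
microtubule-dynamics simulation is not supported; only the uniform
random stagger is implemented.

## rDNA polymer model

The genome is a bead-spring chain (2803 beads at ~5 kb/bead; beads 1221 to
1581 are the rDNA locus, 361 beads) confined to a 1 um-radius sphere with
the centromere bead tethered to a point on the envelope. Dynamics are
overdamped Langevin: Hookean springs between chain neighbors
(k = 0.005 pN/nm, rest length 50 nm), drag 1e-5 pN s/nm, kT = 4.1 pN nm,
dt = 2e-4 s (so dt*k/drag = 0.1), and a per-axis thermal kick of variance
2 kT dt / drag. There is no excluded volume and no hydrodynamic coupling;
the governing scheme is the standard minimal one for crosslink-driven
compaction phenotypes. Beads leaving the sphere are projected back to its
surface.

Crosslink springs use a separate, softer constant (0.002 pN/nm). This is
a stability requirement, not a tuning nicety: in the condensed state a
bead carries on the order of twenty link springs, and the explicit
Euler-Maruyama update is stable only while dt times the summed stiffness
over drag stays below ~2. With links as stiff as the backbone the dense
blob periodically "detonates" (Rg jumping 40 -> 550 nm and back within a
second) — a pure integration artifact that contaminates sampled
snapshots. The softer links keep the densest observed state inside the
stability bound; an alternative would be a ~10x smaller dt at ~10x the
cost.

rDNA beads within a 100 nm capture radius form pairwise crosslinks at
attempt rate `k_on` per eligible (non-adjacent, unlinked) pair; each link
draws an exponential lifetime with mean `mu` at creation and is removed
on expiry. Crosslink bookkeeping runs every 20 steps (4 ms, far below all
`mu` values) with the formation probability computed from the elapsed
interval, so the kinetics do not depend on the bookkeeping cadence.
`k_on` and the capture radius are not physical constants of the source
models but calibration choices; `k_on = 0.04/s` with capture 100 nm puts
the three study conditions in visibly distinct states (see below) and
keeps the crosslink-driven compaction monotone in `mu`. At much higher
formation rates the regime inverts — short-lived links churn the chain
compact while long-lived links freeze an extended topology — which
contradicts the compaction phenotype the model exists to reproduce.

The `rdna_only` preset simulates just the 361 rDNA beads with both chain
ends tethered to the anchoring point (the locus hangs as a loop from the
envelope); since rendered images show only the rDNA channel, the rest of
the chain affects them only through weak entropic coupling, and dropping
it makes image-class generation several-fold faster. The full-genome
chain remains available for fidelity runs.

With the defaults (after a 12 s burn-in), the three conditions occupy
distinct regimes: at mu = 0.09 s the locus is an expanded coil (rDNA
radius of gyration ~250-400 nm, only a handful of transient links); at
mu = 0.19 s persistent-enough links accumulate until the locus condenses
into a single moderately dense cluster (Rg ~60-90 nm, a few hundred
links); at mu = 1.6 s the condensate is much denser (Rg ~40 nm, ~3000
links). The collapse is a stochastic nucleation event, so a minority of
trajectories lag (an uncollapsed 0.19 s run) or arrest as several
distinct clusters (a fragmented 1.6 s run) — this residual overlap, not
image noise, is what bounds classification accuracy; the 12 s burn-in
was chosen because by then a 20-seed scan shows no straddlers in any
condition. Every image class still draws on many independent
trajectories (two snapshots per trajectory, 0.5 s apart, by default), so
no single realization can dominate a training or test partition.

## Image simulation

The widefield PSF is approximated as an anisotropic 3D Gaussian with
sigma_xy = 0.21 lambda / NA and sigma_z = 0.66 lambda n / NA^2 (n = 1.515);
at NA 1.4 and lambda 510/580 nm this gives sigma_xy of 76.5/87 nm. The
classification task depends on blur scale rather than PSF tails, which is
why a parametric Gaussian replaces a vectorial PSF model; the two
coefficients are config fields, not constants. Pixels are 65 nm (6.5 um
camera pixels behind a 100x objective); stacks are 7 planes at 300 nm
spacing (the plane spacing is not stated by the source imaging protocol
and is a package default). In-plane emitter mass is integrated exactly
over pixel extents via error-function differences; the axial profile is
point-sampled at plane centers and weighted by the plane spacing, so a
well-centered emitter deposits ~`photons_per_fluorophore` photons in the
stack. Rendering is linear in the emitter set.

`photons_per_fluorophore` defaults to 2000, a bright regime in which
shot noise barely perturbs the geometry: the simulation studies probe
whether structural classes are distinguishable through the optics, so
the emitter brightness is set high enough that photon noise is not the
limiting factor. The camera stage (Poisson shot noise, 3 e- read noise,
100-count baseline) stays enabled for realism; disabling it gives
strictly noise-free renders.

## Preprocessing

Canonical order: center crop to 50x50 -> per-channel maximum intensity
projection -> per-channel min-max rescale to [0, 65535] (constant
channels map to 0) -> duplication into the 8 dihedral orientations
(original first; 90-degree rotations are lossless on square images,
which is why arbitrary-angle rotations are rejected) -> per-channel
median background subtraction, clipped at 0 -> 3x3 local-adaptive Wiener
denoising. The background estimator and Wiener window are package
choices; the source processing chain names the steps but not these
details. Normalization precedes orientation duplication (the two orders
commute for 90-degree rotations, so the ambiguity is moot). GFP maps to
the green RGB slot, RFP to red; blue is unused.

## Feature extraction

Foci are local maxima above median + 5 MAD, pruned to a 3 px mutual
separation and to >= 30% of the brightest candidate's amplitude (noise
bumps in normalized images otherwise pass as a second focus — the same
reason dim younger-SPB images are discarded rather than rescued), then
refined to subpixel centers by a local 2D Gaussian fit with a centroid
fallback. Two kinetochore (green) and two SPB (red) foci are required;
otherwise the image is flagged and excluded, and flags propagate rather
than raise.

The 13 features follow the standard importance-table definitions:
distances use subpixel centers and are normalized by the SPB-SPB
distance; "height" is the FWHM of the minimum-subtracted perpendicular
profile of a 7 (along-axis) x 15 (perpendicular) region about the
brightest pixel, sampled by bilinear interpolation on rotated axes and
max-projected along the axis; line-scan standard deviations use 15 px
lines parallel/perpendicular to the spindle axis; mean/std intensities
use the 5x5 block around the brightest pixel. Per-focus quantities are
averaged over the two foci of a channel to give one record per image.
Two of the published feature descriptions contradict their own names
(kinetochore vs SPB, parallel vs perpendicular); the names are trusted.
The 15 px line length matches the 7x15 region and is otherwise a choice.

## PCA importance and its normalization

Importance of feature i is sum_j coeff_ij^2 * explained_j over retained
components — squared loadings weighted by explained-variance percent.
With all components retained this sums to the total explained variance
(the loadings are orthonormal), and it is invariant to loading signs and
row order.

One property matters enough to flag twice: if the input is z-scored and
all components are retained, importance_i equals the i-th diagonal of the
correlation matrix — exactly 1 for every feature — and the ranking is
undefined. The metric only discriminates while variance differences
survive normalization. The default here is therefore min-max range
scaling to [0, 1]: units disappear (pixel distances vs 16-bit counts),
but a feature split by a class effect keeps an elevated variance and
ranks high. `scale="zscore"` and `scale=None` are available for
comparison and for raw-variance sanity checks respectively.

Validation follows the repeated-split protocol: Gaussian-kernel SVMs
(exact RBF `SVC`, features standardized on the training fold; C = 1,
gamma = "scale") on 30 stratified 70/30 splits per feature subset
(all 13 / top 2 / bottom 2), compared with two-sided Wilcoxon rank-sum
tests. Stratification is a deliberate deviation from plain random
splitting: it prevents degenerate single-class folds at small n. An
exact-kernel SVM stands in for a random-feature-expansion approximation
of the same kernel; the protocol's conclusions concern accuracy
distributions, not solver internals.

## CNN

Three blocks of [3x3 conv, stride 1, same padding, filters 8/16/32 ->
batch norm -> ReLU -> 2x2 max pool, stride 2], with the third block's
pool replaced by a fully connected layer into softmax. Spatial sizes run
50 -> 25 -> 12 (floor division), so the FC layer sees 4608 inputs.
Training is SGD with momentum 0.9, initial learning rate 0.01, up to 20
epochs, L2 1e-4 on conv/FC weights, validation accuracy recorded every
30 iterations. Weights are Glorot-uniform from a seeded generator;
16-bit images are scaled to [0, 1] floats; batch-norm inference uses
running statistics (momentum 0.1) and no statistic is ever taken from
validation or test data. The implementation is plain numpy (im2col
convolution with full backprop) — the network is small enough that one
CPU core trains desk-scale datasets in about a minute.

Counting learnable-weight layers depends on bookkeeping: 7 weighted
modules (3 conv + 3 batch-norm + 1 FC), or 13 learnable tensors once the
batch-norm scale/shift pairs and biases are itemized. The block structure
above is the specification; the count is presentation.

`TrainConfig` keeps minibatch 128 (the training environment default the
protocol inherited), but the experiment drivers default to minibatch 32:
at 10^3-image desk scale, 20 epochs of batch-128 training is only ~10^2
SGD updates, far short of convergence, while batch 32 restores an
adequate update count without touching the learning-rate or epoch
settings.

Splitting is stratified 56/24/20 (train/validation/test) by
largest-remainder rounding per class. The experiment drivers split whole
source stacks, not individual images: the 8 dihedral orientations of one
stack are near-duplicates, and an image-level split would put a test
image's siblings into training with the same label — enough leakage that
even two identically parameterized classes classify near-perfectly by
memorization (measured), where the indistinguishable-classes control
must sit at chance. Group splitting restores that control without
costing accuracy on genuinely distinct classes. `split_dataset` itself
remains an item-level operation; drivers expand stack-level splits to
image indices. Driver datasets are balanced by construction (equal stack
counts per class); `balance_classes` (seeded downsampling to the
smallest class, applied before splitting) is for imbalanced external
image sets.

## Experiment drivers and scales

* `run_kinet_radial` — classes are Cse4 radial displacements
  {0, 25, 50, 100} nm; each class gets `images_per_class // 8` model
  draws x 8 orientations. Desk scale is 400 images/class (~1.5 min end
  to end); the published study used ~14k/class. With the outward
  displacement geometry the desk-scale CNN reaches ~99-100% validation
  accuracy.
* `run_nucleolus_mu` — classes are mu in {0.09, 0.19, 1.6} s on the
  rDNA-only preset; images come from ~19 independent trajectories per
  class (2 snapshots each, 0.5 s apart, 12 s burn-in). Desk scale is
  300 images/class (~9-10 min, dominated by the polymer integrator).
* `run_feature_analysis` — two image classes, feature extraction (>50%
  flagged aborts), importance ranking, and the three-subset SVM
  comparison. Only one orientation per source stack enters the feature
  table: the 13 features are invariant under the dihedral orientations,
  so the other seven would be exact duplicate rows leaking across the
  SVM's train/test splits.

A sub-70% classification accuracy is annotated in the report manifest as
"iterate" rather than raised as an error, mirroring the go/no-go gates of
the overall workflow.

## Determinism

Every stochastic stage derives its generator from an explicit seed
through `numpy.random.SeedSequence` spawning (per-model, per-trajectory,
per-noise-draw, per-split, per-repetition). Polymer trajectories use
separate thermal and crosslink sub-streams so linking kinetics are
comparable across thermal realizations. Reports are bit-reproducible
from their manifests on a single thread; multi-threaded BLAS reductions
can introduce last-ulp differences in CNN training.

## Known limitations

* The Gaussian PSF has no aberrations, no spectral bleed-through, no
  vignetting; conclusions about real microscopes need a measured PSF.
* The polymer model's `k_on`/capture radius are calibrated, not
  measured; only the mu-ordering of compaction, not absolute cluster
  statistics, is meaningful.
* Simulated images are far cleaner than experimental ones (perfect
  segmentation, centered structures, no cell background). Passing
  desk-scale classification shows the method separates the model
  classes, not that it would classify experimental images at the same
  accuracy.
* Synthetic feature tables used in the recovery tests plant independent
  Gaussian features; real feature tables are correlated, where the
  importance ranking is harder to interpret.
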