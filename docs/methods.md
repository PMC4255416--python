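# Methods

## Phantom model

The synthetic head is an analytic nested-ellipsoid geometry on a regular
voxel lattice.  The brain is an ellipsoid (default semi-axes 60 × 72 × 54 mm,
≈ 977 cc, at 1.5 mm isotropic voxels; a coarse 2 mm "small" variant of
54 × 66 × 48 mm ≈ 729 cc is used throughout the tests to keep simulation
batches cheap).  Shells are carved by exact Euclidean distance from the
brain surface: the outermost 3 mm is subdural/sulcal CSF, the next 5 mm a
cortical grey-matter shell, and the remainder deep white matter carrying two
mirrored ventricular ellipsoids.  Volumes are therefore analytic up to voxel
quantization, which is what makes the ST-TIV and volumetric identities
checkable to a stated tolerance rather than against another segmentation.

Lesions are implanted into white matter only:

- **Periventricular lesions** are grown voxel-by-voxel from a seed placed one
  step outward of the ventricle surface along a configured direction, taking
  the *k* nearest white-matter voxels for a target of *k* × voxel volume.
  Seeded on the surface, they are guaranteed to touch the ventricle, so
  their periventricular ground-truth status is unambiguous.
- **Deep-white lesions** grow around a configured centroid restricted to
  voxels more than a configurable Chebyshev gap (default 3 voxels) from the
  ventricular mask, so the connectivity classifier has a single correct
  answer.  Implanted components are kept 26-disconnected from one another.
- **Lacune cores** replace the voxels of a parent lesion nearest its
  centroid, restricted to voxels at Chebyshev distance ≥ 2 from ventricular
  CSF.  The restriction exists because a centroid core of a ventricle-hugging
  lesion can otherwise touch the ventricle, and its CSF-dark voxels would
  flood-fill into the ventricular compartment — making the ground truth
  itself ambiguous rather than the segmentation wrong.

Every placed structure's realized volume is within one voxel volume of its
target (the lattice quantization step), and identical spec + seed yields
bit-identical volumes (one named RNG stream per modality derived from the
global seed).

Intensities are class-conditional Gaussians per modality in arbitrary
units: on T1, CSF 40 < GM 100 < WM 140 with lesions WM-like (140) and lacune
cores CSF-like (40); on PD (WM 95) and T2 (WM 80) the lesion classes sit
35–60 units above WM, and lacune cores are bright on both (cystic fluid).
Noise levels in tests are expressed as a fraction of the smallest adjacent
gap between class means of each modality — the natural difficulty axis for a
threshold-based detector — with {5, 10, 20, 40}% grades.  Noise is additive
Gaussian; Rician bias, field inhomogeneity, partial-volume mixing and motion
are deliberately absent: the phantoms verify the *algorithms*, not scanner
realism, so a Dice of 1.0 at zero noise demonstrates correctness of the
label-flow logic, not expected performance on clinical scans.

## Brain extraction

Foreground is thresholded at the lowest multi-Otsu cut (4-class, falling
back to 3-class then plain Otsu when the histogram has too few grey levels).
Plain Otsu is a poor head/background split on a strongly multimodal T1
histogram — it tends to land between CSF and parenchyma and shave off the
subdural CSF shell, which belongs inside the intracranial cavity by
definition.  The largest 26-connected component is closed (1 iteration),
hole-filled (ventricles and any interior cavity are intracranial), and
closing accretions that were never foreground are discarded so the
zero-noise mask is exactly the voxelized brain.  A subtentorial exclusion
mask input represents cerebellum removal; phantoms contain no subtentorial
compartment, so it defaults to a no-op.  ST-TIV is voxel count × voxel
volume.

## Tissue segmentation

The in-mask T1 histogram is fitted with a four-component 1-D Gaussian
mixture by EM — globally and within overlapping cubic windows (default 32³
voxels, stride 16, i.e. 50% overlap; windows with fewer than 500 in-mask
voxels inherit the global fit).  EM runs on a 256-bin histogram (equivalent
to weighted EM on the samples at far lower cost), initialized
deterministically from the 5/35/65/95% intensity quantiles, with a relative
log-likelihood tolerance of 1e-6, at most 200 iterations, and an SD floor of
10⁻³ of the intensity range to stop components collapsing on noise-free
data.

Three of the four components carry CSF / GM / WM; the fourth models the
partial-volume shoulder.  The partial component is identified as the lighter
member of the closest pair of global component means — dropping it leaves
the three most separated components as the class centroids.  Each *window*
component is then snapped to the nearest global class centroid and the
window's class posteriors blended across overlapping windows with trilinear
hat weights (a partition of unity on the window lattice).  A per-voxel
posterior-odds merge of the partial component was considered and rejected:
when a window's local histogram is unimodal (deep inside white matter) all
four components collapse onto one mode, a mean-rank mapping mislabels the
entire window, and odds between two equal posteriors are undefined.  The
proximity rule handles these windows exactly and reduces to the same answer
as the odds rule when the partial genuinely sits between two classes.

Ventricular CSF is the union of 26-connected CSF components containing a
ventricle seed; all other CSF is sulcal.  On phantoms the seeds come from
ground truth; on other data they are operator-supplied coordinates —
automatic ventricle detection is out of scope.

## Lesion segmentation

WM reference statistics on PD and T2 are the mean/SD over WM-labelled voxels
(lesions contaminate this reference by construction, but at realistic lesion
loads of ≲2% of WM the inflation is negligible; this matches how the
reference must be obtained when no lesion mask exists yet).  A voxel is SH
iff it is intracranial, not ventricular CSF, not exterior
(boundary-connected) sulcal CSF, not in a majority-GM 26-neighbourhood
(cortical false-positive control), and exceeds WM mean + z·SD on *both* PD
and T2 (z = 3 default; the joint requirement suppresses single-modality
noise spikes).  Interior CSF-labelled islands stay eligible on purpose:
lacune cores are CSF-dark on T1 but hyperintense on PD/T2, and must first be
captured as SH.  Components below 5 voxels are discarded as speckle.

pv/dw classification: components (26-connectivity default, configurable to
6/18) are periventricular iff their minimum Chebyshev distance to the
ventricular mask is ≤ 1 voxel, computed with a chessboard distance
transform.  The test suite checks this against an independent
dilate-and-intersect oracle on random 50-component scenes.

Lacunes: SH voxels with T1 below CSF mean + 2·CSF SD (global-fit CSF class)
are relabelled; they are reassigned, never created, so
pvSH + dwSH + lacune = detected SH exactly.  Lacune components record the id
of the SH component they were carved from.

## Parcellation

A plane-based geometric analog of landmark parcellation: sagittal midline
(mask centroid by default), coronal cuts at fractions (0.35, 0.75) of the
anterior-posterior extent, a temporal split at 0.55, axial cuts at
(0.40, 0.62, 0.80) of the inferior-superior extent, and a medial band of
0.30 of the hemisphere half-width.  Thirteen named regions per hemisphere
(five frontal, two temporal, two parietal, three occipital, one central
basal-ganglia/thalamus block) give exactly 26 disjoint VOIs covering the
mask.  Anatomical fidelity to any published atlas is a non-goal; the
contract is the interface: 26 named regions with lobar groupings whose
volumes are additive to whole-brain volumes (a lesion splitting across
regions contributes each voxel where it lies).  "Left temporal" aggregates
left anterior + posterior temporal, matching the lobar-combination analysis
style.

## Volumetrics and normalization

Profiles are exact voxel counts × voxel volume.  BPF uses parenchyma =
GM + WM as segmented (lesion classes are tallied separately and not folded
into parenchyma).  Head-size normalization is proportion-of-ST-TIV; a
residual-regression alternative can be swapped in via the `normalize` flag.
A variable whose reference-sample skewness (adjusted Fisher-Pearson) exceeds
1.0 is log-transformed with offset equal to the smallest positive observed
value — chosen so the many zero lesion volumes typical of control samples
stay finite.  Z-scores use reference-sample mean/SD; the reference defaults
to controls only (matching the cognitive-composite convention), and
variables with zero reference variance are excluded with a logged reason
rather than propagating NaNs.

## Statistics

- **Composites**: each test z-scored against the control sample, oriented so
  higher = better (times and error counts are sign-flipped), then averaged
  within domain over available tests.
- **ANCOVA**: OLS of outcome on a group indicator + covariates (age, sex,
  education by default), reporting the adjusted group coefficient and test.
- **Cohen's d**: pooled-SD convention; magnitude |d| for tables.
- **Backwards elimination**: at each step the candidate with the largest
  p > α (default α = 0.05; ties broken toward the smaller |β|) is removed
  and the model refitted until all survive; forced covariates are never
  candidates (configurable).  β is standardized by z-scoring outcome and
  predictors; per-predictor R² is the squared partial correlation
  t²/(t² + df).  An α of 0.10 is a documented alternative: published tables
  of this analysis style sometimes retain a term at p = 0.06, implying a
  laxer threshold; the choice is configurable rather than guessed.
- **Stepwise VOI screening**: stage 1 eliminates among the four lobar
  aggregates (standardized sums); stage 2 refits within each surviving
  lobe's subregions, at most six VOI terms per model.
- **Partial regression**: residuals of outcome and focal predictor on the
  covariates; by Frisch-Waugh the residual-on-residual slope equals the
  joint-model coefficient, and the tests assert that identity to 1e-10.

No multiple-testing correction is applied by default, matching the analysis
style the package reproduces; a Holm adjustment can be layered on the
reported p-values by the caller.

## Cohort generator and power considerations

Cohorts are linear-Gaussian: per-group (mean, SD) base variables (Bernoulli
for binary ones such as sex), outcomes built from explicit
(outcome, predictor, coefficient) edges plus Gaussian noise, in dependency
order.  `standardized_effects_spec` puts predictors on N(0,1) and scales the
residual so the outcome has unit variance — planted coefficients are then
standardized βs and recovery tests are calibrated against Monte-Carlo
standard errors.

`voi_cohort_spec` gives each lobe's subregions a shared latent factor with
loading √0.5 (pairwise within-lobe correlation 0.5).  This is a realism
choice with a power consequence: neighbouring regional lesion loads are
strongly correlated in real data, and the lobar screening stage relies on
it.  With five *independent* subregions, a single-region standardized effect
of 0.3 dilutes to a lobar correlation of 0.3/√5 ≈ 0.13 — about 55% power at
n = 250 — whereas at ρ = 0.5 the aggregate retains corr ≈ 0.23 and the
two-stage localization succeeds in well over 80% of runs, which is the
regime the screening strategy was designed for.

## Problem sizes

Defaults used by the test suite and the acceptance script: 2 mm phantoms
(64 × 76 × 64 voxels) for segmentation batches and a 2.5 mm variant for the
noise-sweep property test; 5 seeds per stochastic segmentation claim; 1000
null replicates for type-I error; 200 replicates for coefficient recovery
and stepwise localization at the cohort sizes n = 265 / 250.  These sizes
were chosen so the entire suite, including every simulation, completes in
well under a minute of compute per module while keeping Monte-Carlo
standard errors small relative to the tolerances asserted.

## Known limitations

- Phantom anatomy is convex-ellipsoidal; no gyrification, no partial-volume
  mixing, no bias field.  Zero-noise exactness is a statement about label
  flow, not clinical accuracy.
- The brain extractor assumes a skull-free scene and is not a clinical
  skull-stripper.
- The parcellation is geometric; regional results on real anatomy would
  require a registration- or landmark-based atlas behind the same
  interface.
- WM reference statistics are lesion-contaminated by design (no prior
  lesion mask); at high lesion loads the z-threshold becomes conservative.
- Whether the speed composite's orientation should differ between clinical
  groups (opposite-signed age coefficients appear in published analyses of
  this design) is not resolvable from summary tables; the package keeps one
  orientation convention (higher = better) for all groups.
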