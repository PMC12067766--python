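# Methods

## The problem and the model

Rod/ring (RR) assemblies of enzymes such as IMPDH2 appear in single-channel
fluorescence micrographs as two morphological classes: elongated rods and
annular rings, both bright on a near-dark cytoplasmic background. The
pipeline treats their quantification as two-class semantic segmentation
followed by contour-based morphometry.

The segmentation model is a UNet: an encoder of `depth` stages (each a pair
of 3×3 convolutions with batch normalisation and ReLU, followed by 2×2 max
pooling), a bottleneck, and a mirror-image decoder that upsamples by
nearest neighbour, concatenates the encoder skip at the same resolution and
applies another convolution pair. A final 1×1 convolution emits two logit
channels (rod, ring); the logistic function maps them to per-pixel
probabilities. The two channels are independent sigmoid outputs rather than
a softmax: a pixel's class scores are thresholded separately, matching the
annotation format of one binary mask per class. The head's bias is
initialised at −3 (a background-prior logit): RR pixels are a rare class
(a few percent of each frame), and starting near the base rate saves the
early epochs a zero-initialised head would spend learning it.

Everything is implemented in numpy (`rrseg.nn`): convolutions via im2col
patch matrices so both passes are single BLAS matrix products, with
activations stored channel-outermost `(C, N, H, W)` so the patch matrix is
assembled from nine contiguous slice copies. Gradients are hand-derived and
verified against finite differences in the test suite's development; Adam
is the optimiser. Training is single-threaded-deterministic: weight
initialisation, batch order and the generator all draw from seeded
`numpy.random.Generator` streams.

### Training protocol

The dataset is split into k disjoint folds of near-equal size (k = 5 at
full scale). One member trains per fold on the remaining k−1 folds; its
fold is scored each epoch but never influences any optimisation decision.
Because each image lies in exactly one fold, collecting each member's
predictions on its own fold yields exactly one out-of-sample prediction per
image. Optimisation uses Adam at an initial learning rate of 0.001 decaying
exponentially — the rate at epoch *e* is 0.001 × 0.999ᵉ, i.e. 99.9 %
retained per epoch. The loss is mean per-class binary cross-entropy on the
two channels (default); a soft-Dice loss is available as
`TrainingConfig(loss="dice")`. Epochs (default 15) and batch size (4) are
configuration, not protocol.

### Inference

Member probability maps are averaged per pixel and per class, and the
averaged map is thresholded at 0.2 (a pixel exactly at the threshold is
positive). The low threshold compensates for the ensemble's tendency to
over-predict the dominant background class. Averaging happens on the
probability scale by default because the 0.2 threshold is only meaningful
there; raw-logit averaging (logistic applied after the mean) is available
via `Ensemble(average="logit")` and matters only when members disagree
strongly.

## Preprocessing and the cross-microscope pipelines

Inputs are resized bilinearly to the model frame (512×512 at full scale;
the frame side is a parameter so reduced studies can use 128). No intensity
normalisation is applied at any point — pixel values change only through
interpolation — because normalising these images degrades segmentation.

For a microscope whose pixel size differs from the training reference
(0.192 µm/px over a 1024-px, ≈196.6 µm field), two pipelines exist:

- **fixed magnification**: resize the full frame to the model input. An
  object's pixel extent then scales with the acquisition field of view and
  the model sees out-of-domain object sizes.
- **fixed pixel size**: place the frame on a canvas of
  `ref_field_um / pixel_size_um` pixels — centre-padded with zeros when the
  field is smaller than the reference, centre-cropped when larger — then
  resize. An object of physical size *d* ends up with the same model-frame
  pixel extent it would have had on the reference microscope.

Masks follow the same geometry with nearest-neighbour resampling
(`transform_masks`), preserving binarity. Padding uses 0 (fluorescence
background is dark) and the pad/crop anchor is the field centre, recorded
in each `ModelInput`'s provenance. Batch normalisation makes the network
effectively indifferent to the padded region: a constant-zero area
normalises to strongly negative activations and produces near-zero class
probability.

## Morphometrics

Connected components are extracted at 8-connectivity (thin diagonal rods
stay connected). Each component's outer boundary is traced as a
marching-squares iso-contour at level 0.5 on a zero-padded crop; when a
component yields several closed contours (a ring and its lumen), the one
enclosing the largest area is the outer boundary and hole boundaries are
discarded — lumen edges do not contribute to perimeter. Conventions:

- **area** = component pixel count × pixel_size² (µm²). Pixel counting is
  robust for 1–2-px-wide objects where a vertex-polygon shoelace area is
  badly biased.
- **perimeter** = arc length of the traced boundary polygon × pixel_size
  (µm). On a pixel grid this overestimates smooth contours by a few
  percent (≈5 % for a radius-16 disc), shrinking with object size.
- per-object perimeter:area ratios are averaged per class (not the ratio
  of the means); the rod:ring ratio is `n_rods / n_rings`.

Per-class means are undefined for an image with zero objects of the class,
and the rod:ring ratio is undefined without rings; these propagate as
missing values rather than zeros. There is no minimum-object-size filter by
default; `min_area` is available where tiny spurious components must be
suppressed. Counts are the robust measurement at this resolution — for
few-pixel objects one disputed pixel moves area and perimeter by tens of
percent and quantises the possible ratio values, so area/perimeter
agreement between annotator and model is expected to be much weaker than
count agreement.

## Evaluation

Dice (2|P∩T|/(|P|+|T|)) and Jaccard (|P∩T|/|P∪T|) are undefined when both
masks are empty; for an image genuinely free of RRs this corresponds to a
*perfect* segmentation, so two aggregation policies are provided: `exclude`
(drop undefined images; the primary convention) and `set_to_one` (count
them as 1.0, which credits correct empty predictions at the price of an
artefactual mode at 1.0 in score histograms). If every image is undefined
under `exclude`, aggregation signals "no evaluable images" instead of
returning a number. Reported spreads are sample standard deviations.

ROC curves are computed per image over all pixels of a class probability
map; images whose truth contains one class have no ROC and are excluded,
mirroring the Dice policy. Curves are averaged vertically: each TPR is
interpolated onto a fixed 101-point FPR grid (resolution versus cost) and
mean and SD taken per grid point. The primary AUC summary is the mean of
per-image AUCs; the area under the averaged curve is also reported since
the two differ in general.

"R²" between truth-derived and model-derived measurement vectors is the
squared Pearson correlation — the strength-of-correlation reading used on
agreement scatter plots, invariant to affine miscalibration. A
coefficient-of-determination-against-identity mode is available for when
systematic offsets should be penalised. Images with a missing value in
either vector are dropped pairwise.

## The synthetic generator

The generator emulates the features of RR micrographs that drive the
pipeline's behaviour: rods are capsules — pixels whose centres lie within
width/2 of a centreline segment, so a rod of shaft length L and width w has
continuous area L·w + π(w/2)²; rings are annuli with outer radius R and
wall t, area π(R² − (R−t)²). Pixel membership is by pixel-centre inclusion,
which makes rendered areas converge to these closed forms as objects grow
(the quantisation error is large for few-pixel objects, intentionally
reproducing the measurement-granularity caveat above). Objects are placed
uniformly at random; with overlap disallowed, placements keep a
2-px minimum separation so ground-truth component counts are exact by
construction, and rod and ring masks are disjoint. Intensities add onto a
constant background, a Gaussian blur of σ 0.6 px approximates the PSF
(≈0.12 µm at the reference pixel size), and zero-mean Gaussian noise
(clipped at zero, as a camera clips) models the detector. Ground-truth
masks are the pre-blur pixel sets: blur models optics, not object extent,
matching how an annotator labels the visible core of a structure.

Default conditions (all configurable): 128-px frames at 0.192 µm/px, 2–10
rods and 2–10 rings per frame, rods 1–4 µm long and 0.3–0.6 µm wide, rings
of 0.8–1.5 µm outer radius with 0.2–0.4 µm walls, object intensities
80–200 counts on a background of 8 with noise SD 6. Two choices deserve
comment. The background is near-dark because exported fluorescence
micrographs have close-to-black backgrounds; this also keeps the zero
padding of the fixed-pixel-size pipeline statistically close to real
background. The ring lower radius is 0.8 µm with walls capped at 0.4 µm so
every ring keeps a lumen of at least ~2 px at the reference pixel size: an
annulus whose hole is below the sampling grid is indistinguishable from a
filled blob, which would make the class boundary between "small ring" and
"stubby rod end" undefined for annotator and model alike — and the ring
class ill-posed rather than merely hard.

Two experimental regimes are layered on the generator: a differentiation
time course that scales the object-count ranges by per-timepoint
multipliers in [0, 1] (a multiplier of 0 produces genuinely empty frames,
the case that exercises the empty-mask policies), and a simulated second
microscope that re-samples the same physical field onto a grid with a
different pixel size (bilinear for intensities, nearest for masks).

What the generator does *not* emulate: real PSF anisotropy and diffraction
side-lobes, intensity variation within an object, autofluorescent cytoplasm
and nuclei, annotator bias and inconsistency, out-of-focus light, and the
JPEG compression some acquisition pipelines introduce. Passing tests on
synthetic data therefore demonstrate that the machinery — training
protocol, ensemble inference, preprocessing geometry, metrics — behaves as
designed, not that any particular accuracy will transfer to a given real
dataset.

## Desk-scale study conditions

The self-contained study run by `scripts/acceptance.py` and the acceptance
tests uses 80 synthetic 128×128 images, a k = 2 ensemble of depth-3,
16-channel UNets, 15 epochs at batch 4 — about six minutes of single-core
training — rather than the full-scale 287-image, 512×512, k = 5
configuration, which the package also supports but which is not needed to
exercise any mechanism. Cross-microscope robustness is probed by re-imaging
20 held-out fields at 2× finer pixel size on the same-sized grid (half the
field of view, as a higher-magnification objective gives) and comparing the
two preprocessing pipelines under identical models.

Measurement agreement is assessed two ways: count R² over the
cross-validated held-out predictions (single-member, fixed density), and
count R² under the deployment protocol — full-ensemble inference on a
fresh synthetic differentiation time course whose density multipliers run
1.0 → 0 — which is the setting where count agreement is strongest and
where correctly empty predictions on empty frames anchor the comparison.
The gap between the two is informative: at short training schedules the
single members' residual ring-channel cross-talk (see Known limitations)
inflates ring counts, while ensemble averaging and the density gradient
recover strong agreement.

## Numerical and design notes

- Thresholding uses ≥, so a pixel exactly at the threshold is positive.
- `make_folds` partitions a seeded permutation with `np.array_split`,
  guaranteeing fold sizes within one of each other.
- Member seeds are derived from the training seed and fold index; two runs
  with the same seeds are bit-identical in single-threaded execution.
- BCE is computed in its numerically stable logit form
  max(z,0) − z·y + log(1+e^−|z|).
- Checkpoints are single `.npz` files embedding the architecture config,
  member seeds, all weights and batch-norm running statistics.
- Degenerate inputs: empty masks yield empty polygon lists and missing
  means; single-class truth yields an undefined per-image AUC; an
  all-undefined metric list under `exclude` raises rather than averaging
  nothing.

## Known limitations

- The training loop is CPU-bound numpy; full-scale 512×512, k = 5 training
  is possible but slow (hours, not minutes).
- Perimeters carry a small systematic positive bias from contour tracing
  on the pixel grid; comparisons between pipelines are unaffected, absolute
  perimeters of small objects should be read with that in mind.
- At short training schedules the two class channels retain weak
  cross-talk: a member's ring channel can respond at just above threshold
  on rod end-caps, which inflates ring counts more than ring Dice.
- The 3D structure of cells is ignored; inputs are 2D projections, and
  objects overlapping in projection merge.
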