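# Methods

## Data model

A sample is four co-registered 8-bit grayscale images of one microscopy
field: `blue` (nuclei), `green` (protein of interest), `red`
(microtubules), `yellow` (endoplasmic reticulum), with a label set drawn
from 28 subcellular localization classes. Labels are stored as sets
(serialized in ascending order); loading validates the four channel files
per sample and the label range, aborting on any inconsistency rather than
dropping records silently.

## Phase-1 split

Phase 1 uses only single-label samples. Classes with at least 275 samples
contribute exactly 250 random samples to training; smaller classes
contribute `floor(0.8·count)`. This balances training while leaving the
test side imbalanced, mirroring deployment conditions. A class whose
allotment is zero (a single sample) is flagged unusable. The split is a
pure function of the seed.

## Channel compositions and resizing

Six 3-plane compositions per sample: each channel replicated threefold,
the red/green/blue channels mapped onto the R/G/B planes of a color
composite (natural color order — the plane assignment is a fixed
convention recorded in the block identifiers), and the unweighted
pixelwise mean of all four channels (computed in float, rounded half-up).
Inputs are resized to each extractor's geometry (224², 227² or 299²) by
bicubic interpolation with the result clamped to [0, 255]; clamping rather
than rescaling was chosen so that constant regions stay constant and
calibration of 8-bit intensities is preserved.

## Segmentation

Nuclei are segmented on the blue channel. The default backend is
classical: Gaussian smoothing (σ = 1), Otsu threshold with degenerate-
foreground rejection, hole filling, connected components and an optional
watershed split (`mean_diameter_px` = 55 guides the marker spacing). A
`cellpose_nuclei` backend name is reserved for the external deep model and
errors out with a pointer to the fallback when that package is absent.
ROIs smaller than 100 px or touching the frame (any true pixel in row or
column 0 or max) are removed; both filters are idempotent and commute.
The perinuclear ring is `dilate(mask) AND NOT erode(mask)` with the
13-pixel discrete disk of radius 2 inscribed in a 5×5 window — libraries
differ on what "5×5 disk" means, so the footprint is pinned and tested
against an exhaustive pixel oracle. Masks computed at low resolution are
projected to full resolution by nearest-neighbor upscaling (bicubic would
create non-binary values); crops zero all pixels outside the mask. When
one cell must represent an image (a phase-1 economy), the ROI with the
lower-median area is chosen, ties broken by lowest ROI id.

## Feature blocks

A feature block is the 1000-value output of one extractor on one source
image. The registry holds 12 extractor names in a fixed canonical order
(written into every artifact — chromosomes are meaningless without it);
sources are the 6 compositions (image level) or the nucleus/ring crops of
the green channel (cell level), giving 72 and 24 blocks. Raw final-layer
activations are used without softmax; standardization is deferred to the
classifier stage. Block matrices are float32 with columns grouped per
block; slicing by a chromosome preserves block order.

Mock extractors make the pipeline self-contained: a signal-bearing mock
writes 32 region/shape statistics of its input (intensity moments,
coverage at several thresholds, boundary-to-area ratio, thickness,
component and hole counts) into its first entries; everything else —
including the entire output of a non-signal mock — is pseudo-noise fixed
by (name, seed), so a zero image reproduces the seeded baseline exactly
and non-signal blocks carry no class information. A mock may be further
restricted to a subset of the 32 statistics; the planted-recovery study
uses mean-intensity-only blocks so that no single block can separate all
three pattern families and the search must combine complementary
nucleus- and ring-source blocks.

## Genetic block selection

Chromosomes are binary inclusion vectors (length 72 or 24; all-zero
vectors are repaired by flipping one random bit, since an empty feature
set has no defined fitness). Per generation the 16 individuals are
randomly permuted into 8 mating pairs; single-point crossover draws its
cut uniformly from the interior positions {1, …, L−1}; exactly 2
offspring (0.125 × 16), chosen uniformly without replacement, receive a
single-bit mutation. Any offspring duplicating a previously considered
solution — the global archive plus the current generation's offspring —
is mutated again until novel (bounded at 10·L attempts so exhausted tiny
search spaces terminate; unreachable at production lengths). Each
generation therefore evaluates 16 fresh chromosomes: 400 offspring
evaluations over 25 generations, with the initial population scored once
at generation 0 and not counted. Selection is family-local: the best two
of {two parents, their two offspring}, ties preferring offspring to bias
exploration. Family elitism makes the running best monotone.

Fitness is the held-out macro-F1 of an OAO linear-SVM ensemble on the
selected blocks. Inside the GA the SVM penalty is fixed at C = 1 — running
the full C grid inside each of 400 evaluations would multiply cost
twentyfold for little ranking change — while final reported models re-tune
C on the grid.

## Stage-1 classifiers

Standardization is Z-scoring with population standard deviation, floored
at 1e−8 so constant columns map to zero. Statistics are always fit on
training rows only; during cross-validation each fold fits its own
statistics (retained for audit), and the final refit uses global training
statistics. OAO trains one linear SVM per class pair (target 1 ⇔ the
pair's lower-index class), predicts by majority vote with ties to the
lowest class index, and carries a per-pair Platt-style sigmoid calibrator
(unregularized logistic fit on training decision values) so each output
reads as the probability that the lower-index class wins — these are the
stacked features. OAA trains one-vs-rest models and predicts by argmax
decision value. C is selected by mean cross-validated macro-F1 over a
{0.01, 0.1, 1, 10} grid with 5 folds (reduced to the smallest class count
when classes are tiny), ties to the smaller C; classes with fewer than two
samples are excluded with a warning.

## Stage-2 stacking

The image-level second-level vector is the calibrated pairwise-score
vector of the image-level OAO models (length N(N−1)/2; 276 at N = 24).
The cell-level vector applies the cell-level OAO models to every valid
segmented cell (post-filter survivors; no representative-cell restriction
in phase 2) on the nucleus + ring crops and averages element-wise —
permutation-invariant over cells. An image with zero valid cells yields
the neutral 0.5 vector with a flag: 0.5 is the uninformative calibrated
pairwise probability. Phase-2 scoring reuses the frozen phase-1
standardization statistics. Fusion concatenates image then cell (552 at
N = 24). No further standardization is applied: the features are already
probabilities in [0, 1].

## Multi-label stage

The 80/20 split uses greedy iterative stratification: labels in
increasing frequency order, each sample assigned to the side with the
largest remaining demand for that label, ties by larger remaining global
budget then a seeded coin; pinned ids (the phase-1 training set) are
placed in training first. Binary Relevance fits one binary classifier per
label (absent labels get an always-negative stub); an empty prediction
falls back to the single most confident label, since an empty set would
zero recall unfairly. Label Powerset encodes each observed label
combination as one multiclass target, so it can never emit an unseen
combination. Base learners: linear SVM (single shared C tuned by 5-fold
CV on the grid), logistic regression, decision tree and kNN at library
defaults, k ∈ {1, 3}. Evaluation reports per-class precision/recall/F1
plus macro means over the *full* class list (a class absent from the test
split contributes zero) and support-weighted means.

## Synthetic fixtures and what they show

The generator plants disjoint elliptical nuclei in the blue channel and
paints the green channel by pattern family: inside nuclei (nucleoplasm-
like), a 1–5 px annulus outside the nuclear boundary (membrane-ring-like)
at the same stain intensity as the nuclear family — so intensity alone
cannot distinguish them and location information is genuinely required —
or diffuse texture away from nuclei (cytoplasm-like). Red/yellow carry
label-independent smooth texture; multi-label samples superpose patterns;
Gaussian pixel noise is added per channel. The generator is a pure
function of its seed, down to file bytes.

What it does not model: point-spread blur, uneven illumination, touching
or overlapping nuclei, cell-to-cell expression variability, and the true
28-class frequency spectrum. Passing the end-to-end studies therefore
demonstrates that the pipeline's machinery — splitting, selection,
stacking, fusion, evaluation — is correct and that fusion helps when the
two levels carry complementary information; it does not predict absolute
accuracy on real microscopy data.

## Study sizes and numerical choices

Studies run on 96-px images with ~90–120 samples and 3 classes: large
enough that the three families are estimable per split, small enough that
the GA recovery study (10 runs × 400 evaluations) and the 5-seed
end-to-end study complete in minutes on one CPU. Tolerances: fitness and
metrics compared exactly where deterministic; the fusion-dominance check
allows a 0.05 seeded tolerance on 5-seed means. Degenerate inputs are
handled explicitly: blank images segment to zero ROIs, all-zero
chromosomes are rejected at slicing and repaired inside the GA,
constant feature columns standardize to zeros, single-combination Label
Powerset training yields a constant predictor.

## Known limitations

- The mock extractors' statistics are hand-designed for the three
  synthetic families; real backbones are pluggable but unvalidated here.
- The classical segmentation backend assumes well-separated bright
  nuclei; clumped nuclei need the optional watershed split or an external
  model.
- BR's confidence fallback compares decision values across per-label
  models, which are not strictly commensurable scales.
- Iterative stratification is the greedy single-order variant; it does
  not re-optimize earlier assignments.
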