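# Methods

This note documents the model implemented by `necromap`, the choices
made where the design was genuinely open, the synthetic data the tests
run on, and the known limits of both.

## The estimation problem

A subject contributes up to eleven co-aligned images: three conventional
MR sequences (post-contrast fat-saturated T1 "PC", T1, STIR) and eight
maps derived from advanced MRI — the apparent diffusion coefficient from
multi-b DWI, three DCE subtraction frames, the steepest slope and 100-s
area under the DCE time–intensity curve, and the Tofts parameters
K^trans and v_e. The target is the fraction of tumor that is
histologically necrotic, available at training time as a categorical
viability map of the primary histologic section (necrotic / viable /
non-tumor) plus the pathologist's percent necrosis.

## Pipeline stages and their parameters

**Intensity standardization.** Conventional sequences are mapped onto a
cohort standard scale by landmark matching: intensity landmarks at the
1st percentile, deciles 10–90 and 99th percentile are computed over an
Otsu foreground mask per training image and averaged; a new image is
piecewise-linearly interpolated between its own landmarks and the
standard ones, linearly extrapolated past the ends. The mapping is
monotone; it is numerically idempotent on the foreground it is defined
over (the sub-threshold background is extrapolated and may shift by a
fraction of an intensity unit between passes). Derived parametric maps
are physical quantities and are not standardized.

**Histology-to-MRI registration.** The histologic viability map relates
to the MR plane of interest through 8–12 expert control-point pairs. A
local weighted mean (LWM) transform is fitted: a second-degree bivariate
polynomial per control point, least-squares fitted to its n = 8 nearest
control points, blended with the compactly supported radial weight
(1 − (r/R)³)³ where R is the distance to the n-th neighbor; outside all
neighborhoods the nearest point's polynomial extrapolates. Labels are
transferred by nearest-neighbor sampling (never interpolated); positions
mapping outside the histology map become non-tumor. Collinear
neighborhoods fall back to an affine local fit with a warning. Note that
control points lying on a single conic (e.g. one ellipse around the
tumor) make every quadratic fit degenerate; landmark pickers should
spread points over at least two radii, as the phantom does.

**Derived maps.** ADC comes from a per-pixel log-linear least-squares
fit over the b-values {0, 400, 800} s/mm² (nonpositive signals are
clamped to 10⁻⁶ of the volume maximum and flagged); the fit is exact on
noiseless mono-exponential input. DCE processing subtracts the
pre-contrast frame, detects contrast arrival as the first frame whose
arterial concentration exceeds 5% of peak, snapshots the subtraction at
0/50/100 s after arrival, computes the steepest consecutive-frame
increase scaled by the pre-contrast signal (floored at 10⁻³ of the
volume maximum) and the frame interval T = 19.5 s, and integrates the
subtraction curve over the first 100 s. Signal and concentration are
related by the spoiled-gradient-echo equation with T1 = 1600 ms for
blood, 1100 ms for tumor, and the contrast-agent relaxivity stored as
printed in the acquisition protocol (0.0039 L·mol⁻¹·s⁻¹) together with
an interpretation switch, because that figure is dimensionally
inconsistent with typical Gd-DOTA values (~3.9 L·mmol⁻¹·s⁻¹); the
default interpretation uses the per-mmol reading. The Tofts fit
exploits that the model is linear in K^trans at fixed k_ep: a dense
logarithmic k_ep grid (160 nodes, 0.005–30 min⁻¹) with the closed-form
least-squares amplitude, refined by parabolic interpolation of the
residual, evaluated for all voxels simultaneously; K^trans is bounded to
[0, 5] min⁻¹ and v_e to [0, 1] with a QC flag where a bound is hit. The
convolution uses exact piecewise-linear quadrature of the sampled AIF.

**Features.** Per tumor pixel and per image: the original value, four
sample moments of the W×W window, and 19 Haralick statistics of a
direction-invariant GLCM (eight symmetric distance-1 directions summed
and normalized; window truncated only at image borders; quantization
range taken over the tumor cross-section so neighboring windows share a
gray scale). Conventions: natural logarithms, 0·log 0 = 0, *difference
variance* is the variance of the difference histogram, *sum of squares*
is the marginal variance, degenerate correlation and information
measures are 0. For the canonical definitions HXY1 and HXY2 both reduce
analytically to HX + HY; the test oracle computes them by explicit
double sums and confirms the identity numerically. A compiled (numba)
kernel evaluates the per-pixel features over the compact support of each
window's occupied gray levels; it is verified feature-for-feature
against the plain numpy path, which is itself checked against an
independent brute-force oracle.

**Feature screening.** Pixels are pooled across training cases into
necrotic and viable groups (the documented default; pooling treats
pixels as independent and is anti-conservative — a per-case aggregation
alternative and a Benjamini–Hochberg switch exist but are off by
default, as no multiple-testing correction is applied in the default
protocol). A one-way fixed-effects ANOVA with unequal group sizes
assigns each (image, feature, W, G) a p-value; features are *highly
significant* below 0.001, *significant* below 0.05, and only those two
tiers enter the classifier. An image whose selection is empty at some
(W, G) is dropped from subsets at that setting with a warning.

**Per-image fuzzy c-means.** c = 2 clusters, fuzziness m = 2, center
stopping threshold ε = 10⁻⁵, at most 300 iterations, three restarts
keeping the lowest objective. The first restart seeds centers by
D²-weighted sampling (k-means++ style): under heavy class imbalance the
small-cluster optimum has the lower objective but a vanishing basin of
attraction under random memberships, which is how the default
random-membership initialization fails on > 95%-necrotic tumors. A pixel
coinciding with a center receives crisp membership (the analytic limit).

**Feature standardization.** FCM's Euclidean metric is scale sensitive.
Each selected feature is median-centered and divided by the standard
deviation of its inner 90%, then winsorized at ±20. Two reasons over a
plain z-score: (i) the z-score folds the between-class variance into the
scale, which caps any feature's standardized class separation at
1/√(f(1−f)) — with that cap a two-cluster FCM provably cannot isolate a
~1% minority compartment no matter how strong the raw contrast, because
halving memberships on a within-class split already halves the
objective; the trimmed scale leaves a < 5% compartment out of the scale
estimate so its separation survives; (ii) heavy-tailed texture
statistics (cluster prominence, shade, contrast at small W) would
otherwise dominate the metric through boundary-window outliers — the
winsorization bounds any single feature's influence.

**Necrosis-cluster designation.** Training: the cluster whose hard
assignment agrees best with the histology-transferred labels (restricted
to pixels that carry a tumor label) is necrosis; ties fall to the
cluster with the higher mean ADC value when ADC is the image, otherwise
they are an error. Inference (no histology): absolute cluster centroids
are not comparable across cases because the per-case standardization
scale depends on the case's own necrosis fraction, so designation uses
the cohort-consensus *sign* of the necrotic-minus-viable center
difference on the intensity-anchored features (original value and window
mean) — necrosis is darker on PC, brighter on ADC and STIR, and so on,
regardless of how much of the tumor is necrotic. A single-class guard
supplements the rule: every pixel's raw anchor values are classified
against the pooled training-class means, and if that classification is
unanimous beyond 99.5% the whole plane is assigned crisply to that
class. Without the guard an all-viable plane has no second class for
any designation rule to find and would read ≈ 50% necrotic; with it,
fully viable and fully necrotic planes (including end slices in
whole-volume estimation) are handled correctly. The guard applies only
to the derived parametric maps, whose units are physical and therefore
absolutely comparable across cases; landmark standardization aligns
conventional-image histograms, not tissue classes, so a nearly
single-class tumor gets its class level remapped toward the
cohort-mixed landmarks and its standardized intensities cannot anchor
an absolute comparison.

**Fusion and weight optimization.** The weighted majority rule is used
in its normalized form — a pixel is necrotic iff Σ w_k·u_i^k > 1/2 with
Σ w_k = 1, exactly equivalent to weights summing to the number of maps s
against the threshold s/2 (the two statements are sometimes written
together although they are jointly unsatisfiable for s ≥ 2; the
normalized reading is the consistent one). Weights are searched by brute
force over the discrete simplex with step t = 0.1 (C(19, 9) ≈ 92k–185k
vectors at s = 10–11; an enumeration cap of 10⁶ guards against
infeasible step sizes), minimizing the cohort mean (*min-avg*) or
maximum (*min-max*) absolute error between N_AOI and histology necrosis.
Ties resolve to the first vector in lexicographic order. In the
cohort-fit protocol the (W, G) pair is the one with the lowest
optimized objective over the 3×3 grid. The leave-one-out protocol is
stricter in two ways: the training-fold membership matrices use the
inference-time designation (never histology), so an image whose
designation is unreliable reveals itself during weight fitting rather
than only on the held-out case; and (W, G) is chosen per fold by the
*worst* inner leave-one-out error within the training fold — selecting
by training error was observed to pick scales that fit the fold and
collapse on the held-out case, and averaging inner errors still let
through scales that collapse on a single case.

**Evaluation.** Per case: N_hist, N_AOI, |N_AOI − N_hist|, Dice
2|A∩B|/(|A|+|B|) and Szymkiewicz–Simpson overlap |A∩B|/min(|A|,|B|) of
the necrotic pixel sets, and the responder call at the 90% threshold.
Conventions: Dice of two empty sets is 1; overlap with an empty set is
reported as missing rather than 0. Whole-volume estimation runs the
per-plane pipeline on every VOI slice (slices with fewer pixels than
clusters are skipped with a warning) and reports
N_VOI = 100·(necrotic voxels)/(VOI voxels).

## The synthetic cohort

Each phantom is an ellipsoidal tumor (default ≈ 3000 AOI pixels on a
96×96×12 grid at 1.5×1.5×5 mm) split into necrotic and viable
compartments by a two-pole geometry: necrosis grows around one interior
pole, viable tissue remains a compact lens around the opposite pole, and
a smooth random field wiggles the interface — so both compartments stay
compact (short interface) at any target fraction, mirroring the
coherent regional necrosis of treated osteosarcoma rather than salt-and-
pepper mixing. Per-slice quantile thresholding makes the per-slice
necrosis fraction match the target exactly (in pixel counts), so the
AOI and VOI truths agree by construction.

Class-conditional signals follow the physiology of treated tumors:
necrosis has the higher ADC (2.0 vs 1.1 ×10⁻³ mm²/s), much weaker DCE
uptake (K^trans 0.04 vs 0.25 min⁻¹, v_e 0.12 vs 0.40), no early
enhancement, and — being liquefied — spatially smoother, lower-variance
texture on every image (Gaussian random fields with class-specific
standard deviation and correlation length). The DWI stack and DCE series
are generated through the same signal equations the fitting code
inverts, plus Gaussian noise; a small artery region carries a
biexponential population AIF so the arterial input is itself estimated
from the images. The histologic map is the warped POI label plane at 4×
in-plane resolution under a known smooth quadratic displacement, with
exact (optionally jittered) control-point pairs on two rings around the
tumor, and optional simulated tissue loss that converts a connected
fraction of necrotic pixels to non-tumor. The default suite has ten
cases at 20–99% necrosis, skewed toward good responders as in
post-chemotherapy cohorts. All randomness flows from one seed.

Two generator choices deserve justification. Necrotic K^trans is 0.04
rather than something closer to zero because v_e is unidentifiable when
K^trans ≈ 0 — the fitted v_e then carries no class information and its
cluster polarity flips from case to case, which breaks any designation
rule; 0.04 min⁻¹ is still a factor 6 below viable tumor and keeps the
map's polarity stable. And the necrotic texture variance is lowered but
not removed: with identical class textures the clustering latches onto
the high-contrast boundary ring instead of the class split, while with
too-smooth necrosis the 3×3 windows become quantization-degenerate.

What passing tests do and do not show: the phantom has exactly two
tissue classes with sharp interfaces, stationary class statistics,
exact control points, and modality-independent texture processes. Real
data adds partial-volume voxels, within-class biological gradients,
registration error from imperfect landmarks, tissue loss and artifacts
in histology, and inter-scanner intensity variation; the phantom's
tissue-loss and control-point-jitter switches probe the last two only
coarsely. End-to-end accuracy on the phantom is therefore an upper
bound on, not a promise about, clinical accuracy.

## Numerical choices

Log-linear ADC fitting clamps nonpositive signals (flagged). The SPGR
inversion clips E1 into (10⁻⁸, 1); concentrations clip at 0. The Tofts
grid search uses k_ep nodes spaced ~4.5% apart with parabolic
refinement, giving < 0.1% parameter error on noiseless curves. FCM
restarts are seeded deterministically from case id, image type, (W, G)
and the run seed (CRC32, below 2³¹), so the whole pipeline is
reproducible bit-for-bit given one seed. The weight-grid evaluation runs
in float32 (the membership sums are O(1) and far from the 0.5 threshold
except for a measure-zero set). Degenerate inputs: a constant quantized
region maps to level 1 with a warning; a single-entry GLCM defines
correlation and both information measures as 0; empty masks, empty
feature matrices and sub-cluster-size slices raise or skip with
warnings.

## Known limitations

* **Boundary shrinkage.** Windows centered near the necrosis–viable
  interface mix both classes; their feature vectors attach
  preferentially to the heterogeneous (viable) signature, so every
  per-image map under-counts the majority class near the interface and
  the fused estimate shrinks toward 50% by roughly half the boundary-
  band share (≈ 2–4 pp at the default phantom size for W = 3–9). The
  fusion threshold is fixed at 1/2, so no weight vector can undo a bias
  shared by all maps. This is the dominant residual error of the
  leave-one-out estimates (mean ≈ 4 pp on the default suite) and the
  reason plane-level accuracy improves with tumor cross-section size.
* **Weight overfitting.** With ~10 cases and ~10⁵ candidate weight
  vectors the brute-force argmin fits noise; the leave-one-out protocol
  with inner-fold (W, G) selection reports honest generalization, and
  its residuals are larger than the training objective by design.
* **Unsupervised designation has no absolute reference.** The polarity
  rule needs two clusters with a class contrast; the raw-anchor guard
  covers the single-class limit but depends on cross-case comparability
  of standardized intensities.
* **No spatial regularization, no c > 2, no extended Tofts** (plasma
  volume term), no B1/T1 mapping, no intensity-based deformable
  registration — all outside the model's scope.
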