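# Methods

`tubemorph` quantifies 2-D fluorescence micrographs of vascular networks —
immunostained tissue whole-mounts (e.g. LYVE-1⁺ lymphatic or MECA-32⁺ blood
vessels) and in vitro endothelial tube-formation assays — through a
three-stage pipeline: image pre-processing, tube detection, and
skeleton-based tube analysis.  This note describes the models and numerical
choices behind each stage, the synthetic-data generator used to validate
the measurement chain, and the known limitations.

## Pre-processing

Images are carried internally as floats in [0, 1]; all histogram-based
operators use 256 uniform bins with `bin = floor(v·255)`, matching the
8-bit framing of typical acquisitions.

**Intensity adjustment.**  Auto-contrast (default) saturates a fixed
fraction of pixels at each intensity end (default quantile 0.01, i.e. 1%)
and linearly rescales the rest.  Global histogram equalisation maps each
pixel through the empirical CDF.  CLAHE performs clipped-histogram
equalisation per tile with bilinear interpolation between tile-centre
mappings; it is written in-house so that its single-tile, unclipped limit
reduces bit-for-bit to the global equalisation (a property the tests pin).

**Illumination correction.**  The white top-hat, image minus its
morphological opening with a disk structuring element of radius 51 px
(pixels `(r,c)` with `r²+c² ≤ radius²`).  The opening tracks any smooth
background — including vignetting ramps — while structures narrower than
the disk in both dimensions survive the subtraction with their local
contrast intact.  "Radial size 51" is interpreted as the radius; the value
is a parameter either way.

**Denoising.**  Two options.  (1) A locally adaptive Wiener filter on
per-window mean/variance with the noise power estimated globally as the
mean of local variances; written directly on `scipy.ndimage.uniform_filter`
so that borders use reflective padding and a constant image is a fixed
point.  (2) A two-stage collaborative patch filter (BM3D scheme): block
matching stacks the 16 most similar 8×8 patches inside a 39×39 search
window into a 3-D group (reference grid stride 3); a separable 3-D
transform (2-D DCT per patch, orthonormal Haar along the similarity axis)
is hard-thresholded at 2.7σ and aggregated with weights ∝ 1/(retained
coefficients) to form the basic estimate; a second pass Wiener-shrinks the
noisy image's group spectra using the basic estimate's spectra as the
signal prior.  Block matching is batched per displacement vector via
integral images, so the filter is fully vectorised and deterministic.
Exact-distance ties in flat regions are broken toward small displacements,
which also guarantees the reference patch always belongs to its own group.
Noise σ defaults to the robust MAD estimate on the finest diagonal detail
(`median|d|/0.6745`).  On a 128² tube phantom with σ = 0.08 the filter
gains ≈ 19 dB PSNR; on clean images it is a near-identity (≤ 0.02).

The stage order is fixed: adjust → illumination-correct → denoise, each
step individually switchable.

## Tube detection

Polarity is fixed bright-on-dark.  Optionally the image is first replaced
by its Frangi vesselness response (Hessian eigenvalues |λ1| ≤ λ2 < 0;
blobness `R_b = λ1/λ2`, structure `S = √(λ1²+λ2²)`; response
`exp(−R_b²/2β²)(1−exp(−S²/2c²))` maximised over scales {1,2,3,4} px,
β = 0.5, `c` defaulting to half the maximum Hessian norm per image, via
scikit-image).  Lowering `c` flattens intensity differences between
strongly and weakly stained tubes, which is what makes the option useful
for faint staining.

Four binarisation methods share the 256-bin histogram convention, report
the threshold as a bin index `t`, and take foreground = `bin > t`:

- **Otsu** maximises between-class variance (ties → lowest `t`);
- **Multi-Otsu** maximises the `n`-class between-class variance by
  exhaustive search over cut tuples (default 3 classes, foreground = top
  class; the number of foreground classes is a parameter).  With dominant
  background and heterogeneous staining the three classes read naturally
  as background / weak stain / vessel;
- **Kittler–Illingworth** minimises the two-Gaussian minimum-error
  criterion `J(t) = 1 + P₁ln σ₁² + P₂ln σ₂² − 2(P₁ln P₁ + P₂ln P₂)`;
  class variances are floored at one bin² because `ln σ` is undefined at
  zero.  On histograms whose foreground is a broad mixture of dim and
  bright vessels the fitted foreground Gaussian is wide, the decision
  boundary drops just above the background mode, and weakly stained
  vessels are kept — the reason this method detects more vessels than
  Multi-Otsu on heterogeneous stainings;
- **Adaptive**: foreground iff `intensity > local_mean(block) + offset`
  (reflective borders).  A positive offset demands local contrast.

All three global methods are verified bin-exactly against brute-force
criterion scans.  Refinement removes 8-connected components smaller
(strictly) than `min_region_fraction` of the image pixels (default 1%) and
then optionally fills 4-connected background holes; removal precedes
filling so that filled specks cannot be promoted above the size cutoff.

## Tube analysis

**Skeletonization** is iterative hit-and-miss thinning with the standard
eight rotated 3×3 template pairs applied sequentially until a fixpoint.
Thinning is homotopic (8-connected component count preserved — verified on
hundreds of random masks).  Template thinning can leave "staircase"
residues: non-endpoint pixels whose foreground neighbours form one
connected arc of the 8-ring, which are deletable without changing
topology.  A sequential cleanup pass removes them (after thinning and
after every pruning pass), which is required for the skeleton to be
strictly one pixel wide.

**Topology.**  Endpoints are pixels with exactly one 8-neighbour.  The
branch count of a pixel is the number of circular runs of foreground in
its 8-neighbour ring (so two mutually adjacent neighbours count once);
junction pixels have ≥ 3 branches.  Spur pruning walks from each endpoint
to the first junction; if the geodesic length (including the step onto the
junction) is below `spur_length` (default 15 px; 30 for tube formation)
the branch is deleted up to, but not including, the junction pixel; all
qualifying spurs of a pass are removed together and passes repeat to a
fixpoint, so the result is order-independent.  `spur_length = 0` is an
exact no-op.  Isolated segments shorter than the spur length are removed
entirely (flag-controlled).  Junction pixels within `merge_distance`
(default 10 px) are single-linkage clustered — order-independent, unlike
greedy merging — and replaced by their rounded centroid.  The degree of a
merged junction is the number of distinct skeleton branches leaving the
cluster's dilated footprint (radius `merge_distance/2`, halved if it
swallows every branch); degree 3 is a *branching* point, degree ≥ 4 a
*crossing* point.  Degree is the only information a 2-D skeleton offers,
so two merged 3-way junctions legitimately classify as one crossing.

**Measurements.**  Vessel area = mask foreground count.  Skeleton length
(default *geodesic*) sums 1 per orthogonal and √2 per diagonal adjacency,
each adjacency once; a pixel-count mode is available.  Mean vessel width =
area / length, so `width × length = area` holds exactly by construction.
Note two intrinsic biases of raster skeletons that users should know:
the geodesic chain metric overestimates oblique smooth curves by up to
~8% (≈ +5% on isotropically oriented networks), and homotopic thinning
shortens blunt vessel ends by about half the vessel width (a 10-px-wide
bar of 100 px measures ≈ 92 px).  On branching networks the two effects
largely cancel.

## Synthetic networks

The generator grows self-avoiding branching random walks and is the
package's primary validation instrument: every branch/crossing event is
recorded at generation time, and the geometry is both steered away from
accidental contacts during growth (a clearance grid: no new centerline
point closer than 17 px to unrelated vessels) and verified afterwards by
exact pairwise distances, regenerating from a derived seed on violation.
Consequently the rasterised mask contains exactly the recorded junctions,
and true totals (centerline length, rasterised union area, counts) are
closed-form.

Default study conditions (chosen to mirror the relative geometry of
whole-mount acquisitions at a reduced 256-px canvas): 6 seed walkers, step
10 px, up to 60 steps, heading noise 0.2 rad/step, branch probability
0.15/step, vessel width 10 ± 1.5 px (≈ 4% of the frame, as in typical
whole-mount images), margin 18 px.  Events only count as ground-truth
branch points when all three arms decisively survive spur pruning (child ≥
5 steps, parent continues ≥ 4 steps; shorter children are erased with
their descendants, shorter parent tails are trimmed and the event
discarded as a bend).  Families too small to survive the 1% small-region
removal are dropped whole.

Renders are flat-topped tubes (peak 0.8 over background 0.1) blurred by a
Gaussian PSF (σ 0.3 px, scaled with the canvas so the blur-to-width ratio
matches real acquisitions), crossing half maximum exactly at the true
boundary; overlaps combine by maximum.  Degradations, in order: additive
radial illumination field `a(1−ρ²)` (bright centre — the vignetting
pattern of uneven illumination), multiplicative staining heterogeneity
along each tube's axis (smooth, std-controlled), additive Gaussian sensor
noise, then clipping to [0, 1].

What the fixtures do *not* emulate: out-of-focus haze, anisotropic PSFs,
autofluorescent debris, true 3-D overlap geometry, or vessels entering
from outside the field of view.  Passing the end-to-end tests therefore
demonstrates that the measurement chain is unbiased under controlled
degradations, not that any particular biological dataset will be measured
to the same accuracy.

Measured under these conditions (20 networks, lymphatic preset): clean
renders recover total length within ~6%, area within ~9%, and branch
counts exactly; with sensor noise σ = 0.05 plus vignetting 0.2 the length
error stays below ~5% and branch counts deviate by at most ~1 per 19 true
branches.

Two qualitative claims deserve an honest caveat.  With tube contrast
pinned at 0.8, an additive vignette of amplitude 0.3 raises background and
tubes together, so a histogram gap always separates the brightest
background (bg + 0.3) from the dimmest corner tube (local bg + 0.4): Otsu's
threshold cannot rise above that gap and far-corner *recall* stays ≈ 1.0
with or without top-hat (the failure a vignette actually causes at this
amplitude is threshold drift and false positives, which the degraded-arm
recovery test does exercise through the preset's top-hat step).  The
weak-staining advantage of the Kittler threshold, by contrast, is robust:
on heterogeneously stained renders (stain std 0.35) Kittler's threshold is
~55 bins below Otsu's and its foreground recall strictly higher on every
seed tested.

## Practical parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| saturation_quantile | 0.01 | fraction | auto-contrast saturation per intensity end |
| tophat_radius | 51 | px | disk radius of the illumination correction |
| bm3d_sigma | auto | intensity | noise std; MAD-estimated when `auto` |
| frangi_scales | 1–4 | px | vesselness scales (tube half-widths) |
| multiotsu_classes | 3 | – | histogram classes; foreground = top class |
| min_region_fraction | 0.01 | fraction | small-region cutoff (strict <) |
| spur_length | 15 (30 in vitro) | px | max pruned ramification length |
| merge_distance | 10 | px | junction merge radius |
| pixel_size_um | preset | µm/px | camera px × binning / total magnification |

The three presets (`lymphatic`, `blood`, `tube_formation`) bundle the
channel, thresholding method, vesselness flag, spur length and physical
pixel size used for the three supported dataset types.

## Limitations

- Strictly 2-D: vessels that overlap in projection are junctions; a
  degree-≥4 junction is *called* a crossing, which is an interpretation,
  not a resolved 3-D fact.
- Absolute area and width depend on where the chosen threshold lands on
  the tube's edge ramp; with Multi-Otsu's top class the areas are
  conservative (biased slightly low) on homogeneous stainings.
- The geodesic length metric and end-shortening biases above matter for
  isolated short segments; they are second-order for extended networks.
- Heterogeneous staining can split one vessel into several detected
  fragments; the small-region filter then discards the smallest.
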