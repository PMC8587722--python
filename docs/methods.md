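# Methods

## Problem and model

An area-scanner whole-slide-imaging system acquires a rectangular grid of
camera fields of view (FOVs, "tiles") with a fixed overlap stripe on each
side, and optionally several focal (Z) layers per grid position. Stage
motion, optics and illumination make tile intensities uneven, leaving
visible seams ("tile effects") in the stitched image. Because the overlap
stripe of two adjacent tiles images the same physical region twice, the two
recordings of that region carry everything needed to estimate an intensity
transfer between the tiles — no calibration target and no model of the
optics is required.

`tileshade` implements a ladder of five compensation methods on this idea,
each subsuming the previous one:

1. **Histogram matching.** For a stripe pair, per-channel histograms
   `h(i)` are turned into smoothed CDFs

       cdf(i) = Σ_{j≤i} (h(j)+1) / Σ_{j<N} (h(j)+1),   N = 256,

   and the match table `hm(i₁)` is the level `i₂` whose reference CDF value
   is nearest `cdf₁(i₁)` (ties to the smaller level). The +1 pseudo-count
   per bin makes every CDF strictly increasing, so `hm` is defined for all
   256 levels and is monotone. Matching the whole stripe gives one global
   transfer per tile side.
2. **Patch-based matching.** Each stripe is cut into `n_patches` equal
   pieces along its long axis (default 3; the distortion is mostly uniform
   inside a FOV, with visible deviations confined to roughly the outer
   third) and each patch is matched against the co-located patch of the
   partner stripe, capturing compensation that varies along the edge.
3. **Polynomial regression.** A match table is only observed at the
   intensities present in the stripe; the tile interior can contain any
   level. Assuming one smooth distortion characteristic across the range,
   an ordinary-least-squares polynomial (degree 2 by default: near-linear
   with a mild exponential-like bend; degree 3 adds nothing) fitted to the
   supported `(i, hm(i))` pairs interpolates and extrapolates the transfer.
4. **Iterative spreading.** Repeats estimate-and-compensate with
   geometrically decreasing strength so isolated dark/bright tiles are
   corrected from progressively farther context (below).
5. **Multi-focal.** Adds focal-layer neighbors to the iterative averaging
   so Z layers are pulled toward each other.

### Applying a compensation field

Per tile and channel, the per-patch transfers of the four sides are blended
into one value per pixel and intensity:

- consecutive patch transfers along a stripe are linearly interpolated at
  `p = floor(x·N/W)`, `t = frac(x·N/W)`, with the far-edge index clamped to
  the last patch;
- the top/bottom side values are blended by `t = y/H` (`comp_h`), left/right
  by `t = x/W` (`comp_v`);
- the two are combined as `lerp(comp_h, comp_v, w)` with
  `w = b/(a+b)`, `a = 0.5 − |0.5 − x/W|`, `b = 0.5 − |0.5 − y/H|`
  (`w := 0.5` at the exact corners). `w` is 0 on the top/bottom edges —
  there the tile's own top/bottom stripe transfer applies exactly — 1 on
  the left/right edges, and 0.5 at the center;
- the result is half-applied, `dst = (comp(src) + src)/2`, rounded
  half-away-from-zero and clamped to [0, 255]. The half-strength
  application bounds the damage of any single bad transfer; the strength is
  exposed as `alpha` (default 0.5).

The compensated surface is seam-free in the tile interior; within a few
pixels of the border the rational edge-distance weight changes faster and
single-pixel steps up to about half the largest side disparity can occur
near corners. With identity transfers everywhere the whole pipeline is a
bit-exact no-op.

### Iterative scheme

One pass closes the seams but only half-corrects an isolated dark or bright
tile and drags its neighbors toward it. The iterative method runs
`n_iterations` rounds (default 5); round `k` (0-based), with strength
`w_k = w₀·r^k` (defaults `w₀ = 0.5`, `r = 0.5`):

1. re-estimate all patch match tables from the current, partially corrected
   mosaic;
2. average each tile's tables over its patches (support-masked mean:
   each intensity is averaged over the patches that actually observe it,
   and maps to itself where no patch does);
3. blend ("spread") every table toward its tile's average with weight
   `w_k`, which uniformizes the correction within a tile;
4. re-fit the regressions and apply the field at strength `w_k`.

Because the tables are re-estimated after each partial application, a
correction propagates one tile ring farther per round: the defective tile
climbs toward its neighborhood while the burden spreads over a widening
ring, so the defect fades without spoiling the immediate neighbors. The
decreasing schedule acts like annealing: early rounds move aggressively
toward the local consensus, later rounds make sub-quantization refinements.
`n_iterations = 0` reduces bit-exactly to the one-shot regression method.

A design note on the averaging step: blending a tile's tables toward their
own average preserves the tile's mean correction exactly, so spreading
*alone* (without re-estimation between rounds) can redistribute a
correction within a tile but can never change tile-level brightness
relations — which is precisely what the iterative method exists to fix.
Per-round re-estimation is therefore load-bearing, not an optimization.
Tables are stored per directed tile side (each tile matches its own stripe
pixels toward its neighbor's), since the two directions of a stripe pair
are mutually inverse transfers and cannot share one table.

### Multi-focal extension

Under Z-X-Y acquisition every focal layer of a grid position covers the
same footprint, so the four stripe regions of a tile have exact co-located
counterparts at z±1. These are matched exactly like lateral pairs and the
resulting Z tables join the spreading average (step 2 above), each patch
counting once (`z_weight`, default 1.0, discounts them for thick samples
where layers image different structures). The compensation field itself is
still built from the lateral tables only — Z information flows in through
the average. On a single-layer mosaic the Z average falls back to the plain
tile average with a warning; `run_multifocal` refuses single-layer input.

## Metrics

- `error` — mean |o_ab − o_ba| over lateral overlap pairs, gray levels.
- `heterogeneity` — mean over adjacent pairs of
  |Δ mean intensity| (compensated) / |Δ mean intensity| (original);
  exactly 1.0 for null compensation. Pairs whose original gap is zero are
  excluded (the ratio is undefined) and counted in the report.
- `zerror` — mean |difference| between co-located tiles on adjacent focal
  layers, over the full tile footprint (stacked FOVs overlap completely).

All metrics are computed per channel and averaged uniformly; multiple
mosaics ("cases") aggregate as the mean of per-case means (a pooled-pairs
variant is available). Case means feed the reported mean ± sd.

## Numerical choices

- **Matching tie-break**: nearest reference CDF value, ties to the smaller
  level; equals exhaustive search by construction and keeps `hm` monotone.
- **Fit support**: the regression fits only supported intensities whose
  matched value lands on a level actually observed in the reference. A
  match landing in the reference CDF's pseudo-count-only tail (which
  happens systematically at the top of the range whenever the true
  transfer maps downward) is a smoothing artifact, not evidence, and one
  such point can visibly tilt a fit on a narrow stripe.
- **Solver**: intensities are scaled to [0, 1] before the SVD-backed
  least-squares solve (the raw Vandermonde basis over [0, 255] is badly
  conditioned) and coefficients are mapped back; this agrees with the
  literal normal-equation solve to well below 1e−8 on conditioned inputs.
- **Thin support**: fewer supported points than `degree+1` reduces the
  degree (2 → 1 → 0, where "degree 0" is a constant additive shift); empty
  support yields the identity. A patch with fewer than `tau_support = 8`
  distinct intensities (background-only, the classic low-information
  failure mode) is flagged and its regression falls back to the
  stripe-global table. Each supported intensity contributes one fit point
  regardless of its pixel count; a pixel-count-weighted fit is available
  but off by default.
- **Rounding**: half-away-from-zero, then clamp — stated for bit-exact
  reproducibility of the identity fixed point and the reduction chains.
- **Missing neighbors**: border sides (and absent tiles) get identity
  transfers; all pair iteration simply skips absent neighbors.

## Synthetic data

The generator crops all tiles from one seamless latent image, so every
overlap pair is pixel-identical before distortion and any later
disagreement is attributable to the injected defects alone. Content kinds:
`blobs` (sparse Gaussian spots, fluorescent-like), `texture` (smooth
broadband field, skewed toward the chosen background polarity),
`gradient` (diagonal ramp, dense histograms), `constant`. Distortions:
per-tile gain jitter (sd 0.05) and offset jitter (sd 5 gray levels) — the
standard jitter conditions used throughout the tests — optional radial
vignette, optional per-tile gamma, per-layer offsets (the 3-layer fixtures
use −10/0/+10), and explicit defect tiles (the center-defect fixture
darkens the middle tile of a constant-128 mosaic by 30 levels). One seed
determines everything bit-exactly.

Default geometry is a 128×128 tile with 16-pixel overlaps (~12% overlap
fraction, representative of area scanners). On much smaller tiles the
overlap becomes a large fraction of the tile and the `x/W` edge blending
then leaks the opposite side's transfer into the stripe region — an
artifact of degenerate geometry, not of the method. The parameter-recovery
test uses a 256×1024 tile pair whose shared stripe holds ~49k pixels
(a realistic stripe population) with gradient content, because recovery to
within quantization requires histograms dense enough that the +1-smoothing
bias is negligible.

What the generator does **not** emulate: real tissue structure and its
spatial correlation across tiles, stitching misalignment (overlaps are
assumed perfectly registered), focus differences between Z layers
(Z crops are identical up to the injected shifts), sensor noise, and
saturation effects beyond simple clamping. Passing tests therefore
demonstrate correctness of the estimation/compensation machinery under
controlled distortions, not clinical image quality.

## Problem sizes

The test suite and the reference script run on desk-scale grids — 3×3 to
5×5 tiles, 1–3 focal layers, 128-px tiles — chosen so the full ladder
(including five iterative rounds) completes in seconds while every fixture
still has interior tiles with complete neighborhoods.

## Known limitations

- 8-bit single- or multi-channel input only; higher bit depths are out of
  scope.
- Overlap widths are global per axis; per-tile overlaps are not supported.
- The blend weight is non-smooth at tile corners (inherent to rational
  edge-distance weights); visible only as ≤ half-disparity single-pixel
  steps immediately at the border.
- The iteration count is fixed per run; no dynamic stopping rule.
- Geometric registration, pyramidal WSI formats, and background-model
  methods (flat-field estimation from image stacks) are out of scope.
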