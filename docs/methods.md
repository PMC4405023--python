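# Methods

## Model and procedure

The package segments a single-channel image (gray levels in `[0, L−1]`,
`L = 256`) into `C` fuzzy clusters, by default `C = 2`: parenchyma background
versus bright tissue (nodule, vessel, wall).  The run proceeds as:

1. **2D histogram.**  For every pixel the pair `(f, round(g))` is counted,
   where `f` is the (rounded) gray level and `g` the mean of the
   `(2r+1)×(2r+1)` window under edge-replicate padding.  Each pixel inherits
   the frequency `p_j` of its own bin.  The unquantized `g` raster is kept
   for the adaptive factor and the center update.
2. **Initialization.**  A seeded RNG draws a random column-normalized
   membership matrix, which is mapped to initial centers through the plain
   FCM center update.  All randomness of a run lives in this one draw.
3. **Iteration** (at most `L_max = 100` rounds):
   memberships `μ_ij` from current centers (exponent `2/(m−1)`, crisp
   assignment when a pixel sits exactly on a center) → spatial function
   `h_ij` and fusion `μ′_ij ∝ μ_ij^p h_ij^q` → center update from `μ′` using
   `(x_j + g_j)` → stop when `max_i |Δv_i| < ε`.
4. **Defuzzification.**  Per-pixel argmax of the fused memberships, ties to
   the lowest index; the cluster with the larger center is the foreground
   mask (bright-in-center assumption of nodule CT).

Constant images short-circuit with a warning (all pixels labeled 0, empty
foreground); duplicated centers and zero-mass clusters raise typed errors.

## The spatial-function form: an experiment, not a guess

Two readings of the window accumulation are implemented:

* **additive** (default): `h_ij = Σ_r (μ_ir + ω_r)` — every neighbor's
  membership counts; the affinity weights contribute a cluster-independent
  offset `Σ_r ω_r`.
* **weighted**: `h_ij = Σ_r ω_r μ_ir` — neighbor memberships are discounted
  by gray affinity; `h_ij = 0` iff no neighbor has mass in cluster `i`.

The weighted form looks more principled but measurably disables the noise
robustness that motivates the method.  For an impulse pixel, `λ_j` is large
and `ω_r` underflows to zero for every gray-dissimilar neighbor, so
`h_ij` collapses to the pixel's own membership and the fusion merely
*sharpens* the wrong gray-based assignment.  Head to head on a 64×64
two-region image (40/200) with 5% salt-and-pepper noise, median over 10
seeds: additive 0.52% misclassification, weighted 2.47% — identical to plain
FCM.  On a flat-55 field with a single 142 outlier, the additive form
absorbs the outlier into the surrounding cluster on 8/8 seeds; the weighted
form isolates it on 8/8 (a center migrates to the outlier's
`(x+g)/2 ≈ 103`).  The additive form is therefore the default and the
weighted form remains available via `FsafcmConfig(h_combination="weighted")`
for comparison.

## Center bias of the neighborhood-coupled update

The center update averages `(x_j + g_j)/2`.  In windows that straddle a
region boundary `g ≠ x`, so each center is pulled slightly toward the other
region in proportion to the boundary-pixel fraction and the contrast.  On
the 64×64 half-split 40/200 image the converged fixed point is
`(41.50, 198.50)` — labels are still exact (misclassification 0), but the
centers are *not* the region means to high precision.  This is a property of
the update itself, not of the implementation: with the plain FCM center
update (`center_update="plain"`, `q=0`) the same loop recovers
`(40.000, 200.000)` within 1e−3 and is bit-identical to the baseline FCM.
Users who need unbiased center estimates on near-piecewise-constant data
should read them from the plain update or from the region means under the
final labels.

## Parameters

| name | default | meaning |
|---|---|---|
| `C` | 2 | clusters (background / bright tissue) |
| `m` | 2 | fuzzifier; values outside [1.1, 5] warn |
| `r` | 2 | window radius; 5×5 neighborhood |
| `p`, `q` | 1, 2 | fusion exponents on `μ` and `h` |
| `epsilon` | 0.001 | max-abs center change for convergence (gray levels) |
| `L_max` | 100 | iteration cap |
| `center_update` | normalized | `(x+g)` numerator over `2Σμ′^m`; `as_printed` drops the 2 (centers leave the gray range), `plain` is classical FCM |
| `h_combination` | additive | see above |

Baselines share `m = 2`, `ε = 0.001`, `L_max = 100` and 3×3 windows
(`N_R = 9`, center included), with `α = 0.85` for FCM_S/EnFCM, `λ_g = 6` and
`λ_s = 3` for FGFCM; FLICM is parameter-free apart from the window.  All
five reuse the package's initialization, convergence test and foreground
rule, so iteration-count comparisons measure the update rules, not harness
differences.

## What the phantom generator emulates — and what it does not

`make_phantom` renders the nodule presentations that drive the design:
isolated disks, vessel adhesion (tube at the same nominal intensity as the
nodule), pleural adhesion (wall band with a smooth ramp), GGO (low
contrast) and cavitary (annulus).  Intensities default to background ≈ 40,
nodule/vessel ≈ 180, wall ≈ 220, GGO ≈ 90; shapes are softened with a
Gaussian (σ = 1.5 px) so edges transit smoothly, mild Gaussian texture
(σ = 2) is added, and `add_salt_pepper` provides impulse noise.  At the
default 0.7 mm/px scale, clinical nodule diameters of 8–30 mm correspond to
disks of roughly 11–43 px.  Truth masks come from the hard geometry and mark
nodule pixels only.

The phantoms are deliberately simple: no reconstruction artifacts, no beam
hardening, no anatomic clutter, no partial-volume effects beyond the rim
blur, and contrast far cleaner than clinical CT.  Passing tests on phantoms
therefore demonstrate the *mechanisms* (noise absorption, convergence
ordering, adhesion handling) rather than clinical accuracy; iteration counts
on clinical slices are expected to be larger for every algorithm, with the
same ordering.  Default problem sizes (64–96 px sides, 10-phantom suite, 20
noise seeds) were chosen as the smallest at which these mechanisms are
stable across seeds.

## Evaluation conventions

The signed error rate is `100·(e_m − e_a)/e_m` with `e` the segmented
*area* in pixels (a boundary-length mode exists behind a flag): positive
means undersegmentation, negative oversegmentation; `e_m = 0` raises.
Misclassification is the fraction of pixels whose foreground/background
assignment disagrees with truth.  Suite comparisons aggregate by median
across seeds, robust to the stochastic initialization.  A banding utility
histograms error rates in 50-point bands over [−200%, +100%] and reports
the share within ±50%.

## Preprocessing

Parenchyma extraction is fully automatic: Otsu threshold → drop dark
components touching the border (exterior air) → keep the largest one or two
interior dark components (≥ 5% of the largest) → morphological closing
(disk radius 3 px, configurable) and hole filling so bright vessels and
nodules inside the lung stay in the masked image.  Otsu makes the stage
invariant to affine intensity rescaling.  Juxtapleural re-inclusion beyond
hole filling is out of scope.

## Numerical choices

* Exponent underflow in `ω` (large gray difference × large `λ`) flushes to
  zero; that limit is exactly what the additive form tolerates.
* Fused columns that sum to zero fall back to the unfused column; `q = 0`
  with `p = 1` bypasses fusion exactly (no float drift), which is what makes
  the FCM reduction bit-identical.
* Window sums use explicit padded shifts, so flat windows give `λ = 0`
  exactly and the brute-force loop oracles agree to 1e−10.
* EnFCM/FGFCM iterate over ≤ L rounded gray levels with count weights;
  their label maps are mirror-equivariant by construction.
* FCM_S expands its neighborhood distance term algebraically
  (`E[x²] − 2vE[x] + v²`, clipped at 0 against rounding).

## Known limitations

* `C > 2` runs numerically but the foreground rule (single brightest
  cluster) and all validation target the two-cluster clinical case.
* The neighborhood-coupled center update biases centers near region
  boundaries (see above).
* GGO phantoms at very low contrast sit near the decision noise floor;
  oversegmentation of adhered structures (vessel, wall ramp) is expected
  because they genuinely share the nodule's gray level — separating them
  needs shape priors, which clustering alone does not provide.
* 2D slices only; no volumetric neighborhoods.
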