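# Methods

## Problem and model

`spioquant` quantifies the uptake of superparamagnetic iron-oxide
nanoparticles (SPIO-NPs, crystallite diameter 10–13 nm) by macrophages from
2-D TEM micrographs. Internalized particles concentrate in lysosomes and
microvesicles (160–250 nm across), where they appear as electron-dense
(dark) disks on a lighter cytoplasmic/resin background. The pipeline is:

1. **Read and reduce.** Micrographs are 8-bit grayscale, acquired at a
   native scale of 0.97 nm/pixel (9.7 Å). Large images may be reduced by a
   linear block-averaging factor k per axis; the pixel size scales to
   0.97·k nm (3.88 nm at the usual k = 4). Block means are rounded half-up
   to stay 8-bit; incomplete edge blocks are dropped to avoid biased means
   at borders.
2. **Threshold.** A single global threshold T splits gray levels into a
   dark particle class (g < T, rendered "red") and background (g ≥ T,
   white): h(i,j) = 255 if f(i,j) ≥ T else 0. Two selection rules are
   offered (see below); Otsu is the default.
3. **Count per ROI.** Lysosome/vesicle regions of interest are supplied by
   the user (rectangles or polygons in JSON); for each ROI the foreground
   pixel count `red_px`, the coverage percentage `100·red_px/total_px`, and
   a particle estimate are reported.
4. **Convert coverage to particles.** One particle of diameter d covers an
   expected footprint of (π·d²/4)/p² pixels at pixel size p. The estimate
   is round-half-up(red_px / footprint). At d = 11.5 nm and p = 3.88 nm
   the physical footprint is ≈ 6.90 px/particle. A conventional footprint
   of exactly 6 px/particle is also supported (and is what the shipped
   reference table uses); both are exposed via `--footprint-px`.

### Threshold selection

**Otsu** exhaustively scans T ∈ [1, 255] and minimizes the intra-class
variance w₀σ₀² + w₁σ₁² with classes {g < T} and {g ≥ T}; candidates
leaving either class empty are inadmissible, ties take the smallest T
(conservative foreground), and a histogram with a single occupied level is
rejected as degenerate. Minimizing intra-class variance is equivalent to
maximizing between-class variance; the test suite checks this identity and
an exhaustive per-pixel brute-force oracle.

**First minimum** smooths the histogram with a centered moving average
(default width 5 — raw TEM histograms are jagged; edge bins use the
available partial window) and returns the smallest gray level g with
smoothed(g) < smoothed(g−1) and smoothed(g) ≤ smoothed(g+1), scanning
upward from the first occupied bin and only inside the occupied support
(beyond the last occupied bin the smoothed curve trivially decays to zero,
which is not a valley). If no interior valley exists the result falls back
to Otsu and is flagged (`fallback` in the JSON sidecar). Both rules are
kept because both are in routine use for this kind of micrograph; they
need not agree, and the choice is a CLI flag.

The boundary pixel f = T is background, exactly as the binarization rule
states. The CLI computes one global threshold per image by default;
`--threshold-scope roi` recomputes the threshold from each ROI's own
histogram, which is the better choice when vesicle interiors are shaded
differently from the extracellular background.

### Calibration from background singles

Isolated single particles outside cells give an empirical footprint:
8-connected components of the segmented foreground are size-gated to the
pixel-area equivalents of the 10–13 nm diameter range (≈ 83–141 px at
0.97 nm/px), and the **median** surviving area and equivalent-circle
diameter become the calibrated footprint and particle size. The median
(not mean) makes the estimate invariant to any number of gated-out noise
specks and clumps; at least 3 survivors are required.

## Reference table

The package ships the published eight-lysosome measurement table (total
and red pixel counts, with the printed percentages and estimates) and can
re-derive the derived columns from the pixel counts alone
(`spioquant reproduce-table1`). With the 6 px/particle footprint, rows 2–5
reproduce exactly (88, 98, 84, 72) and the averages row reproduces exactly
(3358 total px, 479 red px, 14% pooled coverage). The printed estimates of
rows 1, 6, 7 and 8 (93, 70, 86, 40) do **not** equal round-half-up(red/6)
of their own printed pixel counts (91, 69, 83, 54), and row 5's printed
14.32% is not 100·431/3016 (= 14.29%); these rows are flagged as not
derivable from the printed inputs rather than silently reproduced. The
headline average of ~78 particles per lysosome is the truncated mean of
the printed estimate column (78.875 → 78); truncation toward zero is the
only rounding rule consistent with that printed mean, and it is the rule
`summarize` applies to the estimate column generally (pixel-count averages
use round-half-up; the pooled percentage is rounded half-up to an integer).

## Synthetic scenes

The generator renders what the counting model needs and nothing more: a
Gaussian background (mean 200, sd 4 on the 8-bit scale), vesicles as
slightly darker anti-aliased disks (interior 180) with a darker membrane
rim (140, 4 nm wide), particles as dark anti-aliased disks (mean 60,
default diameter 11.5 nm), optional isolated background singles, and
additive Gaussian detector noise (default sd 5). Disk edges use 4×4
sub-pixel coverage sampling, so a disk's rasterized area converges to
π·d²/4 with resolution. Particle placement is rejection-sampled with a
minimum center distance solved from the circular-lens equation so pairwise
overlap stays below 5% of a particle's area, matching the approximately
non-overlapping coverage the estimator assumes. One seed gives one
bit-exact image.

Default study conditions: 288×288 px at 0.97 nm/px, one centered vesicle
of 200 nm holding 20–100 particles. What the generator deliberately does
not emulate: tilt-series/projection physics, focus/CTF effects, stain
gradients, membrane substructure, and particle clumping. Passing recovery
tests therefore demonstrates that the segmentation and counting arithmetic
are correct under the stated contrast and overlap assumptions — not that
those assumptions hold for any particular real micrograph; in real data,
clumped particles bias coverage-based counts downward, and no declumping
correction is applied.

## Numerical choices

- All count-like rounding is round-half-up (`floor(x + 0.5)`), never
  banker's rounding; per-row percentages are reported at 2 decimals.
- Otsu tie-break: smallest minimizing T. Objective values are floored at 0
  to absorb ~1e−12 negative variance from catastrophic cancellation.
- RGB inputs are converted with BT.601 luma weights; 16-bit inputs are
  rescaled by the fixed factor 255/65535 (content-independent, so the same
  raster always reads identically).
- Degenerate inputs fail loudly: constant images (no admissible
  threshold), empty ROIs, out-of-bounds geometry, infeasible particle
  packing, and < 3 calibration survivors all raise typed errors.
- ROI polygons are filled by testing pixel centers (r+0.5, c+0.5) under
  the even-odd rule, so an axis-aligned square polygon equals the
  equivalent half-open rectangle; rectangle areas are exact.

## Verification problem sizes

The test suite checks the Otsu implementation against a per-pixel
brute-force oracle on 100 random/bimodal 64×64 images, connected
components against an independent flood fill, and end-to-end count
recovery on a 3×3 grid of conditions (20/50/100 particles ×
noise sd 2/5/10) with 20 seeds per cell (180 scenes), requiring a mean
absolute relative error ≤ 15% per cell with the true footprint supplied.
Calibration must recover the particle diameter within ±1.5 nm from 25
synthetic background singles. The whole suite runs in well under a minute.

## Known limitations

- Coverage division cannot separate touching particles; heavy clumping
  undercounts.
- A global threshold assumes reasonably uniform illumination; strongly
  shaded micrographs should use `--threshold-scope roi`.
- ROIs are user-drawn; no automatic lysosome detection is attempted.
- The first-minimum rule depends on the smoothing window; very flat
  valleys can move by a few gray levels with the window size.
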