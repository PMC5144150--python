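# Methods

## Synthetic scenes

A scene is one or more elliptical nuclei (default semi-axes 70 × 55 px at
0.1 µm/px, i.e. a 14 × 11 µm C2C12-like nucleus) rendered on a dark
background. The nucleoplasm sits at 0.30 (arbitrary units on a [0, 1]
scale); chromocenters are isotropic Gaussian spots truncated at 3σ with
σ = radius/2 (amplitude 0.70 above the nucleoplasm), a simple stand-in for
diffraction-blurred foci. Per-nucleus spot counts are drawn from a normal
distribution rounded to integers (default 15 ± 3, a realistic chromocenter
count for mouse myoblast nuclei) and radii from a normal distribution
(default 5 ± 0.8 px ≈ 1 µm diameter). Spot centres are rejection-sampled
with a minimum centre distance of 3·(σᵢ + σⱼ), which keeps truncated
footprints disjoint; the whole layout is restarted deterministically on
jamming. The sidecar records, per spot, the centre, radius, analytic disc
area πr² and the rasterized truncated-footprint pixel count — the latter is
what a pixel-level detector can recover exactly on a noiseless image, and
segmentation tests compare against it.

The GFP channel encodes the construct's localization state:
`colocalized` renders GFP spots proportional to the DAPI spots over a dim
uniform pool; `partial` renders proportional signal on a random half of the
spots over a brighter pool; `diffuse_mislocalized` renders only a uniform
pool. The diffuse pool carries mild independent per-pixel texture
(sd 0.05) because an unbound fluorophore pool is never optically flat, and
because a strictly constant channel would make the Pearson coefficient
degenerate. Detector noise is additive Gaussian on both channels
(default off; 0.02 of full scale in realism tests). The generator is 2-D;
the segmenter max-projects any stack it is given. Point-spread-function
optics, camera-specific noise and 3-D structure are deliberately not
modelled, so passing tests demonstrate correctness of the measurement
pipeline, not robustness to every optical artifact of real confocal data.

## Segmentation

Nuclei: global Otsu threshold, hole filling, removal of components below
`min_nucleus_area` (default 1000 px²), then a watershed on the smoothed
(Gaussian σ = 2) distance transform with peaks at least
0.7·√(`min_nucleus_area`/π) apart to split touching nuclei. A flat image
yields zero nuclei with a logged warning.

Chromocenters: the nucleoplasm baseline inside each nucleus is estimated by
iterative sigma-clipping (drop pixels above mean + k·sd until stable), so
the bright foci do not inflate their own detection threshold; foreground is
everything above mean + k·sd with k = `threshold_k` (default 2.0). Seeds
are maxima surviving an h-maxima transform with depth `h_seed` × the
within-nucleus dynamic range (default 0.1 — relative, so segmentation is
invariant to rescaling the image); a seeded watershed on inverted intensity
splits merged foci; regions under `min_spot_px` (default 4) are dropped.
These defaults are conventions: the original particle-analysis settings
were not published, and all three are config-exposed. On noiseless scenes
the sigma-clipped baseline converges to the exact nucleoplasm level, so
recovered footprints equal the sidecar's rasterized footprints exactly.
Watershed flooding order (and hence tie-breaking on plateaus) follows the
deterministic raster-order priority queue of scikit-image; a test checks
the labeling against an independent exhaustive flood-fill-by-descending-
threshold oracle on 64 × 64 fixtures. Coordinates are 0-based (x, y) =
(column, row); areas are reported in px² and, when the pixel size is known,
µm².

## Co-localization

The Pearson coefficient is computed over whole-nucleus masks (the main
open choice here: whole-field computation would dilute the statistic with
background pixels; the mask source is an argument, so callers can do
either). Bands are fixed: r ≥ 0.6 positive, 0.5 < r < 0.6 weak positive,
r ≤ 0.5 negligible. Pattern calls layer morphometry on top: low r or
unidentifiable foci → abolished binding; intermediate r → abolished
clustering; high r with significantly more and smaller chromocenters than
WT → impaired clustering; otherwise normal. Calls within 0.02 of a band
edge are flagged borderline rather than silently committed. Zero-variance
channels yield a missing value with a warning, never a number.

## Morphometry statistics

CN statistics use every analyzed cell; CS statistics exclude cells with
CN = 0 (their mean size is undefined, not zero), and a construct with fewer
than two sized cells is flagged not-analyzable rather than tested. CS is
the per-cell mean spot area (matching the per-cell averaging used for CN),
not a pooled spot distribution. The Mann–Whitney U test uses midranks for
ties; the p-value is exact by full enumeration of arrangements when
n₁ + n₂ ≤ 12 with no ties, otherwise the tie-corrected normal
approximation with continuity correction; two-sided p is twice the smaller
tail, capped at 1. Group size defaults to 20 cells per construct. No
multiple-testing correction is applied across constructs by default,
matching the single-comparison reporting the tiers come from.

## FRAP

The simulator puts the pre-bleach plateau at 1, models the ~200 µs bleach
pulse as instantaneous between frames (it is three orders of magnitude
shorter than a frame), and recovers along
I(t) = (1 − depth) + depth·mf·(1 − e^(−t·ln2/t½)). Acquisition
photobleaching is an exponential per-frame decay multiplying both signal
ROIs (default 0; 5 × 10⁻⁴ in realism tests); the background ROI is a
constant (default 0) plus noise. Acquisition defaults mirror the confocal
protocol (25 pre-bleach frames, 200 post-bleach frames at 108.784 ms).
Note that protocol spans only ~22 s, which cannot bracket a ~64 s
half-time; the generator therefore accepts arbitrary frame counts and
intervals, and the reproduction runs use 0.2 s frames with 2000 (slow
constructs) or 600 (fast constructs) post-bleach frames.

Normalization is the standard double + full-scale scheme (formulas in the
README). The full-scale anchor is a single frame, so its noise propagates
to every other point as a common offset; the fitted model therefore
carries a small free baseline b ∈ [−0.5, 0.5], and the mobile fraction is
the fitted amplitude A (not A + b), which cancels most of the anchor error.
Half-time is ln 2/k for the single exponential, or the numerical solution
of f(t) = (A₁+A₂)/2 above baseline for the double. Initialization: A₀ from
the last-decile mean, k₀ = ln 2 / (time to half of A₀), multi-started over
k₀ × {0.1, 1, 10}; non-convergence after all starts raises with
diagnostics. Model selection defaults to the single exponential; in `auto`
mode the double is adopted only when it improves adjusted R² by more than
0.01. Amplitudes above 1.1 trigger a super-recovery warning. R² is
computed over post-bleach points only. FRAP group size is 5 experiments
per construct.

## Severity

FSS uses the deviation-based default form given in the README — an
explicit stand-in, since the original composite's algebraic form is not
available in the source text; the functional form is injectable so a
different composite drops in without code changes. It is zero for a
WT-like mutant, monotone in each relative deviation, and scale-invariant.
Constructs whose binding or clustering is abolished carry a missing FSS
and are excluded from the correlation. CSS values are packaged
per-participant and averaged per mutation; the A140V entry uses the
Natural History Study value (10) with the literature range (1–5) retained
as a note. The FSS–CSS link is summarized by Pearson and Spearman
coefficients with two-sided t-approximation p-values.

## Pipeline and problem sizes

The orchestrated run simulates a construct panel whose clustering
impairment increases monotonically (spot count factor up to 2×, spot area
factor down to 0.4×), segments and scores every cell, fits FRAP panels
from the per-construct reference kinetics, and joins the morphometry to
the packaged CSS table. Default sizes — 6 cells per construct for imaging,
5 traces per kinetic construct, 20-cell groups for power/type-I studies,
100 seeded scenes for the recall/precision property — keep a full run and
the entire test suite in the tens of seconds while leaving all statistical
conclusions unambiguous at the simulated effect sizes. Reruns with the
same seed and config are byte-identical; the manifest records seed, config
hash and package version.

## Known limitations

- The synthetic scenes use non-overlapping spot footprints by default;
  heavily fused chromocenters (common in strong-clustering phenotypes) are
  only exercised through the dedicated two-peak watershed fixtures.
- The FRAP model is a pure-binding single/double exponential; diffusion-
  coupled recovery and spatial bleach profiles are out of scope.
- The FSS default form is a labelled stand-in, not a validated clinical
  composite, and the packaged CSS table covers eleven hemizygous cases —
  correlations on it are illustrative of the method, not new clinical
  evidence.
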