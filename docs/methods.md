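# Methods

## Model and procedure

`axoquant` quantifies lateral branching of a single axon from a 2D
maximum-intensity projection and a manual trace of the axonal shaft. The
trace is an ordered polyline in physical µm coordinates whose first
vertex is the proximal (dorsal) end; all downstream geometry is expressed
in the straightened frame it defines.

**Straightening.** The polyline is resampled at uniform arc-length steps
equal to the source pixel size in y. Tangents come from central
differences of the resampled path; the unit normal is the tangent rotated
by −90° in (x, y), so that for a trace running down the image the
positive transverse side is +x, a convention that is equivariant under
rigid rotation of image and trace. The straightened image samples the
source bilinearly at `path(s) + t·normal(s)` for transverse offsets
`t ∈ [−w/2, +w/2]` at steps of the source x pixel size. The column count
is `round(w / Δx)` forced odd so the shaft occupies the exact center
column; the row count is `floor(L / Δy) + 1` with L the trace length.
Samples falling outside the source are zero-filled and flagged in a
validity mask that all later stages honor. No spline re-fitting or
smoothing is applied to the manual trace beyond the central-difference
tangent estimate: the trace is taken as the analyst drew it.

**Masking.** Foreground is `intensity ≥ threshold` with the threshold from
Otsu's criterion computed on valid pixels only (a fixed threshold is
available as an escape hatch); a constant image yields an empty
foreground rather than an error. The foreground is skeletonized
(`skimage.morphology.skeletonize`) and each 8-connected component is
measured by its *geodesic length*: the longest shortest path over the
component's pixel graph with edge weights Δx (horizontal), Δy (vertical)
and √(Δx²+Δy²) (diagonal), computed exactly with Dijkstra from every
node. Components whose length does not *strictly* exceed the minimum
collateral length (default 0.5 µm) are removed; a component of exactly
0.5 µm is removed. The physical edge-weighted metric was chosen over
pixel count × pixel size because diagonal runs would otherwise be
underestimated by up to √2.

**Shaft-band excision.** Columns whose center lies within ±2.5 µm of the
shaft center (a 5 µm band) are flagged excluded, not deleted, so
transverse positions remain physically meaningful with a visible gap.
Because a collateral is rooted on the shaft centerline, only its extent
beyond 2.5 µm survives excision; a collateral therefore needs roughly
> 3.1 µm of lateral extent (2.5 µm band half-width plus the 0.5 µm
component filter) to register as a countable component. Validation
phantoms use collateral lengths of 4–8 µm for this reason.

**Densities and profiles.** The band-excised mask is binned into cells of
`bin_px` columns × 1 row (default 4 px; at the default 0.2483 µm pixel a
bin spans 0.9932 µm) and each cell's value is its foreground-pixel count
divided by the cell area `bin_px·Δx·Δy`, giving collaterals/µm²
(intensity/µm² when applied to the straightened intensity image). "Sum of
collaterals" per cell is interpreted as foreground-pixel count, not
distinct-component count, since components are not resolvable within a
4 × 1 px cell. Bins tile outward from the band edges on each side so bin
boundaries are registered to the shaft across images; leftover partial
windows at the image edges, and cells containing any invalid pixel, are
excluded. This tiling makes the conservation identity exact: summed
density × cell area over kept cells equals the foreground count within
their coverage. Transverse profiles average cells per signed transverse
bin over all rows of all images of a group (pooled, not mean-of-means;
per-image profiles are retained for statistics); longitudinal profiles
average per along-axon row, with shorter axons simply absent from distal
positions and per-position counts tracked. Group stacks are top-aligned
(proximal ends registered) and padded with excluded pixels; AVG/MAX
projections ignore padding. Straightening is treated as area-preserving;
no curvature correction of area elements is applied.

**Branching metrics.** Total branching is total collateral skeleton
length divided by axon length (dimensionless). Foreground length is
measured per pixel — each valid foreground pixel contributes
√(Δx·Δy) µm, equal to the pixel size on the isotropic grids the pipeline
produces — rather than by summing skeleton graph edges, so the
dorsal/ventral split at a row boundary is exactly additive:
`dorsal·70 + ventral·(L−70) = total·L`. The dorsal region is the first
70 µm from the proximal end, normalized by 70 µm (or by L when the axon
is shorter); the ventral region is the remainder, normalized by its own
length, and reported as absent — not zero — when L ≤ 70 µm. Component
counts are exposed alongside the length ratio as a robustness check. The
method does not classify branch order (primary vs secondary collaterals).

**Statistics.** Scalar comparisons are gated on normality: if both groups
pass Shapiro–Wilk at α = 0.05, an unpaired two-sided Student *t* is used,
otherwise a two-sided Mann–Whitney U — exact when the smaller group has
≤ 8 observations and the pooled sample is tie-free, else the normal
approximation with mid-ranks, tie-corrected variance and continuity
correction. Profile comparisons test each shared position with
Mann–Whitney across per-image profile values, excluding (and reporting)
positions with fewer than 3 valid observations per group, then control
FDR at q = 0.05 jointly across positions. The default step-up procedure
is the two-stage Benjamini–Krieger–Yekutieli (the documented default of
the mainstream graphing software for this analysis); plain
Benjamini–Hochberg is selectable. All tests are two-sided.

## Phantom generator

The generator emulates what the pipeline sees in practice: a bright,
gently curved shaft (Gaussian cross-section, σ = 0.35 µm, peak 200)
with straight lateral collaterals of controlled arc-position, side,
length, off-normal angle and intensity (default 150), an optional
radial terminal arbor, a flat background (10), optional Gaussian
read noise and Poisson resampling. Ridges are rendered from analytic
point-to-segment distances combined by per-pixel maximum, so the ground
truth (trace, per-collateral geometry, total collateral length) is
subpixel-exact and seeds reproduce images bit-for-bit. The default pixel
size is 0.2483 µm so the 4 px transverse bin spans exactly 0.9932 µm.

Three presets set the study conditions: `sparse_24hpf` (shaft ~70 µm,
2–4 collaterals of 1–3 µm — lengths chosen so most do not clear the
excised band, as minor collaterals at this stage barely leave the shaft),
`dense_48hpf` (shaft ~140 µm, 10–20 collaterals of 2–8 µm with 75%
placed ventral of 70 µm, plus a terminal arbor), and `aberrant` (the
dense layout with the bias moved dorsal). Noisy validation uses SNR 5,
defined as (collateral intensity − background)/noise σ = 140/28.

What the phantoms do *not* emulate: a realistic PSF and optical
sectioning, fasciculation with neighboring axons, intensity falloff with
depth, autofluorescent background structure, and tracing error in the
manual path (phantom traces are exact). Passing phantom tests therefore
demonstrates the correctness of the geometry, masking, accounting and
statistics — not robustness to tracing imprecision or to structured
biological background.

## Numerical choices and degenerate inputs

- Pixel coordinates are 0-based with centers on integer positions;
  µm = pixel × per-axis size. TIFF resolution metadata is trusted when
  present, a config override always wins, and the absence of both is an
  error — never a silent default.
- Bilinear interpolation throughout; out-of-bounds samples are zero with
  a validity flag rather than an exception, keeping masks conservative.
- Otsu thresholding uses 256 histogram bins over the valid-pixel range;
  foreground is taken strictly above the returned class boundary so both
  classes separate cleanly on integer data.
- A zero-length trace, a band wider than the image, an empty image list,
  a constant sample in Shapiro–Wilk, and groups of n < 3 are rejected
  with explicit errors.
- Problem sizes in the validation suite (phantom canvases of
  ~600 × 160 px, 19 + 20 axon group studies, 200-replicate null
  calibration at 80 positions) were chosen to exercise every code path
  at the study's own sample sizes while keeping a full run to a couple
  of minutes.

## Known limitations

- The per-pixel length metric in the branching summary slightly
  overestimates a component's geodesic length (an n-pixel straight run
  counts n, not n−1, steps); the bias is identical across groups and
  cancels in comparisons.
- Component counting after band excision merges collaterals that
  branch from a common trunk outside the band and splits collaterals
  that re-cross the band; counts are reported as a robustness companion
  to the length ratio, not as the primary statistic.
- The two-stage FDR procedure assumes independence or positive
  dependence across positions; neighboring profile positions are
  positively correlated, which is the favorable case.
- 3D traces are measured natively (point-to-point), but straightening is
  strictly 2D on the projection, so steeply diving axon segments are
  foreshortened in all image-derived quantities.
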