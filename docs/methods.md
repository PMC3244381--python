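# Methods

## Co-localization model

The analysis treats a nucleus as a grid of anisotropic voxels (default pitch
0.34 µm axially, 0.8 µm laterally) carrying two intensity channels.  A voxel
is *co-localized* when its intensity is strictly above the background
threshold in both channels simultaneously; ties at the threshold are
background, which matters for integer images.  The co-localized volume is
the voxel count multiplied by the physical volume of one voxel, computed
once from the pitch product and used identically everywhere.

Reported coefficients:

* **Pearson (PC)** — the sample correlation of voxel intensities over a
  region.  The default region is the nuclear mask: empty extracellular
  voxels are dark in both channels and would otherwise inflate the apparent
  correlation.  A whole-image variant is available.  Zero variance in either
  channel makes the correlation undefined; it is reported as NaN with a
  warning, never silently as 0, so population summaries can count
  exclusions.
* **Mander pair (M_green, M_red)** — the fraction of one channel's
  integrated intensity residing in voxels where the *other* channel is above
  its threshold.  Two denominator conventions are implemented because the
  field uses both: `total` (classic M1/M2 — the full channel intensity over
  the region; the default) and `thresholded` (both sums restricted to the
  channel's own above-threshold voxels).  Every result row records which
  convention produced it.  A zero denominator yields 0 with a warning.
* **Occupancies** — percent of region voxels above threshold per channel;
  `pct_occupied` is their sum (the two labels are nearly disjoint in
  segregated nuclei, so the sum approximates the union, which is also
  reported separately).

### Most-co-localized region of interest

Local mixing is bounded from above by cropping a fixed-volume box (default
65 µm³), cubic in physical units, placed by exhaustive stride-1 search to
maximize the co-localized voxel count inside it.  Ties are broken toward the
lowest (z, y, x) origin in scan order, so an entirely empty mask
deterministically yields the origin box with count 0.  The search uses a
3-D summed-area table, so it is exact, not heuristic.

## Preprocessing

* **Median 3×3×3** — each voxel takes the median of its 27-neighborhood
  (edge-replicated borders).  An isolated maximal-intensity voxel — the
  electronic-noise model — is eliminated exactly, because 26 of its 27
  neighborhood values belong to the surrounding field.  The same property
  means the filter deletes *real* structures smaller than about half a
  neighborhood; see "Known limitations".
* **Gaussian** — the sigma is specified physically (default 0.08 µm) and
  divided per axis by the pitch, so smoothing is isotropic in µm despite
  anisotropic voxels.
* **SD-rule threshold** — the per-channel threshold equals the standard
  deviation of the channel's voxel-intensity distribution.  The voxel
  population is configurable (`all`, `nucleus`, `positive`) and recorded;
  the default is the nuclear mask, which keeps empty extracellular space
  from dominating the statistic.
* **Nuclear mask** — the channel-sum image has three intensity regimes
  (dark exterior, faint diffuse nucleoplasm, bright foci), and the bright
  tail spans a much wider range than the gap the segmentation must find, so
  plain Otsu locks onto foci-versus-rest.  The default instead smooths the
  sum at a 0.4 µm physical scale, caps it at its 80th percentile so the
  bright tail cannot dominate the histogram, and applies Otsu to the capped
  image; the threshold then falls in the exterior/nucleoplasm gap, close to
  half the nucleoplasmic plateau, which is where the smoothed edge profile
  crosses the true boundary.  Morphological closing (anisotropic ellipsoid,
  2 lateral voxels), hole filling and largest-component selection follow.
  A user-supplied mask (e.g. a DNA counterstain) bypasses all of this.

## Synthetic nuclei

The generator emulates a nucleus pulse-labeled in two consecutive cell
cycles, after mitotic segregation has resolved uniquely labeled chromatin
domains.

* **Geometry** — a voxelized ellipsoid, default semi-axes (4.3, 9.0, 12.0)
  µm (volume ≈ 1945 µm³, matching measured nuclear volumes of ~1950 µm³),
  partitioned among 8 territories by nearest-seed Voronoi assignment in
  physical coordinates; seeds are uniform inside the ellipsoid.  Territories
  alternate green/red by default.
* **Foci** — each labeled territory receives 500 foci of 0.41 µm full-width
  at half maximum, packed around 8 sub-cluster anchors (Gaussian spread
  0.55 µm) scattered uniformly through the territory.  At a 0.8 µm lateral
  pitch individual foci are unresolved, and real labeled chromatin appears
  as contiguous patches; the dense sub-clusters reproduce exactly that.
  Rendering integrates the Gaussian flux over each voxel's extent (voxels
  bin photons), so a focus deposits its full intensity regardless of where
  its center falls relative to the grid — point-sampling would lose most of
  the flux of a sub-voxel blob centered between voxels.  Overlapping foci
  add linearly before clipping to the 8-bit range.
* **Ground-truth mixing** — foci within one focus diameter of a territory
  carrying the other label are *interface* foci; a fraction `f_mix` of them
  is relocated into the neighbor's occupied space, next to one of the twelve
  nearest other-channel foci (chosen at random so displaced foci tile the
  contact surface), with a quarter-diameter jitter.  The true mixed mask is
  defined operationally: voxels whose *noise-free* rendering (clipped to the
  bit depth) is above the SD-rule threshold in both channels.  Truth refers
  to what the detector records, not to unbounded model intensity.
* **Dispersion (TSA analog)** — `dispersion_factor` ≥ 1 multiplies the
  sub-cluster spread, lets foci land outside their own territory, and swells
  the rendered focus diameter by the square root of the factor (histone
  hyperacetylation both scatters and swells foci; the square root keeps the
  occupied volume from exploding quadratically with the scatter).
* **Noise** — additive Gaussian detector noise (sd 6 of 255) plus isolated
  maximal-intensity impulse voxels (probability 10⁻³ per voxel), the
  electronic-noise model the median filter exists to remove.  A faint
  uniform nucleoplasmic baseline (6 of 255 per channel) stands in for the
  diffuse label and autofluorescence that make nuclei segmentable in real
  images; without it the channel data contain no evidence of the nuclear
  boundary at all.
* **Randomness** — one master seed feeds fixed sub-streams (geometry, foci,
  noise, motion), so identical specs give bit-identical stacks and
  rendering extra time-lapse frames never perturbs the geometry.
* **Time lapse** — foci perform reflected (territory-confined) Gaussian
  random walks; the per-axis, per-frame step sd is 0.3 µm for early (green)
  foci — a mean 3-D step of ≈ 0.48 µm per 15-min interval, matching the
  ~0.5 µm scale of euchromatic focus motion — and 0.1 µm for late (red)
  foci, which additionally share a slowly drifting per-territory cluster
  anchor so they behave as coherent landmarks.

### What the generator does not model

No polymer or chromatin mechanics, no photobleaching, no full optical PSF
(blur enters only through the rendered blob width), no mitotic segregation
simulation, no karyotype-accurate territory count or size distribution.
Passing tests therefore show that the *measurement machinery* is correct and
recovers known ground truth under realistic sampling, noise and anisotropy —
not that any particular biological value is reproduced from real data.

## Tracking

Detection is a Laplacian-of-Gaussian scale-space search over the 0.2–0.8 µm
diameter range with per-axis sigmas in voxels (floored at one axial voxel
and 0.4 lateral voxels so sub-voxel scales do not lock onto shot noise).
Two rejection rules follow from the physics: a candidate whose peak does not
clear the channel's SD threshold is background, and a candidate whose axial
neighbors carry under 10% of its peak is a single-section spike (electronic
noise), since a real focus is imaged across several optical sections.
Surviving candidates are refined to background-subtracted intensity-weighted
centroids.

Frames are registered by translation only, estimated as the mean
displacement of mutual-nearest-neighbor-matched landmark foci (the stable
late class); fewer than three matches gives an identity step with a warning.
Linking is per-class mutual nearest neighbor within a 1.5 µm gate; a link
whose competing candidate lies within 10% of the best distance is dropped —
only unambiguously trackable foci enter the statistics, mirroring how such
data are analyzed in practice.

The mobility statistic fixes neighbor pairs at the first frame (separation
within 4 µm — the pairing radius has no literature-prescribed value and is a
config parameter), follows each pair through the series, and reports
|d(t+1) − d(t)| per interval, normalized to µm per 15 min.  Four frames give
three values per pair.  The absolute-value convention is the default
(a signed variant is available); pairs are pooled per class as G/G and R/R.

The time-lapse study condition (`focimix.synth.timelapse_spec`) uses 4
territories with 8 foci each and a 1.8 µm minimum same-channel focus
separation: mobility analysis is only meaningful on foci that can be
followed without ambiguity, so the condition generates exactly such foci.

## Statistics

Two-sided tests throughout; p-values are reported raw (no multiple-testing
correction by default — a Holm/Bonferroni option exists but matches the
field's raw presentation when off).  Mann-Whitney uses exact enumeration of
all C(n+m, n) group assignments (correct under ties) when both samples have
at most 8 observations, and the tie-corrected normal approximation with
continuity correction otherwise; all-identical pooled samples give p = 1.
Kruskal-Wallis is tie-corrected with a chi-square reference; a fully
degenerate input gives (H = 0, p = 1).

## Numerical and design choices

* Axis order is fixed (Z, Y, X, channel) internally; coordinates are 0-based
  and voxel-centered, distances always in µm.  The axial pitch differs from
  the lateral pitch, so axis confusion would silently corrupt volumes.
* Strict `>` thresholding (a voxel exactly at the threshold is background).
* Median-filter border policy is edge replication; recorded as a module
  constant.
* The Gaussian filter's 0.08 µm parameter is interpreted as the physical
  standard deviation.
* `coloc_report` returns two rows — whole nucleus and most-co-localized
  ROI — because every published comparison needs both views side by side.
* Validation problem sizes (10–20 nuclei per arm, 20 seeds per mixing
  level, 10 time-lapse series) were chosen as the smallest populations at
  which the compared distributions separate cleanly; the demo accepts
  larger populations via `--n`.

## Known limitations

* The 3×3×3 median filter deletes sub-voxel minority-channel structures: a
  displaced focus surrounded by the other channel's chromatin has almost no
  same-channel support in its 27-neighborhood and is removed exactly like an
  impulse.  Filter choice therefore changes apparent co-localization
  dramatically (Gaussian > raw > median, as the validation suite checks),
  and ground-truth mixing recovery is assessed with the unfiltered
  SD-thresholded configuration.
* The SD-rule threshold is a population statistic: it shifts when the
  labeled fraction of the nucleus shifts (e.g. under strong dispersion), so
  comparisons across very different occupancies mix threshold and signal
  effects — a property of the empirical rule itself, not of this
  implementation.
* Registration is translation-only; slow territory rotation leaks into the
  mobility statistic as a small additive term for both classes.
* The exact Mann-Whitney enumeration is O(C(n+m, n)) and is capped at
  samples of 8 by default.
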