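# Methods

## Imaging model

The acquisition is modelled as a **parallel-beam** tomography of a cleared,
non-scattering sample: a telecentric OPT setup with high depth of field is
conventionally treated this way, and no refraction, scattering,
point-spread-function or clearing-shrinkage effects are simulated. Slices
perpendicular to the rotation axis (grid axis 0) are independent; each is
projected with the parallel-beam Radon transform (`skimage.transform.radon`)
at n equally spaced angles over [0°, 360°), endpoint-exclusive. Opposing
views are redundant for parallel beams; the full rotation is kept anyway to
mirror how such data are acquired, at the cost of a factor-two oversampling.

Reconstruction is an in-package filtered back-projection:

* profiles are zero-padded to a power of two ≥ 2× their length (wrap-around
  suppression), multiplied by 2|f| in the frequency domain and cropped;
  the zero-frequency gain is exactly 0 for the Ram-Lak filter. The Hann
  option multiplies by a raised cosine falling to zero at Nyquist —
  noise-robust at the price of resolution;
* back-smearing uses linear interpolation at t = y cos θ − x sin θ around a
  rotation axis at detector column `n // 2` — the same convention the
  forward transform uses, which matters: a half-pixel mismatch costs ~2% of
  round-trip correlation;
* the accumulated image is scaled by π/(2n) and voxels outside the inscribed
  circle, which the projections never measure, are zeroed.

On a 128×128 two-layer disk, 400 angles give a round-trip correlation of
0.993 inside the reconstruction circle, and correlation with
`skimage.transform.iradon` of > 0.99; the small residual difference comes
from the textbook |f| frequency response used here versus skimage's
real-space-derived filter, which treats the lowest frequencies slightly
differently.

## Synthetic phantoms

The gut phantom is a straight tube on the rotation axis with the wall layers
of the small intestine at fixed autofluorescence intensities: lumen 0,
mucosa 0.8, submucosa 0.4, muscularis 0.6 (dimensionless, in [0, 1]).
Defaults describe a scaled-down segment — 96³ voxels at 5 μm, layer radii
110/175/205/230 μm — chosen so that the full simulate–reconstruct–unfold
chain runs in seconds while keeping every layer several voxels thick; tests
that probe micrometre-scale quantities (follicle volumes, 500 μm spacing)
use longer grids of the same wall geometry.

**Villi** are radial bumps on the mucosal inner surface: the surface radius
is r(θ, z) = r_lumen − L·b(θ)·b(z) with cos²-shaped bumps of physical width
w (default 40 μm, length L = 55 μm) on a regular lattice — `count_per_ring`
azimuthal positions × rings spaced every 2w along the axis, offset by half a
period so no villus straddles the cardinal seam angles. The apex count is
therefore exact by construction, which is what the density-recovery tests
need. Real villi vary in shape, size and placement; the phantom does not
model that, so passing tests demonstrate correct *detection geometry*, not
robustness to biological shape variation.

**Follicles** are ellipsoids with a super-Gaussian profile
peak·exp(−ln2·ρ⁴), ρ² the normalised ellipsoid coordinate, so the
half-maximum isosurface coincides with the analytic boundary and half-peak
thresholding recovers (4/3)πabc. A pure Gaussian profile has no defined
boundary — measured volume would then be a function of the threshold, and
"volume recovery" would be meaningless. **Cells** are single bright voxels
placed uniformly at random in a named wall layer. Noise is additive Gaussian
(σ in intensity units; the acquisition noise model is not otherwise
constrained), deterministic under the spec's seed.

The synthetic cryosection generator places point cells uniformly on a
compact nuclei mask built to contain exactly `round(area/pixel_area)`
pixels, so the ground-truth density `count/area` is exact; requests denser
than one cell per four mask pixels are rejected as unresolvable. The mask is
a synthetic block, not a tissue silhouette — sufficient for density
arithmetic, not for morphology.

## Virtual unfolding

Per slice: Otsu global threshold → lumen hole-filling → largest connected
component → outer boundary. The boundary is traced on a σ = 1.5 px blurred
copy of the mask at the 0.5 level: the level set of the blurred indicator is
a sub-pixel smooth curve, whereas a marching-squares contour of the raw
binary mask overestimates a circle's perimeter by ~5% through staircase
inflation (measured on the annulus oracle; the smooth trace is within 0.2%).

Angle convention: counterclockwise from +x with y down (image coordinates);
outlines are traversed counterclockwise as seen on screen, fixed so the
unfolded orientation is reproducible. The seam is the outline vertex closest
to the centroid ray at the seam angle (default 45°), ties broken by lowest
vertex index. Seams are chosen per slice with no inter-slice regularisation,
mirroring per-section processing; for straight tubes they are collinear to
within a pixel anyway.

Straightening resamples the outline at uniform arc length (step defaults to
one voxel) from the seam and reads intensities by bilinear interpolation
along inward normals over [−band_outer, +band_inner]; normals come from the
tangent of a 5-vertex moving-average smoothed curve to suppress pixelation
jitter, and inward samples are clamped at the centroid (with a warning) when
the band overshoots it. Rows are radial depth, lumen side last; strips are
zero-padded on the right to the longest perimeter, seam-aligned at column 0.
The unfolded volume is a pure axis transposition of the straightened stack.

Flattening ignores the polar Jacobian: a layer at depth d of a tube of
radius R is stretched by R/(R−d). Band intensity sums therefore match the
band-masked slice mass only for bands thin relative to R (the property test
uses a 10 μm band on R = 120 μm, with (1 − d/R) and trapezoid end weights,
and agrees within 5%); deep-band unfolded images are for localisation and
counting, not densitometry. Non-convex and branched cross-sections are out
of scope; the 45° origin on a non-convex outline is whatever vertex is
nearest the ray.

## Quantification

Villus apexes: blobs of diameter w have maximal scale-normalised LoG
response at σ = w/(2√2); detection uses −σ²·LoG with `peak_local_max`,
an absolute response floor `min_prominence` (default 0.05, ≈ 6% of the
mucosal intensity — safely above the response a 10%-of-amplitude noise
floor produces after LoG smoothing) and a minimum separation of one villus
width to avoid double-counting plateau apexes (ties broken by pixel order).
Sector binning floors coordinates into square sectors, so sector counts
partition the total exactly.

Follicle segmentation smooths at σ = 2 μm (converted to voxels), thresholds
on absolute intensity — the threshold is a required user parameter, as in
practice it is set visually per stain — labels with 26-connectivity (better
matched to smoothed blobs than 6-connectivity) and drops objects below
`min_voxels`. Distance statistics are all-pairs by default ("distance
between each follicle" is ambiguous; all-pairs min gives the
nearest-neighbour distance), with an axial-nearest-neighbour mode for
samples mounted along the axis. The OPT-visibility comparison is inclusive
(≥ 400 cells/mm²) and the threshold configurable, since it is an
approximate, setup-dependent figure.

## Section tracking

Sections are zero-based half-open intervals [k·t, (k+1)·t) from the cutting
face at the configured origin end, so the axis is partitioned without double
assignment; index computation is floor/ceil arithmetic verified against a
brute-force interval scan. Extents measured from opposite ends are mirror
images summing to the sample length. No shrinkage correction is applied by
default (an optional linear scale factor exists); distances are along the
straight grid axis, so curved samples must be mounted straight.

## Reproducibility and problem sizes

All randomness flows through `numpy.random.default_rng` seeded from the
phantom spec or the acceptance script's `--seed`. The acceptance script and
test suite use scaled-down problem sizes — 128×128×32 disks at 400 angles,
96-slice gut segments, 560-slice follicle grids — chosen as the smallest
geometries in which every measured quantity is still several voxels/samples
above its resolution limit; all figures it reports are computed at run time,
none are stored.

## Known limitations

* No optical PSF, refraction, absorption or depth-dependent blur; FBP
  fidelity figures are upper bounds for real acquisitions.
* Slices are processed independently; gut curvature and torsion are not
  corrected (straight-mounting is assumed end to end).
* The phantom's regular villus lattice and super-Gaussian follicles are
  idealisations; parameter recovery on them validates the geometry and
  arithmetic of the pipeline, not its robustness to biological variability.
* Even-sized slice grids put the rotation axis half a pixel off the image
  centre of symmetry; phantoms are built on the axis convention, but a 90°
  `rot90` of an even grid does not commute with it exactly (the rotation
  consistency test uses odd grids).
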