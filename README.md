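# gutopt

Mesoscale imaging analysis of the intestine with optical projection
tomography (OPT): projection simulation and filtered back-projection
reconstruction, **virtual unfolding** of the tubular gut wall, quantification
of villous density and isolated lymphoid follicles (ILFs), and **reverse-OPT**
tracking of 3D regions of interest into physical cryosections.

The package is aimed at labs doing whole-organ cleared-tissue imaging of
tubular organs who need a tested, scriptable version of this processing
chain — and at anyone who wants to validate such a chain end to end, since
every stage here can be exercised on synthetic two-channel gut phantoms
(autofluorescence wall layers + fluorescent-marker follicles and cells)
whose ground truth is known analytically.

## What it computes

**Tomography.** OPT is modelled as a parallel-beam Radon transform applied
slice-by-slice along the rotation axis: a projection at angle θ is the line
integral p(s, θ) = ∫ f(x, y) δ(x cos θ + y sin θ − s) dx dy, acquired at
n equally spaced angles over [0°, 360°). Reconstruction is classical FBP:
each profile is multiplied by |f| in the frequency domain (Ram-Lak; Hann
apodisation optional), back-smeared with bilinear interpolation and scaled
by π/(2n).

**Virtual unfolding.** Each cross-section is segmented (Otsu threshold,
lumen filled, largest component), its outline cut at a seam chosen at a
configurable angle (default 45°) from the centroid, re-parameterised by arc
length and sampled along inward surface normals over a radial band. Stacking
the straightened strips and re-slicing orthogonally yields unfolded images:
one layer per radial depth, spanning the whole sample surface from the outer
wall down to the lumen.

**Quantification.** Villus apexes are detected on unfolded layers as local
maxima of a Laplacian-of-Gaussian response at the villus scale and binned
into sectors (counts/mm²). Follicles in the marker channel are segmented by
Gaussian smoothing (default σ = 2 μm), absolute-intensity thresholding and
26-connected labelling with a minimum voxel-count filter; volumes are
voxel counts × voxel³ and spacing is summarised by min/mean/max
centroid-to-centroid distances. Cell density in cryosection images is cells
per mm² of nuclei-mask area, with a configurable OPT-visibility threshold
(default 400 cells/mm²).

**Reverse OPT.** An ROI's axial extent, measured from either end of the
sample, maps to the half-open windows [k·t, (k+1)·t) of t-μm-thick sections
(default t = 25 μm); observed high-density sections are matched back to the
ROIs that predicted them.

## Worked example

`examples/04_follicle_segmentation.py` renders four spherical follicles with
analytic volumes of 1, 2, 3 and 5 million μm³ at 5 μm voxels, 500 μm apart,
and recovers them:

```
analytic 1.0 Mum^3 -> measured 1.003 Mum^3 (+0.30%)
analytic 2.0 Mum^3 -> measured 1.998 Mum^3 (-0.10%)
analytic 3.0 Mum^3 -> measured 2.998 Mum^3 (-0.07%)
analytic 5.0 Mum^3 -> measured 4.977 Mum^3 (-0.46%)
mean nearest-neighbour spacing: 500.0 um (follicles were placed 500 um apart)
```

Every measured volume sits within half a percent of the closed-form
(4/3)πabc value, and the spacing statistics reproduce the construction
exactly — which is what licenses applying the same operations to real
reconstructions. The other examples cover simulation + reconstruction
(round-trip correlation 0.9928 at 400 angles), unfolding (width within 0.13%
of the analytic perimeter), villous density (48/48 apexes recovered) and
section tracking (extent 1000–1200 μm → sections 40..47).

There is also a thin CLI mirroring the library:
`gutopt phantom|simulate|reconstruct|unfold|quantify|revopt|run`, e.g.

```bash
gutopt run --out results/demo --seed 1
```

runs the full phantom → simulate → reconstruct → unfold → quantify → revopt
chain and writes TIFF/CSV artifacts plus a machine-readable `report.json`.

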