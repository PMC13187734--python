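# Methods

This note documents the models, conventions and numerical choices behind
`ldquant`, what the synthetic generators do and do not emulate, and the
design decisions taken where the quantities admitted more than one
reasonable definition.

## Image conventions

Images are 2D grids indexed (row, col), 0-based, with coordinates at pixel
centres; multichannel images stack channels on the first axis. Masks are
boolean. Multi-page TIFF (one page per channel) plus a JSON sidecar naming
channel roles is the on-disk form; all truth and result tables are CSV.
Intensity noise in the generators is additive Gaussian truncated at zero —
the simplest parameterized model that exercises the estimators; it does not
emulate shot noise, optics (PSF blur), bleaching, or uneven illumination,
so passing tests say nothing about segmentation robustness on real
microscopy data, only about the correctness of the statistics downstream of
segmentation.

## The dispersal statistic D_F

For a droplet centroid p inside a segmented cell,

    D_F(p) = d_nuc(p) / (d_nuc(p) + d_bnd(p)),

where `d_nuc` is the Euclidean distance transform to the nucleus mask (zero
on and inside the nucleus) and `d_bnd` the distance transform to the cell's
boundary pixels (the cell pixels removed by one binary erosion). Both maps
are sampled bilinearly at the (sub-pixel) centroid. This definition:

* is exactly 0 on the nucleus boundary and exactly 1 on the cell boundary,
  the two printed anchor values;
* reduces to the radial fraction (rho − r)/(R − r) in concentric circular
  geometry (verified to ±0.02 rasterization tolerance at R = 100 px);
* is monotone along paths on which `d_nuc` grows and `d_bnd` shrinks, and
  is topology-agnostic: it needs no cell centre, so it remains meaningful
  for elongated or non-convex cells.

A ray-based alternative (fraction of the nucleus-centre-to-boundary ray)
would agree on circular cells but is undefined for non-star-shaped masks;
the distance-transform form is the implemented choice. Centroids inside
the nucleus score 0 with a warning; centroids outside the cell are errors.

Summaries report the sample SD (n−1) by default, population SD by flag.
Both per-cell and pooled-droplet aggregations are emitted, since either
pooling could have been used for the published bar plots.

The cell-scene generator samples per-droplet radial fractions from a
Beta(40·t, 40·(1−t)) law — mean exactly the dispersal target t, with
realistic spread — and places centroids at radius r + f·(R − r). The
extremes t = 0 and t = 1 are placed exactly on the nucleus/cell boundary.
Measured recovery bias of the mean over 500 droplets is < 0.01.

## Peripheral intensity ratio

The peripheral band is the set of cell pixels with `d_bnd` ≤ band_fraction
× equivalent radius (sqrt(area/π)); the ratio is band intensity over
whole-cell intensity. The band width is not fixed by any published
definition; the default band_fraction = 0.2 is explicit and sweepable. For
a uniform image the ratio equals the band's pixel-count fraction exactly.

## Bead-supported membranes

Rings are detected by circle Hough transform on Canny edges with greedy
non-overlap suppression; on a painted ring of width w the detected radius
locks onto an edge circle and can differ from the nominal radius by ~w/2,
which is why measurement uses an annulus of configurable half-width
(default 2 px) around the detected radius. `profile_mean` is the raw
annulus mean; `annulus_integral` subtracts the background (median of
pixels outside all bead disks) per pixel before summing, so constant
offsets cancel.

Retention ratios divide the *arm means* (after / before), not per-bead
paired ratios — beads are not paired across treatment, and the published
formulas divide arm averages. Uncertainty is first-order (delta-method)
propagation of the two arm SDs; a seeded bootstrap percentile CI and the
SD of bead-level after/mean-before ratios are also reported, since a
printed "±" could be either convention.

The generator paints annuli of uniform intensity: monolayer rings default
to half the bilayer intensity (one leaflet of dye instead of two), and the
after-image ring intensity is retention_true × the before intensity. The
surface-area normalization factor is the leaflet-count ratio: monolayer
vs bilayer → 0.5.

## Trajectory contact statistics

Frames hold single-site particles (one bead per residue, one per lipid);
all statistics here operate on distances and labels only, so coarse
single-site particles test them as rigorously as all-atom coordinates
would. Multiple sites per molecule are supported by grouping on
(kind, index); any site within cutoff counts the molecule as in contact —
headgroup and tail sites are never distinguished.

* **Periodicity.** Minimum image in x and y only; z (membrane normal) is
  non-periodic, matching slab geometry.
* **Cutoff.** 0.7 nm is stated explicitly for the lipid fraction; the same
  single coherent contact definition is applied to occupancy by default,
  exposed in config.
* **Implementation.** Cell lists (in-plane cells ≥ cutoff wide, wrapped;
  z binned from the data minimum) with a 27-neighbourhood search; an
  all-pairs brute-force oracle is kept in the package and the two are
  asserted identical on random frames in the tests.
* **Occupancy.** O_ij = (#frames with any class-i lipid in contact with
  residue j) / (#frames); frames equally weighted ("time fraction" under
  uniform sampling). ⟨O⟩_j is the *unweighted* mean of the DOPC and DOPA
  occupancies (not lipid-count-weighted — "averaged across" the two
  classes). O_any (either class) is also emitted for parameter recovery.
* **Δ⟨O⟩_j** = ⟨O⟩_j(monolayer) − ⟨O⟩_j(bilayer), in percentage points;
  positive favours the monolayer. A residue is `reported` only when its
  ⟨O⟩_j exceeds 5 % in at least one system. Summary means over reported
  monolayer-favouring (Δ > 0) and bilayer-favouring (Δ < 0) residues are
  attached to the table. Δ is antisymmetric under swapping the systems.
* **Lipid fraction.** Per frame, N = number of group residues in contact
  that frame (the closest reading of "N residues interacting"; the
  fixed-group-size denominator is available by flag), L_n = distinct lipid
  molecules (DOPC, DOPA or TG by default; class-restricted variants by
  flag) contacted by the group, L_f = L_n/N. Frames with N = 0 are
  undefined and excluded; P(L_f) is a normalized histogram over defined
  frames (mass 1 whenever any frame is defined).
* **APL** = Lx·Ly / (phospholipids in the leaflet). **Thickness** = mean z
  of upper-leaflet phospholipid sites − mean z of lower-leaflet sites.
* **RMSD.** Kabsch superposition (SVD with reflection correction) before
  RMSD when fit=true; reference defaults to the first frame (the original
  reference is unstated; it is configurable). Cross-checked against
  MDAnalysis' superposition in the tests.
* **Secondary structure.** Assignments (helix/sheet/turn/coil) are
  consumed from input, never computed; the module only counts fractions.

The trajectory generator places residues on a safe-spaced grid 1 nm above
the upper leaflet and draws per-frame Bernoulli contacts per residue; on a
hit, the residue's designated partner phospholipid moves into the 0.7 nm
shell. Geometry guarantees no accidental contacts (leaflet plane 1 nm
away; residue spacing 1.5 nm > 2 × cutoff), so the empirical contact
fraction is an exact binomial estimator of the programmed probability.
Phospholipid classes are drawn i.i.d. DOPC:DOPA = 95:5. The monolayer
variant inserts TG particles in a slab of stated thickness (default 3 nm)
between the leaflets and reduces leaflet packing by an APL factor (default
1.08) to encode the looser, TG-interdigitated monolayer surface; leaflet
separation is the slab plus 1 nm of headgroup offsets versus 3.7 nm for
the bilayer (a typical phosphate-to-phosphate distance). The generator
does not emulate lateral diffusion, correlated contacts, membrane
undulations, or realistic lipid conformations — only the label/distance
structure the statistics consume.

Box and counts in examples and tests (e.g. 9×9×8 nm, 20 lipids/leaflet,
110-residue default peptide span) are chosen so the full suite and the
recovery checks run in seconds on one CPU; they are small-scale stand-ins
for microsecond trajectories, which are out of scope.

## Colocalization and morphometry

Pearson is computed over (optionally masked) pixels; constant channels are
flagged NaN. Manders M1 is the fraction of channel-1 intensity on pixels
where channel 2 exceeds its threshold (Otsu per channel by default),
symmetrically for M2 — meaningful in the dark-background/bright-puncta
regime colocalization assumes. Costes-style automatic thresholding is out
of scope. Droplet counting is scale-normalized Laplacian-of-Gaussian blob
detection; blobs closer than the suppression radius merge into one
detection (documented behaviour). Fold changes are ratios of mean counts
with a seeded bootstrap percentile CI.

## Organism readouts

Calibration is unweighted ordinary least squares (no replicate variances
are recorded for serial dilutions); inversion uses the classical
inverse-prediction standard error and floors negative estimates at zero
with a flag. Track total distance is the sum of step lengths. "Angular
velocity" is implemented as the mean absolute wrapped heading-change rate
(rad/s) over interior samples whose adjacent steps both exceed a jitter
floor (default 0.5 px), so positional noise at rest does not read as
turning. The first-stop criterion — speed below threshold (default
1 px/s) continuously for a dwell time (default 0.5 s) — is configurable,
and stop time is monotone in the threshold. Zone schemes (concentric ring
radii) are user-supplied, as no radii are published. The track generator
is a constant-speed correlated random walk with Gaussian turning, Bernoulli
stop events and reflecting arena walls; real larval kinematics (burst-glide
swimming, speed variability) are not emulated, so track tests validate the
metrics, not biological realism.

## Known limitations

* Segmentation is threshold + nucleus-seeded watershed; adequate for the
  synthetic scenes it is tested on, not a general cell segmenter.
* D_F is 2D; z-stacks are out of scope, as is droplet tracking over time.
* The suite quantifies; it makes no inference about motor activity itself.
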