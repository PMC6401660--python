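# Methods

This note documents the models, conventions and parameter choices behind
synquant, in the spirit of a methods section: what is computed, under what
assumptions, and what the synthetic validation does and does not show.

## Coordinates and calibration

Stacks are `(channel, z, y, x)` volumes or `(time, y, x)` time-lapses with
per-axis physical spacing in μm. Voxels are anisotropic by default
(0.5 μm z-steps, 0.1 μm in xy), matching common epifluorescence z-stack
acquisition; every distance and landmark is expressed in μm, never in
voxels. The center of voxel `i` sits at `(i + 0.5) · spacing` (voxel-center
convention), which makes centroid arithmetic exact for symmetric phantoms.
TIFF output uses ImageJ-style metadata (spacing, unit, axes) plus a JSON
blob carrying channel names and frame intervals; files without calibration
must be read with an explicit spacing override.

## Conjugate indices

**Polarity index.** `p = ⟨Cent − CMC, BMC − CMC⟩ / |BMC − CMC|²` — the
signed scalar projection of the centrosome onto the cell→bead axis,
normalized by the axis length. The sign convention puts +1 at the bead mass
center and −1 at its reflection through the cell mass center. Values
outside [−1, 1] are geometrically possible (a centrosome projecting beyond
the bead center); they are reported unclamped with a flag rather than
truncated, preserving information. Landmarks may come from 3-D coordinates
or from 2-D projections; both carry the same formula.

**Centrosome–nucleus distance.** Euclidean distance in μm between the
centrosome and the nucleus mass center. Because all landmarks are physical
coordinates, anisotropic spacing is respected by construction.

**Density index.** `DCent/DCell` with `DCent = FCent/ACent` over a
1 μm radius region at the centrosome and `DCell` over the whole cell. The
default mode quantifies a *circle* in the z-slice nearest the centrosome
(both densities in that plane), matching single-plane practice; a 3-D
sphere mode is available. Uniform fluorescence gives exactly 1 in either
mode; the 1 μm radius is exposed as a parameter.

**Recruitment %.** `100 · F(bead region)/F(cell ∪ bead region)`. The bead
region is a sphere of radius `bead_radius + margin` (margin default
0.5 μm) that must be identical across all beads of a batch — the
"fixed area" contract that makes totals comparable. Including the bead
region in the denominator bounds the metric to [0, 100].

**Extraction %.** Per bead, `100 · (1 − F_bead/mean(F_reference))`, with
the reference taken as the mean over a non-extracted bead population
(time 0 or non-activating ligand): fixed-cell assays have no per-bead
before/after pairs. Totals are computed on z-sum projections restricted to
the bead region; summation commutes with projection, so this equals the
3-D regional total exactly (a tested invariant). No background subtraction
is applied by default; an optional per-voxel background constant can be
subtracted and is recorded with the run. A diffuse background inside the
fixed region biases extraction multiplicatively toward 0, which is why the
phantom's antigen channel defaults to zero diffuse background.

## Segmentation

Cells were traditionally outlined by hand; synquant replaces this with one
documented automated rule used identically in 3-D and 2-D: Gaussian
smoothing (σ = 1 px per axis), Otsu threshold, keep the connected component
containing the brightest smoothed voxel, fill holes. The centrosome is the
brightest point of the smoothed tubulin channel inside the cell mask, with
ties broken deterministically by lowest (z, y, x) scan order. Mass centers
are binary-mask centroids by default (an intensity-weighted option exists);
whether the bead contact region is excluded from the cell mask is an
explicit switch (off by default). Smoothing may be disabled (σ = 0) for
noiseless two-level images, where thresholding is already exact.

## Synaptic-plane partition and kinetics

The center template is an ellipse at the footprint centroid whose
orientation and aspect follow the mask's second moments (a circle when
eccentricity < 0.2), scaled by bisection until its intersection with the
mask holds one third of the mask area; the partition is an exact set
difference, so areas are additive by construction and the center fraction
is within rasterization error (±0.02 enforced for footprints ≥ a few
hundred px) of 1/3. The periphery index and central fraction are ratio
metrics and thus invariant under intensity rescaling.

Spreading velocity is the least-squares slope of area vs time from t = 0 to
the first frame reaching 95% of the maximum area, extended to at least
three frames so that an already-spread (constant-area) movie fits a flat
line with velocity 0 instead of failing; the window and fit residuals are
always reported, since slope extraction from a saturating curve depends on
the window choice (for the default phantom curve the least-squares slope
sits ~10% below the window secant). Kymographs sample bilinear intensity
profiles along a line through the first segmentable frame's centroid
(default: major principal axis), one column per frame, at the pixel pitch.

## Phantom generator

Geometry is spherical implicit surfaces rasterized to the voxel grid —
cell (radius 4 μm, a typical activated B cell lymphoblast), nucleus
(2.2 μm, offset anti-podal to the bead), a 3 μm-diameter bead tangent to
the cell surface, and a centrosome placed to realize a requested polarity.
Spheres keep every mass center analytic, so segmentation and landmark
errors are measurable exactly. Ground truth is a validated pydantic model
serialized as a JSON sidecar next to each TIFF (paired by filename stem);
`polarity_true` is derived from the stored geometry, so the truth is
consistent with the index definition by construction.

Channel models (defaults in `DEFAULT_PARAMS`): a tubulin Gaussian spot
(σ 0.3 μm) over a faint cytoplasmic haze; actin as cytoplasmic fill +
cortical shell (0.3 μm thick) + an optional centrosomal Gaussian pool whose
weight is the knob for "centrosomal actin"; LAMP-1 as 40 puncta of which a
fraction `lysosome_polarization_true` sits in the synaptic cap inside the
fixed bead region; an antigen (OVA) shell on the bead scaled by
`1 − extraction_fraction_true` with zero diffuse background; DAPI as the
filled nucleus. Noise is the standard camera model
`Poisson(photon_scale · expectation)/photon_scale + N(0, read_sigma)`,
clipped at 0; `photon_scale = snr²/amplitude` gives a requested peak SNR,
and `photon_scale=None` renders the noiseless expectation. All randomness
(puncta placement, noise) derives from the scene seed via named
sub-streams, so a fixed seed reproduces stacks bit-exactly. An optional
Gaussian blur stands in for the optical PSF and is off by default — tests
are sharper and the rasterized geometry stays analytic.

Spreading movies render a disk footprint following
`A(t) = A0 + (A_max − A0)(1 − e^(−t/τ))` (defaults A0 30 μm², A_max
120 μm², τ 120 s — a small lymphocyte spreading over ~5 min), with total
fluorescence conserved over time and a fraction `ring_fraction` (default
0.75) placed in the annulus outside the concentric one-third-area disk,
emulating the peripheral actin ring; `ring_fraction > 2/3` is what makes
the periphery index read positive. The default frame interval is 15 s;
10 s framing, as used for kymograph-style acquisitions, is a plain
override — neither is privileged.

Because the centrosome must lie inside the cell, rendered phantoms can only
realize polarities up to about `r_cell/(r_cell + r_bead) ≈ 0.73`; the
recovery suite samples polarity uniformly in [−0.6, 0.6]. The ±1 endpoints
of the index are exercised with bare landmark configurations, which the
formula admits directly.

## Parameter recovery and the two-condition experiment

The recovery suite (`synquant.pipeline.recovery_suite`, also behind
`synquant recover`) renders 50 phantoms at SNR 10 with randomized polarity,
extraction and lysosome polarization, measures everything from the images
(bead geometry comes from the sidecar, as it would from a bead channel or
annotation in real data), and requires every scene to recover polarity
within ±0.1, extraction within ±5 points and the centrosome–nucleus
distance within one voxel diagonal (≈ 0.52 μm at default spacing).

`simulate_two_condition_experiment` renders paired "control" and
"inhibitor-like" phantoms (the latter with higher centrosomal actin weight
1.2 vs 0.3, lower lysosome polarization 0.25 vs 0.70, lower extraction
0.20 vs 0.50, lower polarity 0.15 vs 0.55, and spreading movies with
halved A_max and doubled τ, each jittered per pair) and checks that the
measured ordering — higher density index, lower recruitment, extraction,
polarity and spreading velocity under inhibition — holds in ≥ 95% of
pairs. Problem sizes (50 recovery scenes, 20 pairs) keep the full suite at
about half a minute on one CPU while leaving the stochastic margins wide.

## What the phantoms do not show

The generator emulates geometry, intensity structure and shot/read noise —
not optical aberrations, non-spherical or motile cells, clustered
lysosomes, uneven antigen coats, or out-of-focus haze. Passing recovery
therefore demonstrates that the *measurement chain* is correct and
unbiased under the stated imaging model, not that segmentation is robust
to every real-world artifact; on real data the manual-annotation entry
points (bead/cell seeds, explicit spacing, background constants) exist for
exactly that reason. Hypothesis-testing statistics across conditions are
out of scope beyond mean ± SEM exports.
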