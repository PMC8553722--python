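# Methods

This note documents the models, algorithms and numerical choices behind
`myomol`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the design was genuinely open.

## Coordinate and measurement conventions

Axis order is `(z, y, x)` throughout; voxel indices are 0-based and the
physical position of voxel `i` along an axis with pitch `dv` is
`(i + 0.5)·dv` µm (voxel centers). All distances are in µm. Puncta are
26-connected components; the nuclear perimeter uses 6-adjacency. These
conventions are fixed so that results are bit-reproducible across runs.

## Distance to the nuclear perimeter

The nuclear perimeter is the set of nuclear voxels 6-adjacent to
non-nuclear space (voxels at the volume border count as adjacent to
outside). Distances are exact Euclidean distances between voxel centers,
computed with an anisotropy-aware distance transform over the whole
volume. Measuring to perimeter *voxel centers* rather than a sub-voxel
surface is deliberate: surface fitting would add complexity below the
resolution of the data the method targets (0.25–0.5 µm sampling).
Consequences: the distance map is 0 exactly on the perimeter, 1-Lipschitz
with respect to physical distance, and equal to brute-force
nearest-perimeter search (verified on grids up to 25³).

Puncta inside a nucleus are assigned distance 0 and reported separately;
cytosolic distance CDFs exclude them. Whether intranuclear signals
entered published CDF analyses of this kind is generally ambiguous; the
exclusion is this package's committed convention, stated rather than
silently applied.

## Puncta detection

"Morphological object localization" is implemented as: difference of
Gaussians at the punctum scale (default σ = (0.35, 0.15, 0.15) µm, ratio
1.6), a global threshold at the within-cell median plus `k` robust
standard deviations (MAD × 1.4826, default k = 5), 26-connected
components of at least 2 voxels, intensity-weighted centroids from the
background-subtracted band-passed response, and rejection of centroids
outside the cell. All constants are exposed in `DetectionParams`.

The MAD is scaled to estimate a Gaussian σ so `k` reads as a z-score;
at k = 5 the false-positive rate on pure noise volumes is below 1 per
100 volumes (tested), while recall and precision on 200 well-separated
rendered puncta (500 photons each over a background of 5) exceed 95%
at a 1 µm matching gate.

Detection assumes resolvable spots. At extreme densities (mean spacing
at the PSF scale, e.g. tens of thousands of puncta in one cell) any
connected-component detector saturates: components merge and the
signal-dominated threshold loses meaning. Density comparisons in that
regime should be made on ground-truth occupancy (phantoms) or on
photometric summaries, not on detector output.

## Region partition

The cell is covered disjointly by nucleus and cytosol. Three overlays
support regional densities: a periphery shell (cell voxels within
1 µm of the cell surface by default), intercalated-disk end caps (the
outer 5% of the long-axis extent at each end), and, for multinucleated
cells, the internuclear space (cytosolic voxels whose long-axis
projection lies between nuclear centroid projections). The long axis is
the principal second-moment axis of the cell mask, which is stable for
elongated myocytes. Region assignment of a punctum follows the
precedence nucleus > ID > internuclear > periphery > cytosol, so each
punctum carries exactly one region label.

## Distance CDFs and statistics

Per-cell CDFs are right-continuous step functions evaluated on a uniform
grid (0.1 µm step by default); re-gridding uses linear interpolation.
Cross-cell summaries report pointwise mean ± SD and median ± MAD plus a
"global" CDF from pooling raw distances; on homogeneous simulated groups
(20 cells × 500 puncta) mean and global agree within 0.05 everywhere.
d50 uses the grid-crossing convention (smallest grid point with
F ≥ 0.5, no interpolation) for reproducibility.

Two-sample KS tests are applied to pooled per-punctum distances — a
committed reading, since comparing "mean CDFs" requires a sample and
pooling is the natural one. The Wilcoxon rank-sum test enumerates all
C(n+m, n) group assignments (midranks for ties) when n + m ≤ 12 and
otherwise uses the tie-corrected normal approximation; both match
independent enumeration oracles in the tests. Bonferroni adjustment
multiplies by the size of the comparison family, which must be at least
the number of results supplied. α = 0.05 throughout.

Concentration profiles report the percentage of cytosolic volume
occupied by signal per distance bin (2 µm default); bins with no
cytosolic voxels are flagged empty and excluded.

## Striation periodicity

The axial profile sums a channel over cross-sections perpendicular to
the long axis, binned at the in-plane voxel pitch. Spectra use linear
detrending, a Hann window and zero-padding to 4× the profile length
(frequency spacing ≤ 0.01 µm⁻¹ for a 100 µm cell); the search band is
0.3–0.8 µm⁻¹, bracketing sarcomeric spacing. Windowing and padding are
this package's choices — presence/absence of a peak is insensitive to
them, exact peak power is not, so results always carry these settings.

A period is reported when the in-band peak power is at least
`min_prominence` times the in-band median. The default is 12, not a
smaller conventional factor, because periodogram bins of an unstructured
profile are exponentially distributed: with the ~40–50 independent bins
a 100 µm cell yields in-band, the *expected* maximum is already ~5–8×
the median, so a 3× criterion would flag pure noise essentially always.
At 12 the in-band false-alarm probability is at the percent level, while
genuine striated phantoms at study-scale abundance score prominences in
the hundreds. Detection power grows with puncta abundance, so absence of
a peak in a low-abundance channel is weak evidence of absence.

## Trafficking model

Cytoplasmic mRNA transport is modeled on the nondimensional interval
[0, 1] (nuclear envelope to membrane) by
`∂u/∂t = D ∂²u/∂x² − a ∂u/∂x − d·u`, with total flux
`J = a·u − D·∂u/∂x`, constant nuclear export `J(0) = F` and an
impermeable membrane `J(1) = 0`. Advection `a ≥ 0` stands for
microtubule transport; the colchicine condition sets a = 0. Degradation
is uniform across species; time units are fixed by d = 1, so fitted D
and a are reported in units of the degradation rate (the data constrain
only their ratios to d). Treating the membrane condition as zero *total*
flux (rather than zero diffusive flux) yields the exact mass balance
F = d·∫u, which every returned solution satisfies to 1e-8 and which the
tests verify by quadrature.

The steady state is `u(x) = A e^{r₁(x−1)} + B e^{r₂x}` with
`r₁,₂ = (a ± √(a² + 4Dd)) / (2D)`; anchoring the growing mode at x = 1
keeps the representation overflow-free at extreme Péclet numbers, where
the solution is a thin accumulation layer at the membrane. Coefficients
come from the 2×2 flux-boundary system; degenerate systems raise.

The independent numerical oracle is a conservative finite-volume solve
with exponential-fitted (Scharfetter–Gummel) face fluxes,
`J = (D/h)[B(−P)uᵢ − B(P)uᵢ₊₁]`, `P = a·h/D`, `B(p) = p/(eᵖ − 1)` —
the standard discretization for advection–diffusion at arbitrary Péclet
number. It is second-order accurate (observed error ratio ≈ 4 under mesh
halving), agrees with the closed form to better than 1e-4 across
D ∈ [10⁻³, 10²], a ∈ [0, 10] when the mesh resolves the steepest mode
(r₁·h ≲ 1/60; n = 1001 suffices up to r₁ ≈ 20), and imposes the flux
boundary conditions without the catastrophic cancellation a one-sided
central-difference treatment suffers in the boundary layer.

Fitting minimizes Σ(countₖ − amp·pₖ(D, a))² over distance bins, where
pₖ is the model's bin mass. The amplitude is profiled out in closed form
at each (D, a) and reported as F, since the influx only sets overall
scale. D is optimized in log space with bounds [1e-4, 1e3], a in
[0, 100]; five seeded multi-starts over a log-spaced D grid guard
against local minima, ties broken by residual then by smaller a.
Measured µm distances are mapped to [0, 1] by a per-dataset length
scale (default: the outermost bin edge; the pipeline uses the 95th
percentile of cytosolic voxel distances). Noiseless forward data are
recovered to better than 1%; from 5000 sampled distances the advection
velocity is recovered with ~1% median error over 20 replicates (the
acceptance bound is 15%).

## Synthetic phantoms

The phantom emulates the study geometry: a rod 100 × 20 × 10 µm —
a cylinder with hemispherical caps, squashed to the stated depth —
with two ellipsoidal nuclei (semiaxes 2 × 2.5 × 6 µm) at 1/3 and 2/3 of
the long axis, sampled at 0.5 × 0.25 × 0.25 µm (z, y, x). Acquisition
voxel sizes and PSF are conventions of this generator, not reproductions
of a specific microscope: the Gaussian PSF default
σ = (0.35, 0.15, 0.15) µm approximates a high-NA confocal, with 500
photons per punctum, a uniform background of 5 photons/voxel, Poisson
photon noise and Gaussian read noise (σ = 2).

Placement models operationalize the observed localization patterns:
`uniform` over cytosolic voxels; `perinuclear` with voxel weights
∝ exp(−dist/decay) (default decay 2 µm); `gradient` weighting voxels by
the trafficking steady state evaluated at dist/length-scale; `striated`
as a mixture of Gaussian-profile transverse bands (default period
1.65 µm, band σ 0.3 µm, 60% of mass) over a uniform background, since
real striations sit on a diffuse signal. Each sampled voxel gets a
uniform within-voxel jitter, and rendering deposits photons trilinearly
so ground-truth centroids are preserved to sub-voxel accuracy. One
seeded generator per operation invocation makes every output
reproducible, and ground-truth tables are always written next to
rendered volumes so recall/precision is computable.

What the phantom does not emulate: real optics beyond a Gaussian PSF,
T-tubule/SR ultrastructure, cell-to-cell geometric variability, motion,
or spectral cross-talk. Passing tests on phantoms therefore validate the
measurement chain (geometry, detection, distances, statistics, spectra,
model fitting), not biological conclusions about real images.

## Problem sizes used in tests and scripts

Geometry-heavy unit tests run on a 40 × 12 × 8 µm phantom at 0.5 µm
isotropic sampling; full-scale checks (periodicity recovery, density
folds, d50 ordering) use the default 100 × 20 × 10 µm cell at confocal
sampling. The density-fold reproduction uses 25,000 total puncta thinned
at 8% retention, measured as cytosolic occupancy density of the placed
puncta voxels — at that abundance the mean spot spacing is at the PSF
scale, which is beyond the valid regime of any connected-component
detector (see *Puncta detection*), so the comparison is made on
ground-truth occupancy. Parameter-recovery studies use 5000 distances ×
20 replicates. The end-to-end pipeline demo runs 2 groups × 3 cells at
the small geometry.

## Known limitations

- Single-cell volumes only; multi-cell fields, touching-cell separation
  and tissue mosaics are out of scope.
- The global detection threshold assumes roughly uniform background
  within the cell.
- The 1D model collapses the true geometry onto a radial coordinate and
  assumes a single well-mixed export flux; it cannot represent
  anchoring, local degradation heterogeneity, or multi-modal transport.
- The length-scale mapping from measured µm distances to the unit
  domain is a convention (95th percentile of attainable distances in the
  pipeline) and is exposed in configuration.
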