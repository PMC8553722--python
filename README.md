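# myomol

Quantitative analysis of mRNA localization in cardiac myocytes: where do
transcripts for membrane proteins sit relative to the nuclei, and what
transport process put them there?

Adult ventricular myocytes are rods roughly 100 µm × 20 µm × 10 µm with
1–2 central nuclei and a periodic sarcomeric lattice. Single-molecule in
situ hybridization (e.g. RNAScope) renders each mRNA as a
diffraction-limited fluorescent punctum in a 3D confocal stack. `myomol`
provides the full measurement chain for such data, plus a synthetic
phantom generator so the whole pipeline is testable without microscope
data:

- **Morphological object localization** — nucleus/cell segmentation,
  difference-of-Gaussians puncta detection (threshold at the cell
  background median + k·MAD, 26-connected components, intensity-weighted
  centroids), and an anisotropy-aware exact Euclidean distance transform
  from every voxel to the nearest nuclear-perimeter voxel. Cells are
  partitioned into nucleus, cytosol, internuclear space, a peripheral
  shell and intercalated-disk end caps.
- **Spatial statistics** — per-cell empirical CDFs `F(r)` of puncta
  distance to the nuclear perimeter, cross-cell summaries (mean ± SD,
  median ± MAD, pooled "global" CDF), reference CDFs of all cytosolic
  voxels and the periphery shell, the d50 statistic
  (`d50 = min{r : F(r) ≥ 0.5}`), two-sample Kolmogorov–Smirnov and
  Wilcoxon rank-sum tests (exact enumeration for n+m ≤ 12) with
  Bonferroni correction, concentration-vs-distance profiles, and
  total-to-ribosome-associated density ratios.
- **Striation periodicity** — axial intensity profiles along the cell's
  principal axis and their Hann-windowed, zero-padded power spectra;
  sarcomeric banding appears as a peak near 0.5–0.6 µm⁻¹ (1.65–2 µm
  spacing).
- **Trafficking model** — the 1D advection–diffusion–degradation model
  on the nondimensional domain x ∈ [0, 1] (nuclear envelope to
  membrane):

  ```
  ∂u/∂t = D ∂²u/∂x² − a ∂u/∂x − d·u,   J(x) = a·u − D·∂u/∂x,
  J(0) = F (nuclear export flux),       J(1) = 0 (impermeable membrane)
  ```

  with closed-form steady states, an independent exponential-fitted
  finite-volume oracle, the induced distance CDF, inverse-CDF sampling,
  and nonlinear least-squares fitting of (D, a) to binned distance data.
  Setting a = 0 models microtubule inhibition (colchicine) and shifts
  all predicted distributions toward the nucleus.
- **Phantoms** — rod-shaped cells with ellipsoidal nuclei, puncta placed
  by uniform / perinuclear / model-gradient / striated rules, rendered
  with a Gaussian PSF, Poisson photon noise and Gaussian read noise;
  ground-truth tables ship with every rendered volume.

## Worked example

`examples/` contains one short script per capability. For instance:

```bash
$ python examples/01_phantom_and_distance_cdfs.py
cell: (20, 80, 400) voxels at (0.5, 0.25, 0.25) um
perinuclear (decay 2 um)     d50 =  2.50 um
uniform                      d50 =  8.40 um
gradient (D=1, a=3)          d50 = 12.20 um
all cytosolic voxels         d50 =  8.10 um  (uniform reference)
periphery shell              d50 =  9.70 um  (outer envelope)
```

Half of a perinuclear species lies within 2.5 µm of the nuclear surface;
a uniformly distributed species matches the all-voxel reference
(8.4 vs 8.1 µm), and an advection-driven gradient overshoots it — the
three signatures used to classify localization patterns.

```bash
$ python examples/02_trafficking_model_fit.py
truth:  D = 0.0200  a = 0.300
fitted: D = 0.0210  a = 0.296  (residual 2949.2, converged=True)
model d50: 0.248 (fitted) vs 0.102 (same D, a = 0) -- removing advection
pulls mass toward the nucleus

$ python examples/03_striation_periodicity.py
striated 1.65 um   period 1.65 um at 0.605 1/um (prominence 211)
uniform control    no prominent peak (prominence 7.9 < 12)
```

A thin CLI mirrors the stages (`myomol simulate | measure | stats |
periodicity | fitmodel | run | figures`); `myomol run --config demo.yaml
--out runs/demo` executes an end-to-end multi-group experiment and
writes per-cell puncta CSVs, a JSON report and summary figures.

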