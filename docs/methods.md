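# Methods

`nanouptake` models and measures nanoparticle uptake experiments in
adherent cell culture: how much of an administered particle dose reaches
the cells, and how per-cell uptake is quantified from multichannel
microscopy. This note records the models, the defaults and why they were
chosen, the numerical choices, and the known limits.

## Administered dose: mass to particle number

A particle preparation is polydisperse and core–shell: an inorganic core
(gold or iron oxide) of radius $r_c$ inside a polymer/solvation shell
out to the hydrodynamic radius $R$. Both radii are modelled as normal
distributions $N(\mu, \sigma)$. The mean particle volume follows from
the third raw moment of the radius distribution,

$$\langle r^3 \rangle = \mu^3 + 3\mu\sigma^2,$$

taken over the *untruncated* normal. For $\sigma/\mu > 0.5$ the
negative-radius tail is no longer negligible and the library logs a
warning; the Monte-Carlo oracles in the test suite deliberately sample
the untruncated normal too, so implementation and oracle agree on the
same convention. The mean particle mass is

$$\langle m \rangle = \rho_\text{core}\tfrac{4\pi}{3}\langle r_c^3\rangle
 + \rho_\text{shell}\tfrac{4\pi}{3}\left(\langle R^3\rangle - \langle r_c^3\rangle\right),$$

and the administered particle number is $n = C V / \langle m \rangle$
for mass concentration $C$ and medium volume $V$. Element-specific
assays (e.g. ICP-OES) see only the core, so the inverse conversion
`core_mass_to_number` divides by the mean *core* mass alone.

Defaults carried by the packaged example configuration: gold core
$d_c = 4.7 \pm 2$ nm, $d_h = 11 \pm 3$ nm, $\rho = 19.2$ g/cm³ at
38.6 µg/mL; iron oxide $d_c = 13.6 \pm 4$ nm, $d_h = 28 \pm 9$ nm,
$\rho = 5.24$ g/cm³ at 54.8 µg/mL. The shell density is not measurable
by the above assays and defaults to 1.00 g/cm³; it affects only
sedimentation and total-mass conversions, not diffusion-only deposition.

## Delivered dose: deposition in the medium column

Transport of suspended particles to the cell monolayer is modelled in
one dimension over the medium column height $h = V/A$:

$$\partial_t c = D\,\partial_x^2 c + v\,\partial_x c, \qquad x \in [0, h],$$

with $x = 0$ the cell layer, uniform initial concentration, a perfectly
absorbing bottom (particles adhere on arrival and are counted as
delivered) and a zero-flux top. $D$ is Stokes–Einstein at the mean
hydrodynamic diameter, $D = k_B T / (3\pi\eta d_h)$; the settling speed
$v$ is Stokes drag on the effective core–shell sphere and is off by
default because for both species it moves particles less than 1% of the
column height in 24 h. A quadrature mode (`n_size_bins`) averages
deposition over the hydrodynamic-size distribution; the default is the
single-class mean diameter, which differs from the binned result by
under five percentage points for the example species.

Medium defaults: $T = 310$ K, $\eta = 6.9\times10^{-4}$ Pa·s, density
1.00 g/cm³ (water-like at 37 °C), $A = 1.7$ cm², $V = 0.4$ mL, hence
$h = 2.35$ mm — a typical chamber-slide working volume. The column
height is the dominant uncertainty of the model: deposition scales
roughly as $1/h$ at short times, and experimental protocols rarely
report the exact per-well volume. Every deposition output therefore
records the height it was computed with, and all geometry is
overridable in configuration.

### Numerics

The PDE is discretised as a flux-form finite-volume scheme (400 cells
by default) with Crank–Nicolson time stepping and first-order upwinding
of the advective term. The delivered fraction is the trapezoidal time
integral of the wall flux; because the scheme is in flux form, this
equals the loss of suspended mass to machine precision, so
"deposited + suspended = 1" holds by construction and the real accuracy
checks are against independent closed forms. The time step starts at
the diffusion-stability-like cap $\Delta t \le 0.5\,\Delta x^2/D$ —
which Crank–Nicolson does not need for stability but which resolves the
steep early boundary layer — and then grows proportionally to elapsed
time ($\Delta t \le 0.02\,t$); the advective cap
$\Delta t \le 0.5\,\Delta x/v$ stays hard so the upwind front remains
sharp. Against the eigenfunction-series solution of the absorbing slab
the solver is accurate to a relative error of about $6\times10^{-4}$
over 1 min–24 h, and it matches the half-space law
$2\sqrt{Dt/\pi}/h$ and the plug-settling limit $\min(vt/h, 1)$ within
their 5% test bands. One 24 h curve takes well under a second.

## Per-cell image quantification

Input is a calibrated (z, channel, y, x) stack with a bright-field
channel and 1–3 fluorescence channels.

* **Cell masks** come from bright-field texture: local variance in a
  9×9 window (radius 4 px at 0.2 µm/px), median smoothing with a
  6 px disk, IsoData threshold of the variance map, hole filling, and
  removal of objects below 50 µm². Masks are per z-slice, linked across
  slices by footprint overlap. All radii are configuration-exposed; the
  defaults were calibrated on the synthetic scenes only.
* **IsoData threshold** is the iterative intermeans rule
  $T \leftarrow (\text{mean below } T + \text{mean above } T)/2$
  started from the global mean, stopped at a change below 0.5 intensity
  units. It is affine-equivariant, which the property tests exercise.
* **Uptake load** is the count of in-mask voxels (pooled across z)
  above the IsoData threshold of that cell's own in-mask intensity
  pool. Thresholding per cell after masking makes the load robust to
  between-cell background differences, at the price of a mild
  dependence of the threshold on the cell's own signal content; the
  synthetic benchmarks show the measure is linear in true spot count in
  the sparse-puncta regime and saturates when spot cores cover a
  substantial fraction of the cell volume.
* **MFI** is the arithmetic mean of in-mask intensities (no background
  subtraction — none is applied by default anywhere; a flat-field hook
  exists but is off). The uptake rate Δ is the ordinary least-squares
  slope of MFI against time.
* **Pearson colocalization** is computed over in-mask pixels only.
  A constant channel raises a distinct error rather than returning 0,
  because "undefined" and "uncorrelated" are different findings. The
  default aggregation is per-cell-then-average; a pooled mode exists.
* **Vicinity rim**: the extracellular band holding 20% of the cell's
  footprint area (so cell + rim = 120% of the cell), built by taking
  extracellular pixels in order of distance to the cell; ties resolve
  by the distance-transform rank, landing the area within ±2%. The
  background reference is a 1-µm-wide annulus whose inner edge is 15 µm
  from the cell boundary, clipped to extracellular space and keeping
  3 µm clearance from any other cell so a neighbour's membrane-adjacent
  signal cannot leak into the reference. Enrichment is the vicinity
  mean divided by the background mean. Cells touching the image border
  keep load/MFI but are excluded from rim scoring.

## Synthetic scenes and what "ground truth" means

The generator emulates the study system — an adherent macrophage
monolayer in a ~102 µm field at 0.2 µm/px, 3 z-slices — with textured
elliptical cells (radius 6–9 µm) on a smooth bright-field background
(level 1000, texture amplitude 200), and fluorescence channels with
background 20, Poisson shot noise and Gaussian read noise (σ = 3).
Uptake is linear: spot counts per cell and channel are
Poisson(rate · t) at a default 8 spots/cell/hour, rendered as 2-px-σ
Gaussian kernels with lognormal amplitudes (median 150, σ_ln = 0.25)
placed uniformly through the z-stack. The default rate keeps the
voxel-load instrument in its linear regime (spot cores sparse relative
to the cell volume), matching the linear uptake trends the quantification
is meant to read out; at several-fold higher densities the load
saturates by spot overlap and threshold interaction, which the methods
above cannot distinguish from genuine sub-linearity.

A controllable fraction ρ of spots is shared between the two NP
channels; shared spots share coordinates *and* brightness, since both
labels scale with the particle content of a common endosome. A fraction
of spots can be directed into organelle-marker blobs for
marker-colocalization scenarios. The inhibitor scenario suppresses
intracellular signal and fills the ground-truth vicinity rim with
aggregates at a programmed fold over background.

The voxel load is an instrument-defined quantity — "voxels above an
IsoData threshold" — with no instrument-free truth. The ground truth
therefore records two things: the physical truth (spot counts,
coordinates, amplitudes), used for monotonicity and dose-scaling
checks, and a measurement-model truth load — the voxels above the
IsoData threshold of the *noiseless* stack inside the *true* mask —
used for recovery-accuracy checks. Recovery tests of rim enrichment use
rims built from ground-truth outlines: the vicinity band is only ~1 µm
wide for these cell sizes, so a 1–2 px segmentation error would
dominate the score, and segmentation accuracy is checked separately
(IoU ≥ 0.8, typically 0.89–0.95).

What passing on synthetic data does *not* show: robustness to uneven
illumination, focus drift, spectral bleed-through, cell motion,
confluent monolayers with touching cells, or out-of-focus haze — none
of which the generator produces. Results on real micrographs depend on
re-tuning the segmentation radii and validating masks by eye.

## Statistics

Group summaries are mean, sample SD (n−1) and t-quantile 95% CIs.
Comparisons use the classical equal-variance two-sample Student's
t-test, two-sided at α = 0.05 (Welch via flag); identical groups with
zero pooled variance report p = 1 by convention. Exposure comparisons
report the percent difference in mean load, co- vs single-exposure, per
channel and timepoint, with raw p values and no multiple-testing
correction. Cells are the default replication unit; with single stacks
per condition at desk scale, stack-level means would leave n = 1.
Monte-Carlo calibration (10⁴ null simulations, n = 10 per group) puts
the empirical type-I error within 0.04–0.06.

## Problem sizes

The test suite and the reproduction script run at sizes a laptop
handles in minutes: deposition on a 400-node grid; moment checks with
10⁶ Monte-Carlo draws per grid point; 20 synthetic scenes of 6 cells
per exposure condition (≈120 cells per arm) for the end-to-end
recovery and co-exposure comparison; 10 seeds × 5 colocalization levels
for the ρ-recovery check; 10⁴ simulations for t-test calibration.

## Known limitations

* The deposition model is 1-D: no well-wall effects, convection,
  agglomeration kinetics or protein-corona evolution; "delivered" means
  arrived at the bottom plane with no detachment. Absolute 24 h
  fractions inherit the column-height uncertainty discussed above.
* Masks are 2-D per slice; there is no 3-D surface segmentation, no
  deconvolution, and no tracking of individual particles.
* The untruncated-normal moment formula overstates the mean volume of
  strongly polydisperse preparations (σ/μ > 0.5).
* The equal-variance t-test is used as named; for strongly unequal
  group variances prefer the Welch flag.
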