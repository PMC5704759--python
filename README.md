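# nanouptake

Dosimetry and per-cell image quantification for in vitro nanoparticle
co-exposure experiments.

When two nanoparticle species — say polymer-shelled gold
(d_h = 11 nm) and iron oxide (d_h = 28 nm) — are added to adherent
cells, three questions decide how the experiment is read: how many
particles were administered, what fraction actually reached the cells,
and how much each cell took up. `nanouptake` answers all three:

* **dosimetry** — converts mass concentrations of polydisperse
  core–shell particles to particle numbers using the normal-moment
  identity ⟨r³⟩ = μ³ + 3μσ², and computes the *delivered* dose — the
  fraction of suspended particles that has reached the cell monolayer —
  from a 1-D diffusion(–sedimentation) model of the medium column with
  an absorbing bottom, D from Stokes–Einstein.
* **imaging** — label-free cell masks from bright-field texture
  (variance → median → IsoData), then per-cell voxel "uptake load"
  (voxels above an intermeans IsoData threshold), mean fluorescence
  intensity (MFI) and its slope Δ over time, Pearson colocalization
  between channels over masked pixels, and vicinity-rim enrichment
  (mean fluorescence in an extracellular band of 20% of the cell's
  area, relative to a background annulus 15 µm away) for
  endocytosis-inhibition experiments.
* **synthdata** — a synthetic-microscopy generator with complete ground
  truth (masks, spot placements, true colocalization fraction,
  programmed rim folds), so the whole measurement chain is testable
  without any raw images.
* **stats_report** — mean ± SD, t-based 95% CIs, Student's t-test at
  α = 0.05, and single- vs co-exposure comparisons as percent
  differences in mean load.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example: deposited dose

```python
import numpy as np
from nanouptake.dosimetry import (
    ExposureSetup, ParticleSpecies, SizeDistribution, deposited_fraction,
)

aunp = ParticleSpecies(
    name="AuNP", core_density=19.2, shell_density=1.0,
    core_radius=SizeDistribution.from_diameter(4.7, 2.0),
    hydrodynamic_radius=SizeDistribution.from_diameter(11.0, 3.0),
    mass_concentration=38.6,
)
chamber = ExposureSetup()  # 1.7 cm2, 0.4 mL -> 2.35 mm column, 310 K
curve = deposited_fraction(aunp, chamber, [300, 3600, 86400])
print(np.round(100 * curve.deposited_fraction, 2))
```

prints

```
[ 6.42 22.26 91.91]
```

— 6.4% of the administered gold dose has reached the cell layer after
5 minutes, 22.3% after 1 hour and 91.9% after 24 hours of pure
diffusion in a 2.35 mm medium column. The same run for the iron oxide
species (d_h = 28 nm) gives 13.95% at 1 h and 67.21% at 24 h: the
smaller, faster-diffusing gold particles reach the cells first, so
equal administered masses are *not* equal delivered doses. The 24 h
magnitudes scale with the per-well medium volume, which is the model's
dominant uncertainty (see `docs/methods.md`).

The same curves from the command line, with the packaged example
configuration:

```sh
nanouptake dose --out curves.csv            # time_s, species, deposited_fraction, ...
```

## Worked example: synthetic co-exposure, end to end

```sh
nanouptake end2end --out-dir results/ --seed 7
```

simulates a single-exposure scene (8 spots/cell/h) and a co-exposure
scene at 1.66× that uptake rate, segments the cells from bright-field,
measures per-cell voxel loads, and compares the conditions:

```
channel  time  n_single  n_co  mean_single    mean_co  percent_difference  t_statistic  p_value  significant
    NP1 120.0         6     6   420.000000 675.833333           60.912698     3.633483 0.004586         True
    NP2 120.0         6     6   455.166667 708.166667           55.584035     4.713513 0.000825         True
```

The measured +56–61% recovers the programmed +66% rate difference up to
Poisson sampling noise at 6 cells per condition (the acceptance test
uses 20 scenes per arm and lands at +61% pooled). `simulate`,
`quantify` and `report` run the individual stages; every command writes
a resolved-config copy with its seed next to its outputs.

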