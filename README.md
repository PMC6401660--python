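# synquant

Quantification of B cell immune-synapse imaging experiments: geometric and
fluorometric indices for 3-D cell–bead conjugate stacks and 2-D
synaptic-plane time-lapses, validated end to end against a synthetic
phantom generator with known ground truth.

## The problem

When a B cell recognizes antigen immobilized on a surface — experimentally,
a 3 μm antigen-coated bead or an antigen-coated coverslip — it forms an
immune synapse: it spreads, reorganizes its actin cytoskeleton, repositions
its centrosome (MTOC) toward the contact site, delivers lysosomes there and
extracts antigen for presentation. Quantifying this polarization response
from multi-channel fluorescence microscopy is done with a small set of
per-cell indices, which this package implements as a tested, scriptable
library:

* **Centrosome polarity index.** With cell mass center CMC, bead mass
  center BMC and centrosome position Cent, the centrosome is projected onto
  the CMC→BMC axis and the index is the signed ratio
  `⟨Cent − CMC, BMC − CMC⟩ / |BMC − CMC|²`: +1 fully polarized (centrosome
  at the bead center), 0 at the cell center, −1 anti-polarized.
* **Centrosome–nucleus distance** (μm): Euclidean distance between Cent and
  the nucleus mass center MCN; centrosome detachment from the nucleus
  accompanies polarization.
* **Fluorescence density index** `DCent/DCell`: fluorescence density (sum
  over area) in a 1 μm radius region centered on the centrosome divided by
  the density over the whole cell; values above 1 mean accumulation at the
  centrosome (e.g. centrosomal F-actin), below 1 depletion.
* **Recruitment %**: fluorescence inside a fixed region around the bead as
  a percentage of whole-cell fluorescence (lysosome/LAMP-1 or proteasome
  delivery to the synapse).
* **Antigen extraction %**: fluorescence lost by antigen-coated beads
  relative to a reference bead population, measured on z-sum projections
  over the fixed bead region.
* **Synaptic-plane partition**: the 2-D footprint (CellTemp) is split into
  a concentric center ellipse of one third of its area (CenterTemp) and the
  periphery (PeripheryTemp); the periphery index
  `(F_per/A_per)/(F_cell/A_cell) − 1` is positive for peripheral enrichment
  (actin ring), and the central fraction `F_center/F_cell` scores signal
  confinement (pSyk) at the synapse center.
* **Spreading kinetics**: per-frame footprint areas (μm²), spreading
  velocity (least-squares slope over the rise window, μm²/min) and
  kymographs (distance × time maps) from time-lapse movies.

Because public ground-truth data for such assays do not exist, the package
ships a first-class phantom generator (`synquant.phantoms`): spherical
cell/nucleus/bead scenes with per-channel intensity models and a
Poisson–Gaussian camera, plus spreading movies with a saturating-exponential
area curve — every index is validated by recovering the generator's known
parameters from rendered images.

## Worked example

`examples/conjugate_indices.py` renders one noisy conjugate phantom
(SNR 10), segments it and measures every index:

```
polarity index        +0.445   (truth +0.450)
centrosome-nucleus    3.88 um (truth 3.91 um)
actin density index   0.980   (>1 = centrosomal accumulation)
LAMP-1 recruitment    20.5 %  (lysosome delivery to the bead)
```

The measured polarity and centrosome–nucleus distance recover the
generator's truth to within the suite tolerances (±0.1 and one voxel
diagonal); an actin density index near 1 means no centrosomal actin
accumulation in this phantom. The other scripts in `examples/` cover
antigen extraction, spreading kinetics/kymographs, and a simulated
control-vs-proteasome-inhibitor comparison in which the inhibited condition
shows higher centrosomal actin density and lower polarity, recruitment,
extraction and spreading velocity.

A thin CLI wraps the same library paths:

```
synquant simulate conjugate --seed 1 --out scenes/ -n 10
synquant conjugate --config run.json --out results/
synquant recover --seed 1 -n 20        # parameter-recovery pass/fail table
```

## Layout

* `src/synquant/phantoms.py` — ground-truth scene models and renderers
* `src/synquant/stack.py` — calibrated stacks, ImageJ-style TIFF I/O
* `src/synquant/segmentation.py` — masks, landmarks, bead regions
* `src/synquant/conjugate.py` — conjugate indices
* `src/synquant/synapse_plane.py` — partition, enrichment, kinetics
* `src/synquant/pipeline.py` — batch runs, manifests, recovery suite
* `src/synquant/cli.py` — command-line wrapper
* `docs/methods.md` — models, conventions, parameter choices, limitations
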