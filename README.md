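# bsdti — b-matrix spatial distribution correction for diffusion tensor MRI

Gradient-coil nonlinearity makes the diffusion weighting of an MRI scanner
vary across the imaging volume: the b-matrix that describes each
diffusion-weighted acquisition is not one constant `b` but a spatial field
`b(r) = L(r) b Lᵀ(r)`, where `L(r)` is the scanner's field-correction
("coil") tensor.  Ignoring this — the standard (STD) processing — leaves a
systematic, spatially structured error in every diffusion tensor and every
FA/MD/AD/RD map.  This package implements the phantom-calibrated correction
(BSD, for *b-matrix spatial distribution*): an isotropic phantom of known
diffusivity `D₀` is scanned with the clinical protocol, and each
acquisition's effective b-value per voxel is read off the signal equation

```
ln( A₀(r) / Aᵢ(r) ) = D₀ · tr bᵢ(r)        ⇒    sᵢ(r) = tr bᵢ(r) / tr bᵢ
```

With an isotropic reference only the trace of `bᵢ(r)` is identifiable, so
the correction rescales the nominal matrix per voxel, `bᵢ(r) = sᵢ(r)·bᵢ`,
with `sᵢ(r)` modelled as a low-order polynomial in scanner (world)
coordinates.  Tensors are then fitted per voxel by (weighted) linear least
squares on `ln(Aᵢ/A₀) = −⟨bᵢ(r), D⟩` over the protocol's system of 40, 20,
11 or 6 equations, in both STD and BSD modes, and ROI-level nonparametric
statistics (Mann–Whitney U, Wilcoxon signed-rank, Benjamini–Hochberg FDR,
rank effect size r = |Z|/√N) quantify how well two cohorts — healthy
controls versus an MS-like patient group — are separated by each protocol
subset and processing approach.

The package is aimed at diffusion-MRI methods researchers: every input the
study design assumes (distorted phantom twin scans, a two-group cohort with
a 95-parcel label map, the true `L(r)` field) can be generated synthetically,
so the whole pipeline is testable end to end without any scanner data.

## Worked example

```python
import numpy as np
from bsdti import (Geometry, PhantomSpec, PROTOCOL_NAMES, make_field,
                   make_protocol, simulate_phantom_pair, estimate_b_field,
                   phantom_qc_report)

geometry = Geometry.centered((32, 32, 32), 2.5)          # 80 mm FOV, 2.5 mm voxels
field    = make_field(geometry, amplitude=0.05, seed=7)  # 5 % gradient deviation
scheme   = make_protocol("1000/2000(40)")                # b = 0/1000/2000, 20 dirs
spec     = PhantomSpec(seed=3)                           # D0 = 2.07e-3 mm^2/s
acq1, acq2 = simulate_phantom_pair(spec, field, scheme)  # twin scans, indep. noise

bfield = estimate_b_field(acq1, spec.d0, smooth_degree=2)
qc = phantom_qc_report(acq2, bfield, spec.d0, PROTOCOL_NAMES)
print(qc[["scheme", "approach", "fa_mean", "md_cv_pct"]].to_string(index=False))
```

```
       scheme approach  fa_mean  md_cv_pct
1000/2000(40)      STD 0.012909   0.980716
1000/2000(40)      BSD 0.008546   0.238517
     2000(20)      STD 0.035233   1.263513
     2000(20)      BSD 0.033970   0.852996
     1000(20)      STD 0.013099   0.983199
     1000(20)      BSD 0.008807   0.246260
     1000(11)      STD 0.016198   1.004393
     1000(11)      BSD 0.012884   0.318296
      1000(6)      STD 0.019388   1.044384
      1000(6)      BSD 0.016682   0.424110
```

An isotropic phantom should have FA = 0 and spatially constant MD, so the
mean FA and the coefficient of variation of MD measure the residual error.
On the *independent* twin acquisition the calibrated per-voxel b-matrices
(BSD) cut the phantom's spurious FA and the MD spread for every protocol
subset — e.g. for 1000(20) the MD CV% falls from 0.98 to 0.25 and mean FA
from 0.0131 to 0.0088.  The estimated scale field itself recovers the true
`tr(LbLᵀ)/tr(b)` to better than ±0.01 everywhere in the phantom.

The full study replica — phantom calibration plus a simulated two-group
cohort fitted under 5 protocol subsets × 2 approaches, with coarse-region
group tables and the 95-parcel discrimination report — runs from one config:

```
bsdti run-study --out out --seed 1
```

Individual stages are exposed both as library functions and as subcommands
(`simulate-phantom`, `simulate-cohort`, `calibrate`, `fit`, `roi-summarize`,
`compare-groups`).

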