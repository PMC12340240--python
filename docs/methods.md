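# Methods

## Signal model and the spatial b-matrix distribution

The monoexponential diffusion signal model at the spin-echo center is

    ln( A(2τ) / A(0) ) = − b : D,

with `b` the symmetric 3×3 b-matrix (trace = b-value, s/mm²) and `D` the
symmetric diffusion tensor (mm²/s).  When the gradient field is nonuniform
the weighting acquires a spatial dependence

    b(r) = L(r) · b · Lᵀ(r),

where the dimensionless field-correction tensor `L(r)` maps nominal to
effective gradients; `L ≡ I` recovers the conventional constant-b model.
Gradient waveform/timing detail (δ, Δ, cross-terms) is out of scope:
b-matrices enter as data, either built as `b·ggᵀ` from b-values and unit
directions or read from a per-DWI b-matrix table.

## Phantom calibration (the correction itself)

An isotropic phantom with known diffusivity `D₀` turns each weighted
acquisition `i` into one equation per voxel,

    ln( Ā₀(r) / Aᵢ(r) ) = D₀ · tr bᵢ(r),

with `Ā₀` the arithmetic mean of the b = 0 volumes.  One equation cannot
determine six b-matrix components, so the estimator is the *scalar* scale

    sᵢ(r) = tr bᵢ(r) / tr bᵢ,     b̂ᵢ(r) = sᵢ(r) · bᵢ,

which preserves the nominal eigenstructure.  Properties worth knowing:

* For isotropic objects (the phantom itself) the rescaled matrix is exact
  for *any* `L`, because only `tr b(r)` enters the signal.  Hence
  self-calibration reproduces `MD = D₀`, `FA = 0` to machine precision on
  noise-free data.
* For anisotropic objects the correction is exact whenever `L(r) = c(r)·I`
  (isotropic field).  For anisotropic `L` the direction-dependent part of
  `L b Lᵀ` is not representable by a scalar rescale; the residual bias is
  bounded by that direction-dependent part and the correction removes the
  (dominant) trace error.  A full-matrix estimate would need an anisotropic
  reference object, which this package does not model.

Raw per-voxel scales are noisy (`Var ≈ (σ/Aᵢ)² / (D₀ tr bᵢ)²`), while the
physical field is smooth, so by default each `sᵢ(r)` is replaced by a
polynomial of total degree 2 in *world* coordinates, fitted over the phantom
mask.  The fit is initialized by weighted least squares on the log-signals
(weights `Aᵢ²`) and refined by 3 Gauss–Newton iterations on the
signal-domain residual `Aᵢ − Ā₀ e^{−sᵢ D₀ tr bᵢ}`; the refinement removes
the log-transform's upward bias (≈ σ²/2A² per log), which is material for
the strongly attenuated b = 2000 s/mm² shell.  `smooth_degree = -1` keeps
raw voxelwise scales.  Voxels below the signal floor (default 3× the
background noise estimate) are excluded.  Because the polynomial lives in
laboratory coordinates, the same calibration evaluates on any other grid
positioned in the scanner frame (`apply_field`); evaluation outside the
calibrated bounding box plus a 10 % margin requires an explicit
extrapolation override.

## Tensor fitting

Per voxel the system `ln(Aᵢ/Ā₀) = −⟨bᵢ(r), D⟩` over the protocol's weighted
acquisitions (40, 20, 11 or 6 equations) is solved for the six unique tensor
components; off-diagonal b-matrix entries carry a factor 2 in the design
row.  "Chi-square minimization" is implemented as weighted linear least
squares with weights `Aᵢ²` — the first-order (Gauss–Newton) linearization of
the signal-domain chi-square — with plain OLS available.  STD mode uses the
nominal design everywhere; BSD mode scales each voxel's design rows by
`sᵢ(r)`.  The multi-shell protocol is fitted with a single monoexponential
tensor (no kurtosis term), matching the metrics under study.

Eigenvalues are sorted descending; FA = √(3/2)·‖λ−MD‖/‖λ‖ (0 when all
eigenvalues vanish, clipped to [0, 1]); AD = λ₁, RD = (λ₂+λ₃)/2,
MD = mean λ.  Negative eigenvalues are reported, not clamped — clamping
biases MD on noisy phantoms — and their frequency is logged.  Voxels with
nonpositive signals are masked out and counted.  Rank-deficient designs
(coplanar directions) are rejected.

## Protocols

The primary protocol 1000/2000(40) holds one b = 0 image plus 20 directions
at b = 1000 and the same 20 at b = 2000 s/mm²; subsets 2000(20), 1000(20),
1000(11) and 1000(6) restrict it.  No published direction table exists for
the scanner, so the default 20-direction set is generated by antipodally
symmetric electrostatic-repulsion optimization with a fixed seed; user
bvec files are accepted.  The 11- and 6-direction sub-selections are not
specified either; they are chosen by deterministic backward elimination
minimizing the tensor design-matrix condition number, which keeps the
reduced fits well-posed, makes the 6-set a subset of the 11-set, and records
the chosen indices in the scheme metadata.  The b = 0 count is configurable
(default 1).

## ROI analysis

Label maps live on a finer anatomical grid (1.2 mm, T1-like) and are
resampled to diffusion resolution by nearest-neighbor assignment computed in
world millimetres via the affines — not in index space, which is wrong for
anisotropic voxels.  Near-exact distance ties break toward the lowest source
index.  Per-ROI means of FA/MD/AD/RD are computed over the validity mask,
plus whole-brain / white-matter / gray-matter aggregates from a label→class
grouping; the phantom analysis reuses the same resampled masks.

## Group statistics and the discrimination criterion

Between-group contrasts use the Mann–Whitney U test (two-sided, tie-corrected
normal approximation with continuity correction); within-subject STD-vs-BSD
contrasts use the Wilcoxon signed-rank test (zero differences dropped).  The
rank effect size is r = |Z|/√N with the conventional 0.3 (medium) and 0.5
(large) thresholds — the estimator is a declared choice, as is the Yates
continuity correction in the 2×2 chi-square (it reproduces the null
demographic sex comparison exactly).  Shapiro–Wilk normality is computed and
logged but the pipeline always proceeds nonparametrically.  Benjamini–
Hochberg FDR adjustment (via statsmodels) is applied across all (ROI,
metric) rows of a comparison table and emitted alongside raw p-values; the
discrimination criterion itself uses the *raw* p < 0.005 together with the
effect-size threshold, an interpretation recorded here deliberately: the
criterion is defined on per-ROI significance, with FDR reported as a
companion column.  The criterion report gives, per protocol and approach,
the percentage of parcels where at least one metric (ANY) and each metric
separately qualifies, at both thresholds.

## Synthetic data: what it emulates and what it does not

* **Field**: `L(r) = I + P(r)` with every entry of `P` a random polynomial
  (default degree 2) in normalized world coordinates, zero at isocenter,
  scaled so the maximum spectral norm equals the amplitude (default 0.05,
  i.e. ≤ 5 % gradient deviation, a realistic whole-body-scanner magnitude).
  Real coil fields are smooth but not polynomial; degree-2 captures their
  leading behaviour over a head-sized FOV.
* **Phantom**: sphere of uniform `D₀ = 2.07×10⁻³ mm²/s` (the corrected
  phantom MD of the study this emulates), default radius 35 mm on a 32³
  grid of 2.5 mm voxels, `S₀ = 1000`.  Noise is Gaussian on the magnitude
  (the study's stated model; Rician available), with σ = 2.5 chosen so the
  b = 1000 shell has single-voxel SNR ≈ 50 — the level that reproduces the
  ~2 % per-voxel MD spread seen in single-phantom clinical QC.  Twin
  acquisitions share everything but the noise seed.
* **Cohort**: an ellipsoidal "brain" partitioned into 95 deterministic
  Voronoi parcels on the fine grid, relabeled by centroid for
  reproducibility.  Each parcel gets a base (FA, MD) pair (FA ~ U(0.15,
  0.55), MD ~ U(0.65, 0.95)×10⁻³), a random principal axis, and a WM/GM
  class by FA median split.  Patients have MD raised 5.5 % and FA lowered
  3.7 % in a configurable 40 % subset of parcels — the direction and rough
  magnitude of the published whole-brain group differences — with 4 %
  between-subject CV.  Per-voxel tensors are axially symmetric with exact
  FA/MD (eigenvalues `md(1+2f), md(1−f), md(1−f)`, `f = fa/√(3−2fa²)`).
  No anatomy, lesions, partial volume, EPI distortion or motion are
  modelled, so passing tests demonstrate correctness of the estimator and
  statistics pipeline under the stated noise/distortion model — not
  robustness to real-brain confounds.

All generators are bit-deterministic given their seeds; per-subject noise
seeds derive from the cohort seed via `numpy` seed sequences.

## Problem sizes and numerical choices

Default desk-scale sizes: phantom 32³ voxels (≈11.5 k mask voxels) — enough
that the degree-2 scale fit recovers the true field to ±0.01 at the default
SNR; cohort grids 18–20³ with ≈2 k brain voxels (≈20 voxels per parcel);
the demo study runs 10 subjects per group.  Statistical calibration checks
use 20 per group × 6 null cohorts (> 2000 ROI-metric comparisons).  The
polynomial basis is evaluated on coordinates normalized to the mask bounding
box to keep the least-squares systems well-conditioned; b = 0 entries always
carry scale 1; estimated scales are clamped to a small positive floor if a
fit strays nonpositive (logged).  Stacked 6×6 normal-equation solves use
LAPACK via numpy; eigendecomposition uses `eigh` with descending reorder.

## Known limitations

* The scalar-rescale calibration cannot capture direction mixing from an
  anisotropic `L`; its residual is documented above and exercised in tests.
* The Mann–Whitney/Wilcoxon p-values are normal approximations; at very
  small n (≤10) they deviate from exact enumeration by a few percent.
* The twin-phantom improvement is guaranteed only when the distortion field
  amplitude dominates the calibration noise, matching its study role.
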