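"""Synthetic study inputs: distorted phantom acquisitions and a two-group cohort.

The generator reproduces the structure of a gradient-nonlinearity study on a
single scanner: a known, smooth field-correction tensor L(r) maps every
nominal b-matrix to its effective per-voxel value ``b(r) = L(r) b L(r)^T``;
an isotropic sphere phantom scanned twice with independent noise provides the
calibration and validation acquisitions; and a two-group cohort (healthy
controls vs an MS-like patient group) with a many-parcel label map provides
the material for the ROI discrimination statistics.  Everything is
deterministic given the seeds in the specs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import _poly
from .containers import DwiDataset, Geometry, save_volume
from .gradient_scheme import GradientScheme, write_bvals_bvecs, write_bmatrix_table

logger = logging.getLogger(__name__)

__all__ = [
    "FieldCorrectionTensor",
    "PhantomSpec",
    "CohortSpec",
    "CohortSubject",
    "Cohort",
    "make_field",
    "simulate_dwi",
    "simulate_phantom_pair",
    "simulate_cohort",
    "axisymmetric_tensor",
    "write_dataset",
    "write_field_nifti",
]

#: default isotropic diffusivity of the calibration phantom, mm^2/s
DEFAULT_PHANTOM_D0 = 2.07e-3


# --- field-correction tensor -----------------------------------------------

@dataclass
class FieldCorrectionTensor:
    """Smooth spatial field L(r) = I + P(r) with polynomial perturbation P.

    The polynomial lives in normalized world coordinates ((x - center) /
    halfwidth), so the same physical field can be evaluated on any grid that
    overlaps the calibrated region -- the phantom and the head share the
    scanner's laboratory frame.
    """

    geometry: Geometry
    coeffs: np.ndarray          # (n_monomials, 9) row-major entries of P
    exponents: np.ndarray       # (n_monomials, 3), no constant term
    center: np.ndarray          # (3,) world mm
    halfwidth: np.ndarray       # (3,) world mm
    amplitude: float = 0.0

    def values_on(self, geometry: Geometry) -> np.ndarray:
        """Evaluate L on a grid; shape ``(*geometry.shape, 3, 3)``."""
        pts = geometry.voxel_centers()
        B = _poly.basis(pts, self.exponents, self.center, self.halfwidth)
        P = (B @ self.coeffs).reshape(geometry.shape + (3, 3))
        return np.eye(3) + P

    @property
    def values(self) -> np.ndarray:
        return self.values_on(self.geometry)

    def true_scales(self, geometry: Geometry, bmats: np.ndarray) -> np.ndarray:
        """Exact per-voxel b-value scale tr(L b L^T)/tr(b) for weighted b-matrices."""
        L = self.values_on(geometry)
        tr_nom = np.trace(bmats, axis1=-2, axis2=-1)
        Lb = np.einsum("...ij,njk->...nik", L, bmats)
        beff = np.einsum("...nik,...lk->...nil", Lb, L)
        return np.trace(beff, axis1=-2, axis2=-1) / tr_nom


def make_field(geometry: Geometry, amplitude: float, degree: int = 2,
               seed: int = 0) -> FieldCorrectionTensor:
    """Random smooth field-correction tensor with bounded perturbation.

    ``L(r) = I + P(r)`` where every entry of P is a polynomial of total degree
    <= ``degree`` in normalized world coordinates, zero at the grid center,
    scaled so the maximum spectral norm of P over the grid equals
    ``amplitude`` (the maximum relative gradient deviation).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    lo, hi = geometry.world_bounds()
    center = (lo + hi) / 2.0
    halfwidth = np.maximum((hi - lo) / 2.0, 1e-9)
    exps = _poly.monomial_exponents(degree, include_constant=False)
    rng = np.random.default_rng(seed)
    coeffs = rng.standard_normal((len(exps), 9))
    if amplitude == 0:
        coeffs[:] = 0.0
    else:
        pts = geometry.voxel_centers()
        B = _poly.basis(pts, exps, center, halfwidth)
        P = (B @ coeffs).reshape(-1, 3, 3)
        norms = np.linalg.svd(P, compute_uv=False)[:, 0]
        coeffs *= amplitude / norms.max()
    return FieldCorrectionTensor(
        geometry=geometry, coeffs=coeffs, exponents=exps,
        center=center, halfwidth=halfwidth, amplitude=float(amplitude),
    )


# --- signal simulation ------------------------------------------------------

def simulate_dwi(true_tensor_field: np.ndarray, field: FieldCorrectionTensor,
                 scheme: GradientScheme, S0: float = 1000.0,
                 noise_sigma: float = 0.0, noise_model: str = "gaussian",
                 seed=0, mask: Optional[np.ndarray] = None) -> DwiDataset:
    """Simulate a diffusion-weighted acquisition under the distorted weighting.

    Per voxel r and acquisition i the noise-free magnitude is
    ``S0 * exp(-<L(r) b_i L(r)^T, D(r)>)``; b=0 entries give S0.  The gaussian
    model adds N(0, sigma^2) to the magnitude, the rician model takes
    ``|signal + n1 + i*n2|`` with independent N(0, sigma^2) channels.  Signals
    are clipped below at a small positive floor inside the mask and are zero
    outside it.
    """
    geometry = field.geometry
    D = np.asarray(true_tensor_field, dtype=float)
    if D.shape != geometry.shape + (3, 3):
        raise ValueError("tensor field grid does not match the field-correction grid")
    if noise_model not in ("gaussian", "rician"):
        raise ValueError("noise_model must be 'gaussian' or 'rician'")
    L = field.values
    Lb = np.einsum("...ij,njk->...nik", L, scheme.bmats)
    beff = np.einsum("...nik,...lk->...nil", Lb, L)
    expo = np.einsum("...nij,...ij->...n", beff, D)
    signals = S0 * np.exp(-expo)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_sigma > 0:
        if noise_model == "gaussian":
            signals = signals + rng.normal(0.0, noise_sigma, signals.shape)
        else:
            n1 = rng.normal(0.0, noise_sigma, signals.shape)
            n2 = rng.normal(0.0, noise_sigma, signals.shape)
            signals = np.hypot(signals + n1, n2)
    floor = 1e-6 * S0
    signals = np.maximum(signals, floor)
    if mask is not None:
        signals = signals * mask[..., None]
    return DwiDataset(geometry=geometry, signals=signals, scheme=scheme, mask=mask)


# --- phantom ----------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Isotropic sphere phantom: D(r) = D0 * I inside a sphere.

    Defaults emulate a NiSO4-doped water sphere at room temperature
    (D0 ~ 2.07e-3 mm^2/s) with the noise level set so the b=1000 s/mm^2
    shell has single-voxel SNR ~ 50 -- the level at which the per-voxel MD
    spread of a single phantom measurement sits near 2%, as observed in
    clinical phantom QC.
    """

    d0: float = DEFAULT_PHANTOM_D0     # mm^2/s
    center: tuple = (0.0, 0.0, 0.0)    # world mm
    radius_mm: float = 35.0
    s0: float = 1000.0
    noise_sigma: float = 2.5           # b=1000 shell signal (~126) / 50
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.radius_mm <= 0 or self.noise_sigma < 0:
            raise ValueError("invalid phantom specification")


def phantom_mask(spec: PhantomSpec, geometry: Geometry) -> np.ndarray:
    pts = geometry.voxel_centers()
    r2 = ((pts - np.asarray(spec.center)) ** 2).sum(axis=-1)
    return r2 <= spec.radius_mm ** 2


def simulate_phantom_pair(spec: PhantomSpec, field: FieldCorrectionTensor,
                          scheme: GradientScheme) -> tuple[DwiDataset, DwiDataset]:
    """Twin phantom acquisitions with independent noise realizations.

    The first is meant for calibration, the second for independent
    validation; they share geometry, field and true diffusivity and differ
    only in the noise seed (seed and seed + 1).
    """
    geometry = field.geometry
    mask = phantom_mask(spec, geometry)
    D = np.zeros(geometry.shape + (3, 3))
    D[mask] = spec.d0 * np.eye(3)
    out = []
    for k in range(2):
        ds = simulate_dwi(D, field, scheme, S0=spec.s0,
                          noise_sigma=spec.noise_sigma,
                          noise_model=spec.noise_model,
                          seed=spec.seed + k, mask=mask)
        ds.metadata.update({"true_d0": spec.d0, "acquisition": k + 1,
                            "radius_mm": spec.radius_mm})
        out.append(ds)
    return out[0], out[1]


# --- axially symmetric tensors ---------------------------------------------

def axisymmetric_tensor(fa: float, md: float, axis) -> np.ndarray:
    """Symmetric tensor with prescribed FA, MD and principal axis.

    Eigenvalues are ``md(1+2f), md(1-f), md(1-f)`` with
    ``f = fa / sqrt(3 - 2 fa^2)``; recomputing FA and MD from the result
    reproduces the inputs exactly.
    """
    if not (0.0 <= fa < 1.0):
        raise ValueError("fa must lie in [0, 1)")
    if md <= 0:
        raise ValueError("md must be positive")
    a = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("axis must be nonzero")
    a = a / norm
    f = fa / np.sqrt(3.0 - 2.0 * fa ** 2)
    lam = md * np.array([1.0 + 2.0 * f, 1.0 - f, 1.0 - f])
    # orthonormal frame with `a` first
    helper = np.array([1.0, 0.0, 0.0])
    if abs(a[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(a, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(a, e2)
    R = np.column_stack([a, e2, e3])
    return (R * lam) @ R.T


# --- cohort -----------------------------------------------------------------

@dataclass
class CohortSpec:
    """Two-group cohort with parcel-level diffusion differences.

    The patient group's affected parcels have MD raised by ``md_shift`` and
    FA lowered by ``fa_shift`` (relative fractions); subject-level parcel
    means vary with coefficient of variation ``between_subject_cv``.
    Defaults follow the whole-brain group summaries of the clinical study the
    generator emulates: MD ~5.5% higher and FA ~3.7% lower in patients, with
    ~4% between-subject spread.
    """

    n_per_group: int = 50
    n_rois: int = 95
    affected_roi_fraction: float = 0.4
    md_shift: float = 0.055
    fa_shift: float = 0.037
    between_subject_cv: float = 0.04
    noise_sigma: float = 2.5
    s0: float = 1000.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1 or self.n_per_group < 1:
            raise ValueError("invalid cohort size")
        if not (0.0 <= self.affected_roi_fraction <= 1.0):
            raise ValueError("affected_roi_fraction must be in [0, 1]")


@dataclass
class CohortSubject:
    subject_id: str
    group: str                    # "HC" or "MS"
    dwi: DwiDataset
    labels: "object"              # roi_analysis.LabelMap on the fine grid

    def __iter__(self):
        return iter((self.subject_id, self.group, self.dwi, self.labels))


@dataclass
class Cohort:
    subjects: list
    manifest: dict
    grouping: dict                # roi label -> "WM" | "GM"


def _parcellate(fine_geometry: Geometry, n_rois: int,
                rng: np.random.Generator) -> np.ndarray:
    """Voronoi parcellation of an ellipsoidal 'brain' into n_rois parcels.

    Seeds are drawn inside the ellipsoid, parcels are nearest-seed regions,
    relabeled 1..K by sorted parcel centroid so labeling is reproducible.
    """
    pts = fine_geometry.voxel_centers()
    lo, hi = fine_geometry.world_bounds()
    center = (lo + hi) / 2.0
    semi = 0.8 * (hi - lo) / 2.0
    u = (pts - center) / semi
    mask = (u ** 2).sum(axis=-1) <= 1.0
    in_pts = pts[mask]
    seeds = []
    while len(seeds) < n_rois:
        cand = center + (rng.uniform(-1, 1, size=(4 * n_rois, 3))) * semi
        inside = ((cand - center) / semi) ** 2
        cand = cand[inside.sum(axis=1) <= 1.0]
        seeds.extend(cand.tolist())
    seeds = np.asarray(seeds[:n_rois])
    tree = cKDTree(seeds)
    _, assign = tree.query(in_pts)
    labels = np.zeros(fine_geometry.shape, dtype=np.int16)
    labels[mask] = assign + 1
    # relabel by centroid order
    cents = np.array([in_pts[assign == k].mean(axis=0) for k in range(n_rois)])
    order = np.lexsort((cents[:, 2], cents[:, 1], cents[:, 0]))
    remap = np.zeros(n_rois + 1, dtype=np.int16)
    remap[order + 1] = np.arange(1, n_rois + 1)
    return remap[labels]


def simulate_cohort(spec: CohortSpec, field: FieldCorrectionTensor,
                    scheme: GradientScheme,
                    label_voxel_mm: float = 1.2) -> Cohort:
    """Simulate a two-group cohort on the field's grid.

    Label maps are generated on a finer, T1-like grid (``label_voxel_mm``)
    covering the same world extent, so the downstream nearest-neighbor
    resampling step is exercised exactly as in a real study.  Returns the
    subjects together with a manifest of every true generator parameter.
    """
    from .roi_analysis import LabelMap, resample_labels  # local import: no cycle

    geometry = field.geometry
    lo, hi = geometry.world_bounds()
    extent = hi - lo + geometry.voxel_size
    fine_shape = tuple(int(np.ceil(e / label_voxel_mm)) for e in extent)
    fine_geometry = Geometry.centered(fine_shape, label_voxel_mm)

    rng = np.random.default_rng(spec.seed)
    labels_fine = _parcellate(fine_geometry, spec.n_rois, rng)
    K = spec.n_rois

    fa0 = rng.uniform(0.15, 0.55, size=K)
    md0 = rng.uniform(0.65e-3, 0.95e-3, size=K)
    axes = rng.standard_normal((K, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    n_aff = int(round(spec.affected_roi_fraction * K))
    affected = np.sort(rng.choice(K, size=n_aff, replace=False))
    wm = fa0 >= np.median(fa0)
    grouping = {int(k + 1): ("WM" if wm[k] else "GM") for k in range(K)}

    # group-level targets; patient shifts applied to affected parcels only
    fa_target = {"HC": fa0.copy(), "MS": fa0.copy()}
    md_target = {"HC": md0.copy(), "MS": md0.copy()}
    fa_target["MS"][affected] *= (1.0 - spec.fa_shift)
    md_target["MS"][affected] *= (1.0 + spec.md_shift)
    for grp in ("HC", "MS"):
        bad = np.where((fa_target[grp] < 0) | (fa_target[grp] >= 1.0)
                       | (md_target[grp] <= 0))[0]
        if bad.size:
            raise ValueError(f"infeasible FA/MD after shifts in ROI {bad[0] + 1}")

    labels_dwi = resample_labels(
        LabelMap(geometry=fine_geometry, labels=labels_fine), geometry
    ).labels
    mask_dwi = labels_dwi > 0

    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(2 * spec.n_per_group)
    fine_map = LabelMap(geometry=fine_geometry, labels=labels_fine,
                        grouping=grouping)

    subjects = []
    subject_truth = {}
    si = 0
    for grp in ("HC", "MS"):
        for k in range(spec.n_per_group):
            sid = f"{grp}{k + 1:03d}"
            fa_s = fa_target[grp] * (1.0 + spec.between_subject_cv
                                     * rng.standard_normal(K))
            md_s = md_target[grp] * (1.0 + spec.between_subject_cv
                                     * rng.standard_normal(K))
            fa_s = np.clip(fa_s, 0.0, 0.95)
            md_s = np.maximum(md_s, 1e-5)
            tensors_roi = np.array(
                [axisymmetric_tensor(fa_s[j], md_s[j], axes[j]) for j in range(K)]
            )
            Dfield = np.zeros(geometry.shape + (3, 3))
            Dfield[mask_dwi] = tensors_roi[labels_dwi[mask_dwi] - 1]
            dwi = simulate_dwi(
                Dfield, field, scheme, S0=spec.s0,
                noise_sigma=spec.noise_sigma, noise_model=spec.noise_model,
                seed=np.random.default_rng(child_seeds[si]), mask=mask_dwi,
            )
            dwi.metadata["subject_id"] = sid
            subjects.append(CohortSubject(sid, grp, dwi, fine_map))
            subject_truth[sid] = {"group": grp, "roi_fa": fa_s.tolist(),
                                  "roi_md": md_s.tolist()}
            si += 1

    manifest = {
        "spec": asdict(spec),
        "affected_rois": (affected + 1).tolist(),
        "roi_fa_base": fa0.tolist(),
        "roi_md_base": md0.tolist(),
        "roi_axis": axes.tolist(),
        "grouping": grouping,
        "subjects": subject_truth,
    }
    return Cohort(subjects=subjects, manifest=manifest, grouping=grouping)


# --- on-disk export ---------------------------------------------------------

def write_field_nifti(field: FieldCorrectionTensor, path,
                      geometry: Optional[Geometry] = None) -> None:
    """Write L(r) as a 4D NIfTI with 9 components (row-major 3x3 per voxel)."""
    geometry = geometry or field.geometry
    L = field.values_on(geometry)
    save_volume(path, L.reshape(geometry.shape + (9,)), geometry)


def write_dataset(dwi: DwiDataset, prefix) -> None:
    """Write a dataset as NIfTI + bval/bvec + b-matrix table + JSON manifest."""
    prefix = str(prefix)
    save_volume(prefix + "_dwi.nii.gz", dwi.signals, dwi.geometry)
    if dwi.mask is not None:
        save_volume(prefix + "_mask.nii.gz", dwi.mask.astype(np.int16),
                    dwi.geometry, dtype=np.int16)
    write_bvals_bvecs(dwi.scheme, prefix + ".bval", prefix + ".bvec")
    write_bmatrix_table(dwi.scheme.bmats, prefix + "_bmatrix.txt")
    with open(prefix + "_manifest.json", "w") as fh:
        json.dump({k: v for k, v in dwi.metadata.items()
                   if isinstance(v, (int, float, str, list, dict))}, fh, indent=2)
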