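"""Phantom-based estimation of the spatial b-matrix distribution b(r).

An isotropic phantom of known diffusivity D0 turns each diffusion-weighted
acquisition into a per-voxel measurement of its own effective b-value:
``ln(A0(r)/A_i(r)) = D0 * tr(b_i(r))``.  With an isotropic reference only the
trace of the effective b-matrix is identifiable per acquisition (one equation,
six unknowns), so the calibration estimates a positive scalar scale
``s_i(r) = tr(b_i(r)) / tr(b_i)`` and models the effective matrix as
``b_i(r) = s_i(r) * b_i`` -- the nominal matrix rescaled, eigenstructure
preserved.  When the underlying field-correction tensor is isotropic
(c(r) I) this is exact for any imaged object; for an anisotropic field the
residual bias is the direction-dependent part of ``tr(L b L^T)/tr(b)``, and
the correction remains exact for isotropic objects such as the phantom
itself.

The raw per-voxel scales are optionally replaced by a low-order polynomial in
world coordinates (gradient nonlinearity is smooth), fitted by weighted least
squares on the log-signals and refined by a few Gauss-Newton steps on the
signal-domain residual to remove the log-transform's small-signal bias.  The
polynomial model also defines evaluation on other grids sharing the
scanner's laboratory frame.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _poly
from .containers import DwiDataset, Geometry, save_volume
from .gradient_scheme import GradientScheme, _match_entries
from .tensor_fit import compute_metrics, fit_tensor

logger = logging.getLogger(__name__)

__all__ = [
    "BMatrixField",
    "CalibrationError",
    "estimate_b_field",
    "apply_field",
    "phantom_qc_report",
    "cv_percent",
    "save_field",
    "load_field",
]


class CalibrationError(RuntimeError):
    """The phantom acquisition cannot support a b-field estimate."""


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, 100 * SD / mean."""
    return 100.0 * sd / mean


@dataclass
class BMatrixField:
    """Per-voxel, per-acquisition effective b-matrices as nominal * scale.

    ``scales`` has shape ``(*geometry.shape, n_entries)`` aligned with
    ``scheme``; b=0 entries carry scale 1.  With all scales identically 1 the
    field reduces to the conventional constant-b-matrix (STD) case.
    ``model`` optionally holds the smooth polynomial representation used for
    evaluation on other grids.
    """

    geometry: Geometry
    scheme: GradientScheme
    scales: np.ndarray
    valid: np.ndarray
    model: Optional[dict] = None
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        if self.scales.shape != self.geometry.shape + (len(self.scheme),):
            raise ValueError("scale array does not match geometry/scheme")
        self.valid = np.asarray(self.valid, dtype=bool)

    @classmethod
    def unit(cls, geometry: Geometry, scheme: GradientScheme) -> "BMatrixField":
        """The degenerate constant field: every scale 1 (STD behaviour)."""
        scales = np.ones(geometry.shape + (len(scheme),))
        return cls(geometry=geometry, scheme=scheme, scales=scales,
                   valid=np.ones(geometry.shape, dtype=bool))

    @classmethod
    def from_true_field(cls, field_correction, geometry: Geometry,
                        scheme: GradientScheme) -> "BMatrixField":
        """Ground-truth scale field tr(L b L^T)/tr(b) from a known L(r)."""
        scales = np.ones(geometry.shape + (len(scheme),))
        w = scheme.weighted_mask
        scales[..., w] = field_correction.true_scales(geometry, scheme.bmats[w])
        return cls(geometry=geometry, scheme=scheme, scales=scales,
                   valid=np.ones(geometry.shape, dtype=bool))

    def scales_for(self, scheme: GradientScheme) -> np.ndarray:
        """Scales for the weighted entries of `scheme` (a subset or the full set)."""
        if scheme is self.scheme:
            return self.scales[..., scheme.weighted_mask]
        idx = _match_entries(self.scheme, scheme)
        return self.scales[..., idx][..., scheme.weighted_mask]

    def effective_bmats(self) -> np.ndarray:
        """Per-voxel effective b-matrices, shape (*shape, n_entries, 3, 3)."""
        return self.scales[..., None, None] * self.scheme.bmats


def _background_sigma(dwi: DwiDataset) -> float:
    """Noise SD estimated from voxels outside the object mask."""
    bg = dwi.signals[~dwi.mask]
    bg = bg[bg > 0]
    if bg.size < 100:
        return 0.0
    return float(bg.std())


def estimate_b_field(phantom: DwiDataset, reference_D: float,
                     smooth_degree: int = 2,
                     min_signal_floor: Optional[float] = None,
                     refine: bool = True, n_refine: int = 3) -> BMatrixField:
    """Estimate the b-matrix scale field from an isotropic phantom scan.

    Per weighted acquisition i and mask voxel r, the raw scale is
    ``s_i(r) = ln(A0(r) / A_i(r)) / (reference_D * tr(b_i))`` with A0 the
    mean of the b=0 volumes.  ``smooth_degree >= 0`` replaces the raw scales
    with a polynomial of that total degree in world coordinates (fitted over
    the mask; this also defines extrapolation); ``smooth_degree = -1`` keeps
    the raw voxelwise scales.  Voxels whose signal falls below the floor
    (default: 3x the background noise estimate) are excluded from the fit and
    marked invalid in the raw case.
    """
    if reference_D <= 0:
        raise CalibrationError("reference diffusivity must be positive")
    scheme = phantom.scheme
    if not np.any(scheme.b0_mask):
        raise CalibrationError("phantom scheme has no b=0 image")
    a0 = phantom.signals[..., scheme.b0_mask].mean(axis=-1)
    w = scheme.weighted_mask
    aw = phantom.signals[..., w]
    traces = scheme.bvals[w]

    if min_signal_floor is None:
        min_signal_floor = 3.0 * _background_sigma(phantom)
    floor = max(float(min_signal_floor), 1e-12)

    valid0 = phantom.mask & (a0 > floor)
    valid_i = valid0[..., None] & (aw > floor)          # per-acquisition
    if not np.any(valid_i):
        raise CalibrationError("no voxel above the signal floor")

    denom = reference_D * traces
    with np.errstate(divide="ignore", invalid="ignore"):
        s_raw = np.log(a0[..., None] / aw) / denom
    s_raw = np.where(valid_i, s_raw, np.nan)

    scales = np.ones(phantom.geometry.shape + (len(scheme),))
    model = None
    if smooth_degree < 0:
        s_filled = np.where(np.isnan(s_raw), 1.0, s_raw)
        scales[..., w] = s_filled
        valid = valid_i.all(axis=-1) & valid0
    else:
        exps = _poly.monomial_exponents(smooth_degree, include_constant=True)
        pts = phantom.geometry.voxel_centers()
        mpts = pts[valid0]
        lo, hi = mpts.min(axis=0), mpts.max(axis=0)
        center = (lo + hi) / 2.0
        halfwidth = np.maximum((hi - lo) / 2.0, 1e-9)
        B_all = _poly.basis(pts, exps, center, halfwidth)
        n_w = int(np.count_nonzero(w))
        coeffs = np.zeros((len(scheme), len(exps)))
        coeffs[:, 0] = 1.0
        aw_m = aw[valid0]                                # (V, n_w)
        a0_m = a0[valid0]
        s_m = s_raw[valid0]
        B_m = B_all[valid0]
        for j in range(n_w):
            ok = ~np.isnan(s_m[:, j])
            if np.count_nonzero(ok) < len(exps):
                raise CalibrationError(
                    f"too few valid voxels to smooth acquisition {j}"
                )
            # WLS on log-signals, weights A^2 (first-order signal-domain fit)
            wts = aw_m[ok, j] ** 2
            Bw = B_m[ok] * np.sqrt(wts)[:, None]
            yw = s_m[ok, j] * np.sqrt(wts)
            c, *_ = np.linalg.lstsq(Bw, yw, rcond=None)
            if refine:
                # Gauss-Newton on the signal-domain residual removes the
                # log-transform bias at low per-acquisition SNR
                cj = denom[j]
                for _ in range(n_refine):
                    pred = a0_m[ok] * np.exp(-cj * (B_m[ok] @ c))
                    r = aw_m[ok, j] - pred
                    J = -cj * pred[:, None] * B_m[ok]
                    dc, *_ = np.linalg.lstsq(J, r, rcond=None)
                    c = c + dc
            coeffs[np.where(w)[0][j]] = c
        scales = (B_all @ coeffs.T)
        scales[..., ~w] = 1.0
        valid = valid0
        model = {
            "exponents": exps,
            "center": center,
            "halfwidth": halfwidth,
            "coeffs": coeffs,
            "degree": int(smooth_degree),
            "calib_lo": lo,
            "calib_hi": hi,
        }
    # scales must stay positive on the validity mask
    bad = np.count_nonzero((scales[valid] <= 0))
    if bad:
        logger.warning("estimate_b_field: %d nonpositive scales clamped", bad)
        scales = np.maximum(scales, 1e-6)
    return BMatrixField(geometry=phantom.geometry, scheme=scheme,
                        scales=scales, valid=valid, model=model,
                        metadata={"reference_D": reference_D,
                                  "smooth_degree": smooth_degree,
                                  "signal_floor": floor})


def apply_field(field: BMatrixField, target_geometry: Geometry,
                margin: float = 0.1,
                allow_extrapolation: bool = False) -> BMatrixField:
    """Evaluate a calibrated field on another grid in laboratory coordinates.

    Requires the smooth polynomial model unless the geometry is identical.
    The target grid must stay within the calibrated region's world bounding
    box expanded by ``margin`` (fraction of its extent) unless
    ``allow_extrapolation`` is set.
    """
    if target_geometry.matches(field.geometry):
        return BMatrixField(geometry=field.geometry, scheme=field.scheme,
                            scales=field.scales.copy(), valid=field.valid.copy(),
                            model=field.model, metadata=dict(field.metadata))
    if field.model is None:
        raise CalibrationError(
            "resampling a raw (unsmoothed) field requires the polynomial model"
        )
    m = field.model
    lo, hi = np.asarray(m["calib_lo"]), np.asarray(m["calib_hi"])
    extent = np.maximum(hi - lo, 1e-9)
    tlo, thi = target_geometry.world_bounds()
    if not allow_extrapolation:
        if np.any(tlo < lo - margin * extent) or np.any(thi > hi + margin * extent):
            raise CalibrationError(
                "target grid extends beyond the calibrated region; "
                "pass allow_extrapolation=True to override"
            )
    pts = target_geometry.voxel_centers()
    B = _poly.basis(pts, m["exponents"], m["center"], m["halfwidth"])
    scales = B @ np.asarray(m["coeffs"]).T
    scales[..., ~field.scheme.weighted_mask] = 1.0
    scales = np.maximum(scales, 1e-6)
    return BMatrixField(geometry=target_geometry, scheme=field.scheme,
                        scales=scales,
                        valid=np.ones(target_geometry.shape, dtype=bool),
                        model=field.model, metadata=dict(field.metadata))


def phantom_qc_report(phantom2: DwiDataset, field: BMatrixField,
                      reference_D: float,
                      scheme_names: Sequence[str],
                      weighting: str = "wlls") -> pd.DataFrame:
    """Systematic-error assessment on an independent phantom acquisition.

    For every protocol subset and both approaches, fits the tensor over the
    phantom mask and reports mean FA, mean MD, the spatial SD of MD and its
    CV% -- the quantities by which an isotropic phantom exposes residual
    systematic error (ideal FA is 0, ideal MD spread is 0).  A paired
    Wilcoxon test across voxels quantifies the STD-vs-BSD change per subset.
    """
    from .group_stats import wilcoxon_paired

    rows = []
    for name in scheme_names:
        ds = phantom2.subset(name)
        per_approach = {}
        for approach in ("STD", "BSD"):
            f = field if approach == "BSD" else None
            tf = fit_tensor(ds, field=f, mode=approach, weighting=weighting)
            mm = compute_metrics(tf)
            msk = tf.mask
            fa = mm.fa[msk]
            md = mm.md[msk]
            per_approach[approach] = (fa, md)
            rows.append({
                "scheme": name,
                "approach": approach,
                "n_voxels": int(msk.sum()),
                "fa_mean": float(fa.mean()),
                "fa_sd": float(fa.std(ddof=1)),
                "md_mean": float(md.mean()),
                "md_sd": float(md.std(ddof=1)),
                "md_cv_pct": cv_percent(float(md.mean()), float(md.std(ddof=1))),
                "md_bias_vs_reference": float(md.mean() - reference_D),
            })
        for metric_name, k in (("fa", 0), ("md", 1)):
            _, z, p, r = wilcoxon_paired(per_approach["STD"][k],
                                         per_approach["BSD"][k])
            for row in rows[-2:]:
                row[f"wilcoxon_{metric_name}_p"] = p
                row[f"wilcoxon_{metric_name}_r"] = r
    return pd.DataFrame(rows)


# --- serialization ----------------------------------------------------------

def save_field(field: BMatrixField, json_path, nifti_path=None) -> None:
    """Serialize the polynomial model as JSON, optionally the voxel scales as NIfTI."""
    payload = {
        "shape": list(field.geometry.shape),
        "affine": field.geometry.affine.tolist(),
        "bvals": field.scheme.bvals.tolist(),
        "directions": field.scheme.directions.tolist(),
        "metadata": {k: v for k, v in field.metadata.items()
                     if isinstance(v, (int, float, str))},
    }
    if field.model is not None:
        payload["model"] = {
            "exponents": np.asarray(field.model["exponents"]).tolist(),
            "center": np.asarray(field.model["center"]).tolist(),
            "halfwidth": np.asarray(field.model["halfwidth"]).tolist(),
            "coeffs": np.asarray(field.model["coeffs"]).tolist(),
            "degree": field.model["degree"],
            "calib_lo": np.asarray(field.model["calib_lo"]).tolist(),
            "calib_hi": np.asarray(field.model["calib_hi"]).tolist(),
        }
    with open(str(json_path), "w") as fh:
        json.dump(payload, fh)
    if nifti_path is not None:
        save_volume(nifti_path, field.scales, field.geometry)


def load_field(json_path) -> BMatrixField:
    with open(str(json_path)) as fh:
        payload = json.load(fh)
    geometry = Geometry(tuple(payload["shape"]), np.asarray(payload["affine"]))
    scheme = GradientScheme.from_bvals_bvecs(payload["bvals"],
                                             np.asarray(payload["directions"]))
    model = None
    if "model" in payload:
        m = payload["model"]
        model = {
            "exponents": np.asarray(m["exponents"], dtype=int),
            "center": np.asarray(m["center"]),
            "halfwidth": np.asarray(m["halfwidth"]),
            "coeffs": np.asarray(m["coeffs"]),
            "degree": int(m["degree"]),
            "calib_lo": np.asarray(m["calib_lo"]),
            "calib_hi": np.asarray(m["calib_hi"]),
        }
        B = _poly.basis(geometry.voxel_centers(), model["exponents"],
                        model["center"], model["halfwidth"])
        scales = B @ model["coeffs"].T
        scales[..., np.asarray(payload["bvals"]) == 0] = 1.0
    else:
        raise CalibrationError("field JSON lacks a polynomial model")
    return BMatrixField(geometry=geometry, scheme=scheme, scales=scales,
                        valid=np.ones(geometry.shape, dtype=bool),
                        model=model, metadata=payload.get("metadata", {}))
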