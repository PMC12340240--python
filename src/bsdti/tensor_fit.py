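"""Per-voxel diffusion tensor estimation and scalar metric maps.

The monoexponential signal model ``ln(A_i / A_0) = -<b_i, D>`` is solved per
voxel as a linear system in the six unique tensor components, over however
many weighted acquisitions the protocol provides (40, 20, 11 or 6 here).
Two weighting modes are available: ordinary least squares on the
log-signals, and weighted least squares with squared-signal weights -- the
first-order (Gauss-Newton) linearization of the signal-domain chi-square,
which is the standard deterministic reading of chi-square minimization for
this model.

Two fit modes mirror the two processing approaches under study: STD uses the
single nominal b-matrix per acquisition everywhere; BSD substitutes the
calibrated per-voxel b-matrices b_i(r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .containers import DwiDataset, Geometry
from .gradient_scheme import design_matrix

logger = logging.getLogger(__name__)

__all__ = ["TensorField", "MetricMaps", "fit_tensor", "compute_metrics"]


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor with its eigensystem."""

    geometry: Geometry
    tensors: np.ndarray        # (*shape, 3, 3), mm^2/s
    eigenvalues: np.ndarray    # (*shape, 3), sorted descending
    principal_axis: np.ndarray  # (*shape, 3)
    mask: np.ndarray
    mode: str                  # "STD" | "BSD"
    weighting: str             # "ols" | "wlls"
    residual: np.ndarray       # per-voxel weighted sum of squared residuals
    n_masked_out: int = 0


@dataclass
class MetricMaps:
    """FA/MD/AD/RD scalar volumes derived from a tensor field."""

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    mask: np.ndarray
    geometry: Geometry

    def as_dict(self) -> dict:
        return {"FA": self.fa, "MD": self.md, "AD": self.ad, "RD": self.rd}


def fit_tensor(dwi: DwiDataset, field=None, mode: str = "STD",
               weighting: str = "wlls") -> TensorField:
    """Fit the diffusion tensor at every masked voxel.

    mode "STD" uses the scheme's nominal b-matrices for all voxels; "BSD"
    requires a calibrated b-matrix field (:class:`~bsdti.bsd_calibration.
    BMatrixField`) and uses its per-voxel effective b-matrices.  Voxels with
    nonpositive signals are excluded and counted.
    """
    scheme = dwi.scheme
    if mode not in ("STD", "BSD"):
        raise ValueError("mode must be 'STD' or 'BSD'")
    if weighting not in ("ols", "wlls"):
        raise ValueError("weighting must be 'ols' or 'wlls'")
    if mode == "BSD" and field is None:
        raise ValueError("BSD mode requires a calibrated b-matrix field")
    w_mask = scheme.weighted_mask
    n_w = scheme.n_weighted
    if n_w < 6:
        raise ValueError("tensor fit needs at least 6 weighted acquisitions")
    if not np.any(scheme.b0_mask):
        raise ValueError("tensor fit needs at least one b=0 acquisition")

    X = design_matrix(scheme.bmats[w_mask])          # (n, 6)
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("rank-deficient design: directions are coplanar")

    a0 = dwi.signals[..., scheme.b0_mask].mean(axis=-1)
    aw = dwi.signals[..., w_mask]
    valid = dwi.mask & (a0 > 0) & np.all(aw > 0, axis=-1)
    n_masked_out = int(np.count_nonzero(dwi.mask) - np.count_nonzero(valid))
    if n_masked_out:
        logger.info("fit_tensor: %d voxels excluded for nonpositive signal",
                    n_masked_out)

    shape = dwi.geometry.shape
    tensors = np.zeros(shape + (3, 3))
    resid = np.zeros(shape)
    evals = np.zeros(shape + (3,))
    pax = np.zeros(shape + (3,))

    idx = np.where(valid)
    if idx[0].size:
        y = -np.log(aw[valid] / a0[valid][:, None])   # (V, n); y = <b, D>
        if mode == "BSD":
            if not field.geometry.matches(dwi.geometry):
                raise ValueError("b-matrix field geometry does not match data")
            scales = field.scales_for(scheme)[valid]  # (V, n)
            Xv = scales[:, :, None] * X[None, :, :]
        else:
            Xv = np.broadcast_to(X, (idx[0].size,) + X.shape)
        if weighting == "wlls":
            w = aw[valid] ** 2
        else:
            w = np.ones_like(aw[valid])
        XtW = Xv.transpose(0, 2, 1) * w[:, None, :]
        A = XtW @ Xv
        b = (XtW @ y[:, :, None])[:, :, 0]
        d6 = np.linalg.solve(A, b[..., None])[..., 0]  # (V, 6)
        Dv = np.zeros((idx[0].size, 3, 3))
        Dv[:, 0, 0] = d6[:, 0]
        Dv[:, 1, 1] = d6[:, 1]
        Dv[:, 2, 2] = d6[:, 2]
        Dv[:, 0, 1] = Dv[:, 1, 0] = d6[:, 3]
        Dv[:, 0, 2] = Dv[:, 2, 0] = d6[:, 4]
        Dv[:, 1, 2] = Dv[:, 2, 1] = d6[:, 5]
        tensors[valid] = Dv
        r = (Xv @ d6[:, :, None])[:, :, 0] - y
        resid[valid] = (w * r ** 2).sum(axis=-1)
        ev, evec = np.linalg.eigh(Dv)
        evals[valid] = ev[:, ::-1]
        pax[valid] = evec[:, :, 2]

    return TensorField(geometry=dwi.geometry, tensors=tensors,
                       eigenvalues=evals, principal_axis=pax, mask=valid,
                       mode=mode, weighting=weighting, residual=resid,
                       n_masked_out=n_masked_out)


def compute_metrics(tensors: TensorField) -> MetricMaps:
    """FA, MD, AD, RD maps from the eigenvalues.

    FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||, defined as 0 where all
    eigenvalues vanish and clipped to [0, 1].  Negative eigenvalues are kept
    for MD/AD/RD (clamping would bias noisy-phantom means); their frequency
    is logged.
    """
    lam = tensors.eigenvalues
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = (lam[..., 1] + lam[..., 2]) / 2.0
    num = np.linalg.norm(lam - md[..., None], axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    neg = np.count_nonzero((lam < 0) & tensors.mask[..., None])
    tot = np.count_nonzero(tensors.mask) * 3
    if tot:
        logger.info("compute_metrics: %.3f%% negative eigenvalues",
                    100.0 * neg / tot)
    return MetricMaps(fa=fa, md=md, ad=ad, rd=rd, mask=tensors.mask,
                      geometry=tensors.geometry)
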