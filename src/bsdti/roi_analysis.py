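"""ROI label maps: resampling to the DWI grid and per-region metric summaries.

Label maps come from a finer anatomical (T1-like) grid and are brought to
diffusion resolution by nearest-neighbor assignment in world millimetre
coordinates -- nearest in the scanner frame, not in index space, because
anisotropic voxels make index-space distances wrong.  Summaries are tidy
per-(region, metric) means, including the whole-brain / white-matter /
gray-matter aggregates used for the coarse group comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .containers import Geometry
from .tensor_fit import MetricMaps

logger = logging.getLogger(__name__)

__all__ = ["LabelMap", "resample_labels", "summarize", "AGGREGATES"]

AGGREGATES = ("WB", "WM", "GM")


@dataclass
class LabelMap:
    """Integer parcellation: 0 is background, 1..K are regions."""

    geometry: Geometry
    labels: np.ndarray
    grouping: Optional[Mapping[int, str]] = None   # label -> "WM" | "GM"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.shape != self.geometry.shape:
            raise ValueError("label grid does not match geometry")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.grouping is not None:
            present = set(int(v) for v in np.unique(self.labels) if v != 0)
            missing = present - set(int(k) for k in self.grouping)
            if missing:
                raise ValueError(f"grouping misses labels: {sorted(missing)}")

    @property
    def roi_ids(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals != 0]


def _orthogonal_axes(affine: np.ndarray, tol: float = 1e-9) -> bool:
    A = affine[:3, :3]
    G = A.T @ A
    off = G - np.diag(np.diag(G))
    return bool(np.max(np.abs(off)) < tol * max(1.0, np.max(np.abs(G))))


def resample_labels(labels: LabelMap, target_geometry: Geometry) -> LabelMap:
    """Nearest-neighbor resampling of a label map onto a target grid.

    Each target voxel takes the label of the nearest source voxel *center* in
    world coordinates; targets outside the source grid get background.  For
    grids with orthogonal axes the nearest center factorizes per axis and is
    found by rounding the continuous source index; the general (oblique)
    case falls back to a KD-tree over source centers, which breaks exact
    ties toward the lowest source index.
    """
    src = labels.geometry
    if abs(np.linalg.det(src.affine[:3, :3])) < 1e-12:
        raise ValueError("singular source affine")
    tgt_pts = target_geometry.voxel_centers().reshape(-1, 3)
    shape = np.asarray(src.shape)
    if _orthogonal_axes(src.affine):
        cont = src.world_to_index(tgt_pts)
        idx = np.rint(cont).astype(int)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.zeros(len(tgt_pts), dtype=labels.labels.dtype)
        ii = idx[inside]
        out[inside] = labels.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    else:
        src_pts = src.voxel_centers().reshape(-1, 3)
        tree = cKDTree(src_pts)
        dist, flat = tree.query(tgt_pts, k=2)
        nearest = flat[:, 0].copy()
        # near-exact ties break toward the lowest source index
        tol = 1e-9 * max(1.0, float(np.abs(src_pts).max()))
        tied = np.where(dist[:, 1] - dist[:, 0] <= tol)[0]
        for i in tied:
            cand = tree.query_ball_point(tgt_pts[i], dist[i, 0] + tol)
            nearest[i] = min(cand)
        # out-of-bounds: farther than half a voxel diagonal from any center
        halfdiag = 0.5 * np.linalg.norm(src.affine[:3, :3].sum(axis=1))
        out = labels.labels.reshape(-1)[nearest].copy()
        out[dist[:, 0] > halfdiag] = 0
    return LabelMap(geometry=target_geometry,
                    labels=out.reshape(target_geometry.shape),
                    grouping=labels.grouping)


def summarize(metrics: MetricMaps, labels: LabelMap,
              grouping: Optional[Mapping[int, str]] = None) -> pd.DataFrame:
    """Per-ROI means of each metric plus WB/WM/GM aggregates.

    Returns a tidy frame with columns (roi, metric, mean, n_voxels); ``roi``
    is the integer label as a string, or one of "WB"/"WM"/"GM".  Only voxels
    inside the metric validity mask contribute; empty regions are recorded
    with count 0 and a missing mean.
    """
    if not labels.geometry.matches(metrics.geometry):
        raise ValueError("label map must be resampled to the metric grid first")
    grouping = grouping if grouping is not None else labels.grouping
    lab = labels.labels
    valid = metrics.mask
    rows = []
    roi_ids = labels.roi_ids
    metric_dict = metrics.as_dict()

    masks = {str(int(r)): (lab == r) & valid for r in roi_ids}
    masks["WB"] = (lab > 0) & valid
    if grouping is not None:
        for cls in ("WM", "GM"):
            ids = [int(k) for k, v in grouping.items() if v == cls]
            masks[cls] = np.isin(lab, ids) & valid

    for roi, m in masks.items():
        n = int(np.count_nonzero(m))
        for metric_name, vol in metric_dict.items():
            if n == 0:
                logger.warning("summarize: region %s is empty", roi)
                rows.append({"roi": roi, "metric": metric_name,
                             "mean": np.nan, "n_voxels": 0})
            else:
                rows.append({"roi": roi, "metric": metric_name,
                             "mean": float(vol[m].mean()), "n_voxels": n})
    return pd.DataFrame(rows)
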