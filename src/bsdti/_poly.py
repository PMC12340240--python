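"""Low-order 3D polynomial bases on normalized world coordinates.

Shared by the synthetic field generator and the calibration smoother.  A
model is defined by its monomial exponents together with a normalization
(center, halfwidth in mm) so it can be evaluated on any grid in world space.
"""

from __future__ import annotations

import itertools

import numpy as np


def monomial_exponents(degree: int, include_constant: bool = True) -> np.ndarray:
    """Exponent triples (i, j, k) with total degree <= `degree`, sorted."""
    lo = 0 if include_constant else 1
    exps = [
        (i, j, k)
        for i, j, k in itertools.product(range(degree + 1), repeat=3)
        if lo <= i + j + k <= degree
    ]
    exps.sort(key=lambda e: (sum(e), e))
    return np.asarray(exps, dtype=int)


def basis(points: np.ndarray, exponents: np.ndarray,
          center: np.ndarray, halfwidth: np.ndarray) -> np.ndarray:
    """Evaluate the monomial basis at world points.

    points: (..., 3) world mm; returns (..., n_monomials) with coordinates
    normalized to roughly [-1, 1] by (x - center) / halfwidth.
    """
    u = (np.asarray(points, float) - center) / halfwidth
    out = np.empty(u.shape[:-1] + (len(exponents),), dtype=float)
    for m, (i, j, k) in enumerate(exponents):
        out[..., m] = u[..., 0] ** i * u[..., 1] ** j * u[..., 2] ** k
    return out


def fit(points: np.ndarray, values: np.ndarray, exponents: np.ndarray,
        center: np.ndarray, halfwidth: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for values sampled at world points.

    values may have trailing dimensions; one fit per trailing column.
    """
    B = basis(points, exponents, center, halfwidth)
    B = B.reshape(-1, B.shape[-1])
    v = np.asarray(values, float).reshape(B.shape[0], -1)
    coef, *_ = np.linalg.lstsq(B, v, rcond=None)
    return coef  # (n_monomials, n_cols)
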