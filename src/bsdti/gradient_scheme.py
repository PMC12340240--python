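"""Diffusion gradient schemes: b-values, directions, nominal b-matrices.

A multi-shell clinical protocol is represented as an ordered list of
acquisitions, each carrying its b-value (s/mm^2), unit gradient direction and
nominal symmetric 3x3 b-matrix with ``trace(b) = b-value``.  The primary
protocol studied here, 1000/2000(40), holds one b=0 reference plus 20
directions at b=1000 and the same 20 at b=2000 s/mm^2; four named subsets
(2000(20), 1000(20), 1000(11), 1000(6)) restrict it to single shells and to
reduced direction counts.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GradientScheme",
    "InvalidSchemeError",
    "PROTOCOL_NAMES",
    "nominal_b_matrix",
    "make_protocol",
    "electrostatic_directions",
    "design_matrix",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_bmatrix_table",
    "write_bmatrix_table",
]

PROTOCOL_NAMES = ("1000/2000(40)", "2000(20)", "1000(20)", "1000(11)", "1000(6)")

_UNIT_TOL = 1e-9


class InvalidSchemeError(ValueError):
    """A gradient scheme violates its structural invariants."""


def nominal_b_matrix(b_value: float, direction) -> np.ndarray:
    """Nominal b-matrix ``b * g g^T`` for a single acquisition.

    For b=0 the direction is irrelevant and the zero matrix is returned; a
    positive b-value with a zero direction is rejected.
    """
    g = np.asarray(direction, dtype=float)
    if g.shape != (3,):
        raise InvalidSchemeError("direction must be a 3-vector")
    if b_value < 0:
        raise InvalidSchemeError("b-value must be nonnegative")
    if b_value == 0:
        return np.zeros((3, 3))
    norm = np.linalg.norm(g)
    if norm == 0:
        raise InvalidSchemeError("zero gradient direction with positive b-value")
    g = g / norm
    return b_value * np.outer(g, g)


def design_matrix(bmats: np.ndarray) -> np.ndarray:
    """Tensor-fit design rows from b-matrices.

    Maps ``(..., n, 3, 3)`` symmetric b-matrices to ``(..., n, 6)`` rows
    ``[bxx, byy, bzz, 2 bxy, 2 bxz, 2 byz]`` so that the Frobenius inner
    product <b, D> equals ``row @ [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]``.
    """
    b = np.asarray(bmats, dtype=float)
    return np.stack(
        [
            b[..., 0, 0],
            b[..., 1, 1],
            b[..., 2, 2],
            2.0 * b[..., 0, 1],
            2.0 * b[..., 0, 2],
            2.0 * b[..., 1, 2],
        ],
        axis=-1,
    )


@dataclass
class GradientScheme:
    """Ordered set of acquisitions: b-values, unit directions, b-matrices."""

    bvals: np.ndarray            # (n,)
    directions: np.ndarray       # (n, 3); zero rows for b=0 entries
    bmats: np.ndarray            # (n, 3, 3)
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        self.bmats = np.asarray(self.bmats, dtype=float)
        self.validate()

    @classmethod
    def from_bvals_bvecs(cls, bvals, bvecs, name: str = "") -> "GradientScheme":
        bvals = np.asarray(bvals, dtype=float)
        bvecs = np.asarray(bvecs, dtype=float)
        if bvecs.shape == (3, len(bvals)):
            bvecs = bvecs.T
        bmats = np.array([nominal_b_matrix(b, g) if b > 0 else np.zeros((3, 3))
                          for b, g in zip(bvals, bvecs)])
        dirs = bvecs.copy()
        dirs[bvals == 0] = 0.0
        return cls(bvals=bvals, directions=dirs, bmats=bmats, name=name)

    def validate(self) -> None:
        n = len(self.bvals)
        if self.directions.shape != (n, 3) or self.bmats.shape != (n, 3, 3):
            raise InvalidSchemeError("inconsistent scheme array shapes")
        if not np.any(self.bvals == 0):
            raise InvalidSchemeError("scheme has no b=0 reference image")
        weighted = self.bvals > 0
        norms = np.linalg.norm(self.directions[weighted], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidSchemeError("weighted directions must be unit vectors")
        if not np.allclose(self.bmats, np.swapaxes(self.bmats, -1, -2), atol=1e-9):
            raise InvalidSchemeError("b-matrices must be symmetric")
        traces = np.trace(self.bmats, axis1=-2, axis2=-1)
        scale = np.maximum(self.bvals, 1.0)
        if np.any(np.abs(traces - self.bvals) / scale > 1e-6):
            raise InvalidSchemeError("b-matrix trace must equal the b-value")
        eigs = np.linalg.eigvalsh(self.bmats)
        if np.any(eigs < -1e-6 * np.maximum(self.bvals, 1.0)[:, None]):
            raise InvalidSchemeError("b-matrices must be positive semidefinite")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def weighted_mask(self) -> np.ndarray:
        return self.bvals > 0

    @property
    def n_weighted(self) -> int:
        return int(np.count_nonzero(self.weighted_mask))

    def subset(self, name: str):
        """Return ``(subset_scheme, indices)`` for a named protocol subset.

        Only defined for schemes built by :func:`make_protocol` (the indices
        of the reduced-direction subsets are stored in metadata).
        """
        if name == self.name:
            return self, np.arange(len(self))
        base = self.metadata.get("base_directions")
        if base is None:
            raise InvalidSchemeError(
                "subsetting requires a scheme built by make_protocol"
            )
        sub = make_protocol(name, np.asarray(base), n_b0=self.metadata["n_b0"])
        idx = _match_entries(self, sub)
        return sub, idx

    def design(self) -> np.ndarray:
        """Design rows for the weighted entries only, shape (n_weighted, 6)."""
        return design_matrix(self.bmats[self.weighted_mask])


def _match_entries(parent: GradientScheme, sub: GradientScheme) -> np.ndarray:
    """Indices in parent matching each entry of sub (b-value + direction)."""
    idx = np.empty(len(sub), dtype=int)
    used = np.zeros(len(parent), dtype=bool)
    for k in range(len(sub)):
        found = -1
        for j in range(len(parent)):
            if used[j]:
                continue
            if parent.bvals[j] == sub.bvals[k] and np.allclose(
                parent.directions[j], sub.directions[k], atol=1e-9
            ):
                found = j
                break
        if found < 0:
            raise InvalidSchemeError(
                f"subset entry {k} not found in parent scheme {parent.name!r}"
            )
        used[found] = True
        idx[k] = found
    return idx


# --- default direction set -------------------------------------------------

@functools.lru_cache(maxsize=None)
def electrostatic_directions(n: int = 20, seed: int = 42, n_iter: int = 3000) -> np.ndarray:
    """Antipodally symmetric electrostatic-repulsion direction set.

    Minimizes the Coulomb energy sum(1/|di-dj| + 1/|di+dj|) over unit vectors
    by projected gradient descent from a seeded random start.  Deterministic
    for fixed (n, seed, n_iter).
    """
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    step = 0.01
    for _ in range(n_iter):
        diff = d[:, None, :] - d[None, :, :]
        summ = d[:, None, :] + d[None, :, :]
        nd = np.linalg.norm(diff, axis=-1)
        ns = np.linalg.norm(summ, axis=-1)
        np.fill_diagonal(nd, np.inf)
        np.fill_diagonal(ns, np.inf)
        ns[ns < 1e-12] = np.inf
        grad = -(diff / nd[..., None] ** 3).sum(axis=1) - (summ / ns[..., None] ** 3).sum(axis=1)
        d = d - step * grad
        d /= np.linalg.norm(d, axis=1, keepdims=True)
    # canonical orientation and order, for reproducibility of downstream subsets
    flip = d[:, 2] < 0
    d[flip] *= -1.0
    order = np.lexsort((d[:, 2], d[:, 1], d[:, 0]))
    d = d[order]
    d.setflags(write=False)
    return d


def _condition_number(dirs: np.ndarray) -> float:
    """Condition number of the unit-b design matrix for a direction set."""
    bmats = np.einsum("ni,nj->nij", dirs, dirs)
    X = design_matrix(bmats)
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] <= 0:
        return np.inf
    return float(s[0] / s[-1])


@functools.lru_cache(maxsize=None)
def _greedy_subset_indices(dirs_key: bytes, n_dirs: int, target: int) -> tuple:
    """Backward-eliminate directions, keeping the design best conditioned.

    Starting from all ``n_dirs`` directions, repeatedly drop the direction
    whose removal minimizes the design-matrix condition number, until
    ``target`` remain.  Ties break toward the lowest index, so the result is
    deterministic; subsets produced along the way are nested.
    """
    dirs = np.frombuffer(dirs_key, dtype=float).reshape(n_dirs, 3)
    keep = list(range(n_dirs))
    while len(keep) > target:
        conds = []
        for pos in range(len(keep)):
            trial = keep[:pos] + keep[pos + 1:]
            conds.append(_condition_number(dirs[trial]))
        best = int(np.argmin(conds))
        keep.pop(best)
    return tuple(keep)


def subset_direction_indices(base_directions: np.ndarray, n: int) -> np.ndarray:
    base = np.ascontiguousarray(np.asarray(base_directions, dtype=float))
    if n > len(base):
        raise InvalidSchemeError("cannot select more directions than available")
    if n < 6:
        raise InvalidSchemeError("tensor estimation needs at least 6 directions")
    idx = _greedy_subset_indices(base.tobytes(), len(base), n)
    return np.asarray(idx, dtype=int)


def make_protocol(name: str, base_directions=None, n_b0: int = 1) -> GradientScheme:
    """Build one of the named clinical protocols from a 20-direction set.

    ``1000/2000(40)`` is one (or ``n_b0``) b=0 plus the 20 directions at both
    b=1000 and b=2000 s/mm^2; the single-shell subsets restrict it.  The 11-
    and 6-direction subsets are chosen by deterministic backward elimination
    on the design-matrix condition number; the selected indices are recorded
    in the scheme metadata.
    """
    if name not in PROTOCOL_NAMES:
        raise InvalidSchemeError(
            f"unknown protocol {name!r}; valid names: {', '.join(PROTOCOL_NAMES)}"
        )
    if base_directions is None:
        base_directions = electrostatic_directions(20)
    dirs = np.asarray(base_directions, dtype=float)
    if dirs.shape != (20, 3):
        raise InvalidSchemeError("base_directions must be 20 unit 3-vectors")
    if np.any(np.abs(np.linalg.norm(dirs, axis=1) - 1.0) > 1e-6):
        raise InvalidSchemeError("base_directions must be unit vectors")
    if n_b0 < 1:
        raise InvalidSchemeError("at least one b=0 image is required")

    meta: dict = {"base_directions": dirs.copy(), "n_b0": n_b0}
    if name == "1000/2000(40)":
        shells = [(1000.0, np.arange(20)), (2000.0, np.arange(20))]
    elif name == "2000(20)":
        shells = [(2000.0, np.arange(20))]
    elif name == "1000(20)":
        shells = [(1000.0, np.arange(20))]
    elif name == "1000(11)":
        sel = subset_direction_indices(dirs, 11)
        meta["direction_indices"] = sel.tolist()
        shells = [(1000.0, sel)]
    else:  # "1000(6)"
        sel = subset_direction_indices(dirs, 6)
        meta["direction_indices"] = sel.tolist()
        shells = [(1000.0, sel)]

    bvals = [0.0] * n_b0
    dlist = [np.zeros(3)] * n_b0
    for b, sel in shells:
        for i in sel:
            bvals.append(b)
            dlist.append(dirs[i])
    bvals = np.asarray(bvals)
    darr = np.asarray(dlist)
    bmats = np.array([nominal_b_matrix(b, g) if b > 0 else np.zeros((3, 3))
                      for b, g in zip(bvals, darr)])
    return GradientScheme(bvals=bvals, directions=darr, bmats=bmats,
                          name=name, metadata=meta)


# --- text I/O ---------------------------------------------------------------

def read_bvals_bvecs(bval_path, bvec_path, name: str = "") -> GradientScheme:
    """Read FSL-style whitespace-separated .bval / .bvec files."""
    bvals = np.loadtxt(str(bval_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return GradientScheme.from_bvals_bvecs(bvals, bvecs, name=name)


def write_bvals_bvecs(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(str(bval_path), scheme.bvals[None, :], fmt="%g")
    np.savetxt(str(bvec_path), scheme.directions.T, fmt="%.10f")


def read_bmatrix_table(path) -> np.ndarray:
    """Read a per-DWI b-matrix table: rows 'bxx bxy bxz byy byz bzz' (s/mm^2).

    Lines starting with '#' are comments.  Returns (n, 3, 3) symmetric arrays.
    """
    rows = np.loadtxt(str(path), comments="#", ndmin=2)
    if rows.shape[1] != 6:
        raise InvalidSchemeError("b-matrix table must have 6 columns")
    bxx, bxy, bxz, byy, byz, bzz = rows.T
    b = np.zeros((len(rows), 3, 3))
    b[:, 0, 0] = bxx
    b[:, 1, 1] = byy
    b[:, 2, 2] = bzz
    b[:, 0, 1] = b[:, 1, 0] = bxy
    b[:, 0, 2] = b[:, 2, 0] = bxz
    b[:, 1, 2] = b[:, 2, 1] = byz
    return b


def write_bmatrix_table(bmats: np.ndarray, path) -> None:
    b = np.asarray(bmats, dtype=float)
    rows = np.column_stack(
        [b[:, 0, 0], b[:, 0, 1], b[:, 0, 2], b[:, 1, 1], b[:, 1, 2], b[:, 2, 2]]
    )
    header = "bxx bxy bxz byy byz bzz (s/mm^2)"
    np.savetxt(str(path), rows, fmt="%.10e", header=header)
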