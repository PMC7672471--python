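"""Affine-gap overlap alignment of two profile matrices.

Columns are compared with a paired-product correlation score and aligned
with the three-matrix (M / I_x / I_y) affine-gap dynamic program. Overlap
semantics: all first-row/first-column cells are initialised to 0, traceback
starts from the best cell on the lower-right quadrant border and continues
until the top or left edge is reached, so overhanging ends are free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


from .profiles import ProfileMatrix

__all__ = [
    "GapPenaltyConfig",
    "PairwiseAlignment",
    "column_similarity",
    "similarity_matrix",
    "gap_penalty",
    "align_overlap",
]

# traceback codes
_MAT_M, _MAT_IX, _MAT_IY = 0, 1, 2


@dataclass(frozen=True)
class GapPenaltyConfig:
    """Affine gap costs: a length-g gap scores -d - (g-1)e."""

    d: float = 100.0  # gap-open
    e: float | None = None  # gap-extension; defaults to 0.1*d

    def __post_init__(self):
        if self.e is None:
            object.__setattr__(self, "e", 0.1 * self.d)
        if self.d <= 0 or self.e <= 0:
            raise ValueError("gap penalties must be positive")
        if self.e > self.d:
            raise ValueError("gap extension penalty must not exceed gap open penalty")


def gap_penalty(g: int, cfg: GapPenaltyConfig) -> float:
    """Score of a length-``g`` gap run: -d - (g-1)e."""
    if g < 1:
        raise ValueError("gap length must be >= 1")
    return -cfg.d - (g - 1) * cfg.e


def column_similarity(x_col: np.ndarray, y_col: np.ndarray) -> float:
    """Paired-product correlation between two 2K-entry profile columns.

    With per-column deviations a_k = q_kw - qbar, b_k = q_kc - qbar (and
    likewise for the other column), the score is

        sum_k a_k b_k a'_k b'_k /
            ( sqrt(sum_k a_k^2 b_k^2) * sqrt(sum_k a'_k^2 b'_k^2) )

    where qbar is the mean over all 2K entries of the column. Bounded in
    [-1, 1] by Cauchy-Schwarz on the K-vectors of paired products. Columns
    with zero paired-product norm (including constant columns) score 0 by
    convention: empty flanks neither attract nor repel. Note that for K=1
    the score degenerates to {-1, 0, +1}; K >= 2 is the intended regime.
    """
    x = np.asarray(x_col, dtype=np.float64).reshape(-1, 1)
    y = np.asarray(y_col, dtype=np.float64).reshape(-1, 1)
    if x.shape != y.shape or x.shape[0] % 2:
        raise ValueError("columns must both have 2K entries")
    return float(similarity_matrix(x, y)[0, 0])


def similarity_matrix(x_values: np.ndarray, y_values: np.ndarray) -> np.ndarray:
    """All-pairs column similarity: (n, m) matrix for 2K x n and 2K x m inputs."""
    x = np.asarray(x_values, dtype=np.float64)
    y = np.asarray(y_values, dtype=np.float64)
    if x.shape[0] != y.shape[0] or x.shape[0] % 2:
        raise ValueError("profiles must share the same 2K row count")
    ax = x - x.mean(axis=0)
    ay = y - y.mean(axis=0)
    u = ax[0::2] * ax[1::2]  # (K, n) paired Watson*Crick deviations
    v = ay[0::2] * ay[1::2]  # (K, m)
    nu = np.sqrt((u * u).sum(axis=0))
    nv = np.sqrt((v * v).sum(axis=0))
    s = u.T @ v
    denom = np.outer(nu, nv)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, s / np.where(denom > 0, denom, 1.0), 0.0)
    return s


def _dp_fill_py(S, d, e):
    n, m = S.shape
    M = np.zeros((n + 1, m + 1))
    Ix = np.zeros((n + 1, m + 1))
    Iy = np.zeros((n + 1, m + 1))
    PM = np.zeros((n + 1, m + 1), dtype=np.int8)
    PX = np.zeros((n + 1, m + 1), dtype=np.int8)
    PY = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best, ptr = M[i - 1, j - 1], _MAT_M
            if Ix[i - 1, j - 1] > best:
                best, ptr = Ix[i - 1, j - 1], _MAT_IX
            if Iy[i - 1, j - 1] > best:
                best, ptr = Iy[i - 1, j - 1], _MAT_IY
            M[i, j] = best + S[i - 1, j - 1]
            PM[i, j] = ptr
            a, b = M[i - 1, j] - d, Ix[i - 1, j] - e
            if a >= b:
                Ix[i, j], PX[i, j] = a, _MAT_M
            else:
                Ix[i, j], PX[i, j] = b, _MAT_IX
            a, b = M[i, j - 1] - d, Iy[i, j - 1] - e
            if a >= b:
                Iy[i, j], PY[i, j] = a, _MAT_M
            else:
                Iy[i, j], PY[i, j] = b, _MAT_IY
    return M, Ix, Iy, PM, PX, PY


if _HAVE_NUMBA:
    _dp_fill = njit(cache=False)(_dp_fill_py)
else:  # pragma: no cover
    _dp_fill = _dp_fill_py


@dataclass
class PairwiseAlignment:
    """Result of an overlap alignment of X (n columns) against Y (m columns).

    ``steps`` is the traceback path in forward order, each step one of
    ``("M", i, j)`` (x_i matched to y_j), ``("X", i)`` (x_i over a gap) or
    ``("Y", j)`` (y_j inserted); i, j are 1-based column indices. ``start``
    is the (i, j) cell where traceback reached the top/left edge (the
    columns before it are free overhang); ``end`` is the traceback start
    cell on the border (columns after it are free overhang).
    """

    score: float
    steps: list[tuple]
    start: tuple[int, int]
    end: tuple[int, int]
    n: int
    m: int
    orientation: str = "+"  # '+' if Y aligned as given, '-' if reversed

    def aligned_columns(self) -> list[tuple[int | None, int | None]]:
        """Merged column layout: 0-based (x_col | None, y_col | None) per
        output column, including the free overhangs at both ends."""
        cols: list[tuple[int | None, int | None]] = []
        i0, j0 = self.start
        for i in range(1, i0 + 1):
            cols.append((i - 1, None))
        for j in range(1, j0 + 1):
            cols.append((None, j - 1))
        for step in self.steps:
            if step[0] == "M":
                cols.append((step[1] - 1, step[2] - 1))
            elif step[0] == "X":
                cols.append((step[1] - 1, None))
            else:
                cols.append((None, step[1] - 1))
        i1, j1 = self.end
        for i in range(i1 + 1, self.n + 1):
            cols.append((i - 1, None))
        for j in range(j1 + 1, self.m + 1):
            cols.append((None, j - 1))
        return cols

    def x_map(self) -> np.ndarray:
        """0-based x column -> merged output column."""
        out = np.full(self.n, -1, dtype=np.int64)
        for c, (xi, _) in enumerate(self.aligned_columns()):
            if xi is not None:
                out[xi] = c
        return out

    def y_map(self) -> np.ndarray:
        out = np.full(self.m, -1, dtype=np.int64)
        for c, (_, yj) in enumerate(self.aligned_columns()):
            if yj is not None:
                out[yj] = c
        return out

    def n_gap_columns(self) -> int:
        return sum(1 for s in self.steps if s[0] != "M")


def _border_cells(n: int, m: int):
    """Cells on the lower-right quadrant border: (n, j) for j >= ceil(m/2)
    and (i, m) for i >= ceil(n/2)."""
    for j in range((m + 1) // 2, m + 1):
        yield n, j
    for i in range((n + 1) // 2, n + 1):
        if (i, m) != (n, m):  # (n, m) already yielded above
            yield i, m


def _align_one(S: np.ndarray, cfg: GapPenaltyConfig) -> tuple[float, list, tuple, tuple]:
    n, m = S.shape
    M, Ix, Iy, PM, PX, PY = _dp_fill(np.ascontiguousarray(S, dtype=np.float64),
                                     float(cfg.d), float(cfg.e))
    mats = (M, Ix, Iy)
    best = None  # (score, overlap, -mat_priority, mat, i, j)
    for i, j in _border_cells(n, m):
        for mat in (_MAT_M, _MAT_IX, _MAT_IY):
            key = (mats[mat][i, j], i + j, -mat)
            if best is None or key > best[:3]:
                best = key + (mat, i, j)
    score, _, _, mat, i, j = best
    end = (i, j)
    steps: list[tuple] = []
    while i > 0 and j > 0:
        if mat == _MAT_M:
            steps.append(("M", i, j))
            mat = PM[i, j]
            i, j = i - 1, j - 1
        elif mat == _MAT_IX:
            steps.append(("X", i))
            mat = PX[i, j]
            i -= 1
        else:
            steps.append(("Y", j))
            mat = PY[i, j]
            j -= 1
    steps.reverse()
    return float(score), steps, (i, j), end


def align_overlap(
    X: ProfileMatrix, Y: ProfileMatrix, cfg: GapPenaltyConfig, try_reverse: bool = True
) -> PairwiseAlignment:
    """Best-scoring affine-gap overlap alignment of Y against X.

    Both orientations of Y are scored (Y column-reversed with strand rows
    swapped) and the higher-scoring one is returned; ties prefer the
    forward orientation.
    """
    if X.K != Y.K:
        raise ValueError(f"experiment count mismatch: {X.K} vs {Y.K}")
    if X.experiments != Y.experiments:
        raise ValueError("profiles must share the same experiment order")
    S = similarity_matrix(X.values, Y.values)
    fwd = _align_one(S, cfg)
    if try_reverse:
        S_rev = similarity_matrix(X.values, Y.reversed().values)
        rev = _align_one(S_rev, cfg)
        if rev[0] > fwd[0]:
            score, steps, start, end = rev
            return PairwiseAlignment(score, steps, start, end, X.L, Y.L, orientation="-")
    score, steps, start, end = fwd
    return PairwiseAlignment(score, steps, start, end, X.L, Y.L, orientation="+")
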