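"""Independent reference implementations used as test oracles.

These deliberately avoid the package's vectorised/DP code paths: the
similarity oracle is a literal per-k transliteration of the scoring
formula, and the alignment oracle exhaustively enumerates monotone
alignment paths with affine gap costs and overlap (free overhang)
semantics.
"""

from __future__ import annotations

import math


def direct_similarity(x_col, y_col) -> float:
    """Literal evaluation of the paired-product correlation formula."""
    x = list(map(float, x_col))
    y = list(map(float, y_col))
    K = len(x) // 2
    qbar = sum(x) / (2 * K)
    pbar = sum(y) / (2 * K)
    num = 0.0
    dx = 0.0
    dy = 0.0
    for k in range(K):
        qw, qc = x[2 * k], x[2 * k + 1]
        pw, pc = y[2 * k], y[2 * k + 1]
        num += (qw - qbar) * (qc - qbar) * (pw - pbar) * (pc - pbar)
        dx += (qw - qbar) ** 2 * (qc - qbar) ** 2
        dy += (pw - pbar) ** 2 * (pc - pbar) ** 2
    denom = math.sqrt(dx) * math.sqrt(dy)
    if denom == 0.0:
        return 0.0
    return num / denom


def brute_force_overlap(S, d: float, e: float) -> float:
    """Max score over all overlap alignments of an n x m similarity matrix.

    Path semantics mirrored from the alignment definition, independently of
    the three-matrix DP:

    * a path starts on the top or left edge (the unconsumed prefix of the
      other profile is free) and may stop at any cell on the lower-right
      quadrant border ((n, j) with j >= ceil(m/2), or (i, m) with
      i >= ceil(n/2)); the unconsumed suffix is free;
    * steps are matches (score S[i, j]), gaps in x ("X": x column against a
      gap) or insertions in y ("Y"); a gap run of length g scores
      -d - (g-1)e, except a run that opens the path at the edge, which
      scores -g*e (the zero-initialised boundary never charges the open
      penalty, only extensions);
    * opposite gap runs are never adjacent (runs must be separated by a
      match), matching the absence of I_x <-> I_y transitions.

    Exhaustive: only usable for small n, m.
    """
    n, m = len(S), len(S[0]) if len(S) else 0
    jmin = (m + 1) // 2
    imin = (n + 1) // 2
    best = -math.inf

    starts = [(0, j) for j in range(m + 1)] + [(i, 0) for i in range(1, n + 1)]
    # DFS over (i, j, last_step, score); last_step in {None, "M", "X", "Y"}
    for start in starts:
        stack = [(start[0], start[1], None, 0.0)]
        while stack:
            i, j, last, score = stack.pop()
            if (i == n and j >= jmin) or (j == m and i >= imin):
                if score > best:
                    best = score
            if i < n and j < m:
                stack.append((i + 1, j + 1, "M", score + S[i][j]))
            if i < n and last != "Y":
                cost = e if last in ("X", None) else d
                stack.append((i + 1, j, "X", score - cost))
            if j < m and last != "X":
                cost = e if last in ("Y", None) else d
                stack.append((i, j + 1, "Y", score - cost))
    return best
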