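"""PCA summary of crosslinking relationships between experiments."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .deconvolve import CrosslinkMatrix

__all__ = ["PcaResult", "pca_crosslinks"]


@dataclass
class PcaResult:
    experiments: list[str]
    coordinates: np.ndarray  # (K, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (n_components, J)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.experiments, columns=cols)


def pca_crosslinks(m: CrosslinkMatrix, n_components: int = 2) -> PcaResult:
    """Standard PCA of the row-normalised crosslink strength matrix.

    Rows (experiments) are the samples; the matrix is mean-centred but not
    variance-scaled. PC signs are oriented so the first experiment has a
    non-negative coordinate on every component, making output deterministic
    up to that convention. A degenerate matrix (identical rows) yields
    all-zero coordinates and explained ratios.
    """
    X = np.asarray(m.normalized, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 experiments")
    max_comp = min(X.shape[0], X.shape[1])
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} clipped to {max_comp}", RuntimeWarning, stacklevel=2
        )
        n_components = max_comp
    centred = X - X.mean(axis=0)
    if not np.any(np.abs(centred) > 1e-12):
        zeros = np.zeros((X.shape[0], n_components))
        return PcaResult(list(m.experiments), zeros, np.zeros(n_components),
                         np.zeros((n_components, X.shape[1])))
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_
    for c in range(coords.shape[1]):
        ref = coords[0, c]
        if ref < 0 or (ref == 0 and coords[:, c].sum() < 0):
            coords[:, c] *= -1
            loadings[c] *= -1
    ratio = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    return PcaResult(list(m.experiments), coords, ratio, loadings)
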