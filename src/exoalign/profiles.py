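"""Multi-experiment profile matrices.

A profile matrix stacks the strand-separated per-base tag counts of K
experiments over a length-L window into a 2K x L array. Rows are ordered
experiment-major: row 2k is experiment k's + strand, row 2k+1 its - strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tagio import Region, TagLibrary, extract_window

__all__ = ["ProfileMatrix", "build_profile", "normalize_per_region"]


@dataclass
class ProfileMatrix:
    values: np.ndarray  # (2K, L), non-negative
    experiments: list[str]
    region_ids: list[str]
    gap_mask: np.ndarray | None = None  # (L,) bool; True where every region is gapped
    is_normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != 2 * len(self.experiments):
            raise ValueError(
                f"profile must be 2K x L with K={len(self.experiments)}; got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.values.shape[1], dtype=bool)

    @property
    def K(self) -> int:
        return len(self.experiments)

    @property
    def L(self) -> int:
        return self.values.shape[1]

    def total(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "ProfileMatrix":
        return replace(self, values=self.values.copy(), gap_mask=self.gap_mask.copy(),
                       experiments=list(self.experiments), region_ids=list(self.region_ids))

    def reversed(self) -> "ProfileMatrix":
        """Column-reversed profile with +/- rows swapped within each experiment
        (the profile as read from the opposite strand)."""
        idx = np.arange(2 * self.K)
        swap = idx ^ 1  # 0<->1, 2<->3, ...
        out = self.copy()
        out.values = self.values[swap][:, ::-1].copy()
        out.gap_mask = self.gap_mask[::-1].copy()
        return out

    def experiment_rows(self, k: int) -> np.ndarray:
        return self.values[2 * k : 2 * k + 2]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (experiment, strand, offset, count)."""
        rows = []
        for k, name in enumerate(self.experiments):
            for s, strand in enumerate("+-"):
                v = self.values[2 * k + s]
                rows.append(pd.DataFrame({
                    "experiment": name, "strand": strand,
                    "offset": np.arange(self.L), "count": v,
                }))
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_profile(
    libraries: dict[str, TagLibrary] | list[TagLibrary], region: Region, L: int
) -> ProfileMatrix:
    """Stack per-experiment window extractions into one raw 2K x L matrix."""
    if isinstance(libraries, dict):
        items = list(libraries.items())
    else:
        items = [(lib.name, lib) for lib in libraries]
    if not items:
        raise ValueError("need at least one experiment")
    blocks = [extract_window(lib, region, L) for _, lib in items]
    return ProfileMatrix(
        values=np.vstack(blocks),
        experiments=[name for name, _ in items],
        region_ids=[region.id],
    )


def normalize_per_region(p: ProfileMatrix) -> ProfileMatrix:
    """Divide each experiment's pair of strand rows by that experiment's
    maximum cell value in this region (both strands jointly). Experiments
    with no signal are left at zero. Idempotent."""
    out = p.copy()
    for k in range(p.K):
        block = out.values[2 * k : 2 * k + 2]
        mx = block.max()
        if mx > 0:
            block /= mx
    out.is_normalized = True
    return out
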