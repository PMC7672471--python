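"""Progressive multiple alignment of region profiles and background subtraction.

Regions start as single-profile nodes. The most similar pair of nodes (by
overlap-alignment score of their per-experiment max-normalised composites)
is aligned and merged into a composite; similarities against the merged
node are recomputed and the process repeats until one node remains. Gap
columns are tracked in a one-dimensional array alongside the composite.
After the final alignment is built, scaled control tag counts can be
projected through the per-region coordinate maps and subtracted from the
composite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align_pair import GapPenaltyConfig, PairwiseAlignment, align_overlap
from .profiles import ProfileMatrix, normalize_per_region
from .tagio import Region, RegionSet, TagLibrary, extract_window

__all__ = [
    "MultipleAlignment",
    "ControlScaling",
    "progressive_align",
    "merge_pair",
    "estimate_control_scale",
    "subtract_background",
]

log = logging.getLogger(__name__)


@dataclass
class ControlScaling:
    scale_factor: float
    method: str = "low-bin-median"

    def __post_init__(self):
        if not np.isfinite(self.scale_factor) or self.scale_factor <= 0:
            raise ValueError("control scale factor must be finite and positive")


@dataclass
class _Node:
    """One agglomeration node: raw composite plus per-region bookkeeping."""

    raw: ProfileMatrix
    gap_counts: np.ndarray  # (L,) number of member regions gapped at each column
    maps: dict[str, np.ndarray]  # region id -> window offset -> composite column
    orientations: dict[str, str]  # region id -> '+' / '-' relative to input window
    order: list[str]  # leaf order, left to right
    key: int  # smallest original region index, for deterministic tie-breaks
    newick: str

    @property
    def n_regions(self) -> int:
        return len(self.maps)

    def normalized(self) -> ProfileMatrix:
        return normalize_per_region(self.raw)

    def flipped(self) -> "_Node":
        L = self.raw.L
        return _Node(
            raw=self.raw.reversed(),
            gap_counts=self.gap_counts[::-1].copy(),
            maps={r: (L - 1 - m) for r, m in self.maps.items()},
            orientations={r: ("-" if o == "+" else "+") for r, o in self.orientations.items()},
            order=list(reversed(self.order)),
            key=self.key,
            newick=self.newick,
        )


@dataclass
class MultipleAlignment:
    composite: ProfileMatrix  # raw (background-correctable) tag counts
    gap_counts: np.ndarray
    region_maps: dict[str, np.ndarray]
    orientations: dict[str, str]
    region_order: list[str]
    merge_tree: str  # Newick
    window_size: int
    background_subtracted: bool = False

    @property
    def n_regions(self) -> int:
        return len(self.region_maps)

    def region_columns(self, region_id: str) -> np.ndarray:
        return self.region_maps[region_id]


def merge_pair(a: "_Node | ProfileMatrix", b: "_Node | ProfileMatrix",
               aln: PairwiseAlignment) -> _Node:
    """Merge two aligned nodes into a composite per the gapped alignment.

    Matched columns are summed cell-wise in raw counts; at gap columns the
    present node's counts are carried over and every absent-node region is
    counted in the gap array; overhangs are retained.
    """
    if not isinstance(a, _Node):
        a = _leaf_node(a, 0)
    if not isinstance(b, _Node):
        b = _leaf_node(b, 1)
    if aln.orientation == "-":
        b = b.flipped()
    cols = aln.aligned_columns()
    L = len(cols)
    K2 = a.raw.values.shape[0]
    values = np.zeros((K2, L))
    gaps = np.zeros(L, dtype=np.int64)
    a_to_new = np.full(a.raw.L, -1, dtype=np.int64)
    b_to_new = np.full(b.raw.L, -1, dtype=np.int64)
    for c, (ai, bj) in enumerate(cols):
        if ai is not None:
            values[:, c] += a.raw.values[:, ai]
            gaps[c] += a.gap_counts[ai]
            a_to_new[ai] = c
        else:
            gaps[c] += a.n_regions
        if bj is not None:
            values[:, c] += b.raw.values[:, bj]
            gaps[c] += b.gap_counts[bj]
            b_to_new[bj] = c
        else:
            gaps[c] += b.n_regions
    maps = {r: a_to_new[m] for r, m in a.maps.items()}
    maps.update({r: b_to_new[m] for r, m in b.maps.items()})
    composite = ProfileMatrix(
        values=values,
        experiments=list(a.raw.experiments),
        region_ids=a.raw.region_ids + b.raw.region_ids,
        gap_mask=gaps >= (a.n_regions + b.n_regions),
    )
    return _Node(
        raw=composite,
        gap_counts=gaps,
        maps=maps,
        orientations={**a.orientations, **b.orientations},
        order=a.order + b.order,
        key=min(a.key, b.key),
        newick=f"({a.newick},{b.newick})",
    )


def _leaf_node(p: ProfileMatrix, index: int) -> _Node:
    rid = p.region_ids[0]
    return _Node(
        raw=p.copy(),
        gap_counts=np.zeros(p.L, dtype=np.int64),
        maps={rid: np.arange(p.L, dtype=np.int64)},
        orientations={rid: "+"},
        order=[rid],
        key=index,
        newick=str(rid).replace("(", "_").replace(")", "_").replace(",", "_"),
    )


def progressive_align(
    profiles: list[ProfileMatrix], cfg: GapPenaltyConfig | None = None
) -> MultipleAlignment:
    """Greedy agglomerative multiple alignment of raw region profiles.

    Similarity between nodes is the overlap-alignment score of their
    re-normalised composites; the most similar pair is merged first, then
    similarities against the merged node are recomputed. Ties are broken by
    the lexicographically smallest pair of node keys, so reruns are
    deterministic.
    """
    if len(profiles) < 2:
        raise ValueError("progressive alignment needs at least 2 regions")
    cfg = cfg or GapPenaltyConfig()
    window_size = profiles[0].L
    nodes: dict[int, _Node] = {i: _leaf_node(p, i) for i, p in enumerate(profiles)}
    norm: dict[int, ProfileMatrix] = {i: n.normalized() for i, n in nodes.items()}
    cache: dict[tuple[int, int], PairwiseAlignment] = {}

    def pair_aln(i: int, j: int) -> PairwiseAlignment:
        if (i, j) not in cache:
            cache[(i, j)] = align_overlap(norm[i], norm[j], cfg)
        return cache[(i, j)]

    ids = sorted(nodes)
    for i_idx in range(len(ids)):
        for j_idx in range(i_idx + 1, len(ids)):
            pair_aln(ids[i_idx], ids[j_idx])

    next_id = max(nodes) + 1
    while len(nodes) > 1:
        live = sorted(nodes)
        best = None  # (score, -keyA, -keyB) maximised
        for x in range(len(live)):
            for y in range(x + 1, len(live)):
                i, j = live[x], live[y]
                a = pair_aln(i, j)
                ka, kb = sorted((nodes[i].key, nodes[j].key))
                cand = (a.score, -ka, -kb, i, j)
                if best is None or cand[:3] > best[:3]:
                    best = cand
        _, _, _, i, j = best
        merged = merge_pair(nodes[i], nodes[j], cache[(i, j)])
        for k in (i, j):
            del nodes[k]
            del norm[k]
        cache = {key: v for key, v in cache.items() if i not in key and j not in key}
        nodes[next_id] = merged
        norm[next_id] = merged.normalized()
        for other in sorted(nodes):
            if other != next_id:
                pair_aln(min(other, next_id), max(other, next_id))
        next_id += 1

    root = nodes.popitem()[1]
    return MultipleAlignment(
        composite=root.raw,
        gap_counts=root.gap_counts,
        region_maps=root.maps,
        orientations=root.orientations,
        region_order=root.order,
        merge_tree=root.newick + ";",
        window_size=window_size,
    )


def estimate_control_scale(
    signal: TagLibrary, control: TagLibrary, bin_size: int = 10_000
) -> ControlScaling:
    """Simplified control-to-signal scaling.

    The genome is binned; among bins whose signal+control total is below the
    genome-wide median of totals (the background-dominated bins), the scale
    is the median of per-bin signal/control ratios. Falls back to the total
    count ratio when no usable bins exist.
    """
    if control.total_tag_count == 0:
        raise ValueError("control library is empty; skip background subtraction instead")
    chroms = set(signal.tags) | set(control.tags)
    sig_bins, ctl_bins = [], []
    for chrom in sorted(chroms):
        sp, sm = signal.chrom_tags(chrom)
        cp, cm = control.chrom_tags(chrom)
        s_all = np.concatenate([sp, sm])
        c_all = np.concatenate([cp, cm])
        hi = int(max(s_all.max(initial=0), c_all.max(initial=0)))
        if hi == 0:
            continue
        nbins = hi // bin_size + 1
        sig_bins.append(np.bincount(s_all // bin_size, minlength=nbins))
        ctl_bins.append(np.bincount(c_all // bin_size, minlength=nbins))
    sig = np.concatenate(sig_bins) if sig_bins else np.zeros(0)
    ctl = np.concatenate(ctl_bins) if ctl_bins else np.zeros(0)
    totals = sig + ctl
    occupied = totals > 0
    usable = np.zeros_like(occupied)
    if occupied.any():
        med = np.median(totals[occupied])
        usable = occupied & (totals < med) & (ctl > 0)
    if usable.sum() >= 3:
        scale = float(np.median(sig[usable] / ctl[usable]))
        method = "low-bin-median"
    else:
        scale = signal.total_tag_count / control.total_tag_count
        method = "total-ratio"
    if scale <= 0:  # all low bins empty of signal; fall back rather than zero out
        scale = signal.total_tag_count / control.total_tag_count
        method = "total-ratio"
    return ControlScaling(scale_factor=scale, method=method)


def project_library(
    ma: MultipleAlignment, library: TagLibrary, regions: RegionSet
) -> np.ndarray:
    """Project a tag library into alignment space through the per-region
    coordinate maps, honouring each region's alignment orientation.
    Returns a (2, L_alignment) strand-separated count array."""
    L_aln = ma.composite.L
    out = np.zeros((2, L_aln))
    by_id = {r.id: r for r in regions}
    for rid, cmap in ma.region_maps.items():
        region = by_id[rid]
        win = extract_window(library, region, ma.window_size)
        if ma.orientations[rid] == "-":
            # the coordinate map already encodes the positional flip; only
            # the strand identity swaps for flipped regions
            win = win[::-1]
        np.add.at(out[0], cmap, win[0])
        np.add.at(out[1], cmap, win[1])
    return out


def subtract_background(
    ma: MultipleAlignment,
    control: TagLibrary | None,
    scaling: dict[str, ControlScaling] | ControlScaling | float | None,
    regions: RegionSet,
) -> MultipleAlignment:
    """Subtract scaled, alignment-projected control counts from each signal
    experiment of the final composite, flooring at zero. With no control the
    alignment is returned unchanged (logged)."""
    if control is None:
        log.info("no control experiment supplied; background subtraction skipped")
        return ma
    ctrl = project_library(ma, control, regions)
    values = ma.composite.values.copy()
    for k, name in enumerate(ma.composite.experiments):
        if isinstance(scaling, dict):
            sc = scaling[name].scale_factor
        elif isinstance(scaling, ControlScaling):
            sc = scaling.scale_factor
        else:
            sc = float(scaling if scaling is not None else 1.0)
        block = values[2 * k : 2 * k + 2]
        np.maximum(block - sc * ctrl, 0.0, out=block)
    composite = ProfileMatrix(
        values=values,
        experiments=list(ma.composite.experiments),
        region_ids=list(ma.composite.region_ids),
        gap_mask=ma.composite.gap_mask.copy(),
    )
    return MultipleAlignment(
        composite=composite,
        gap_counts=ma.gap_counts.copy(),
        region_maps=ma.region_maps,
        orientations=ma.orientations,
        region_order=list(ma.region_order),
        merge_tree=ma.merge_tree,
        window_size=ma.window_size,
        background_subtracted=True,
    )
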