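"""Synthetic multi-experiment tag datasets with known truth.

Regions on a toy chromosome all carry the same layout of crosslink sites,
split into sub-blocks separated by a region-specific spacer; tags are drawn
from the paired-Gaussian tag model (sigma = 6 bp, strands offset 12 bp)
plus uniform background. Anchors can be jittered and whole regions can be
planted in reverse orientation, so alignment, orientation and spacer
recovery are all testable against recorded truth.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .deconvolve import TagDistributionModel
from .tagio import Region, RegionSet, TagLibrary, write_tags_sam, write_tags_tsv

__all__ = ["SyntheticTruth", "generate", "sample_composite", "write_bundle"]


@dataclass
class SyntheticTruth:
    experiments: list[str]
    n_regions: int = 10
    window: int = 240
    # canonical layout: per-site offset from layout start, and block index;
    # a region's spacer is inserted once per block boundary crossed
    site_offsets: list[int] = field(default_factory=lambda: [60, 100])
    site_blocks: list[int] = field(default_factory=lambda: [0, 1])
    strengths: list[list[float]] | None = None  # (K, J) rows sum to 1
    tags_per_region: int = 600  # per experiment, split across sites by strengths
    spacer_range: tuple[int, int] = (0, 0)  # inclusive; 0 disables spacers
    spacers: list[int] | None = None  # explicit per-region override
    reversed_fraction: float = 0.0
    orientations: list[str] | None = None  # explicit '+'/'-' per region
    jitter: int = 0  # max |anchor shift| in bp
    background_rate: float = 0.0  # window background, tags/bp/experiment
    control_rate: float = 0.0  # control window background, tags/bp
    genome_background_rate: float = 0.0  # chromosome-wide, tags/bp (signal)
    control_genome_rate: float = 0.0  # chromosome-wide, tags/bp (control)
    chrom: str = "chrS"
    region_spacing: int = 4000
    margin: int = 2000
    seed: int = 0
    sigma: float = 6.0
    strand_offset: float = 12.0
    # Reuse one canonical tag cloud per experiment for every region, so
    # regions differ only by the planted spacer / jitter / orientation.
    # With independently sampled clouds the planted offsets are not exactly
    # optimal for the sampled data, so exact-recovery tests need this mode.
    shared_noise: bool = False

    @property
    def J(self) -> int:
        return len(self.site_offsets)

    @property
    def K(self) -> int:
        return len(self.experiments)

    def resolved_strengths(self) -> np.ndarray:
        if self.strengths is None:
            s = np.full((self.K, self.J), 1.0 / self.J)
        else:
            s = np.asarray(self.strengths, dtype=np.float64)
        if s.shape != (self.K, self.J):
            raise ValueError(f"strengths must be (K={self.K}, J={self.J})")
        if not np.allclose(s.sum(axis=1), 1.0):
            raise ValueError("per-protein site strengths must sum to 1")
        return s


def _draw_site_tags(rng, n, site, sigma, half_offset):
    """n tag (position, strand) draws around one site; strand is fair."""
    strands = rng.integers(0, 2, size=n)
    shift = np.where(strands == 0, -half_offset, half_offset)
    pos = np.rint(rng.normal(site + shift, sigma)).astype(np.int64)
    return pos, strands


def generate(truth: SyntheticTruth):
    """Build per-experiment tag libraries, a region set and a truth record.

    Deterministic for a fixed seed. Regions are given to the pipeline with
    '+' strand; planted reversals live in the tag content only (mirrored
    about the anchor with strands flipped) so the aligner must discover
    them. Raises if region windows would overlap on the toy chromosome.
    """
    rng = np.random.default_rng(truth.seed)
    R, L, J = truth.n_regions, truth.window, truth.J
    strengths = truth.resolved_strengths()
    offs = np.asarray(truth.site_offsets, dtype=np.int64)
    blocks = np.asarray(truth.site_blocks, dtype=np.int64)
    if len(blocks) != J:
        raise ValueError("site_blocks must parallel site_offsets")

    if truth.spacers is not None:
        spacers = list(truth.spacers)
    elif truth.spacer_range[1] > 0:
        lo, hi = truth.spacer_range
        spacers = [int(v) for v in rng.integers(lo, hi + 1, size=R)]
    else:
        spacers = [0] * R
    if truth.orientations is not None:
        orients = list(truth.orientations)
    else:
        orients = ["-" if v else "+" for v in rng.random(R) < truth.reversed_fraction]
    jitters = (
        [int(v) for v in rng.integers(-truth.jitter, truth.jitter + 1, size=R)]
        if truth.jitter
        else [0] * R
    )
    max_layout = int(offs.max() + blocks.max() * max([0, *spacers]))
    if truth.region_spacing < L + 2 * truth.jitter + 1:
        raise ValueError("regions would overlap: increase region_spacing")
    if max_layout + 2 * truth.jitter + 40 > L:
        raise ValueError("window too small for the site layout plus jitter")

    chrom_len = truth.margin * 2 + R * truth.region_spacing
    half = truth.strand_offset / 2.0
    clouds = None
    if truth.shared_noise:
        clouds = {}
        for k, name in enumerate(truth.experiments):
            counts = np.rint(truth.tags_per_region * strengths[k]).astype(int)
            clouds[name] = [
                _draw_site_tags(rng, counts[j], 0, truth.sigma, half) for j in range(J)
            ]
    regions: list[Region] = []
    site_positions = np.zeros((R, J), dtype=np.int64)
    site_window_offsets = np.zeros((R, J), dtype=np.int64)
    tag_buffers: dict[str, tuple[list, list]] = {name: ([], []) for name in truth.experiments}
    tag_buffers["__control__"] = ([], [])

    for r in range(R):
        base = truth.margin + r * truth.region_spacing
        sites = base + offs + blocks * spacers[r]
        centre = int(round((sites.min() + sites.max()) / 2))
        anchor = centre + jitters[r]
        win_start = anchor - L // 2
        rid = f"region{r:03d}"
        regions.append(Region(chrom=truth.chrom, anchor=anchor, strand="+", id=rid))

        mirrored = orients[r] == "-"
        for k, name in enumerate(truth.experiments):
            counts = np.rint(truth.tags_per_region * strengths[k]).astype(int)
            for j in range(J):
                if clouds is not None:
                    rel, strands = clouds[name][j]
                    pos = rel + sites[j]
                else:
                    pos, strands = _draw_site_tags(rng, counts[j], sites[j], truth.sigma, half)
                if mirrored:
                    pos = 2 * anchor - pos
                    strands = 1 - strands
                _push(tag_buffers[name], pos, strands)
            if truth.background_rate > 0:
                nb = rng.poisson(truth.background_rate * L)
                pos = rng.integers(win_start, win_start + L, size=nb)
                _push(tag_buffers[name], pos, rng.integers(0, 2, size=nb))
        if truth.control_rate > 0:
            nb = rng.poisson(truth.control_rate * L)
            pos = rng.integers(win_start, win_start + L, size=nb)
            _push(tag_buffers["__control__"], pos, rng.integers(0, 2, size=nb))

        if mirrored:
            site_positions[r] = 2 * anchor - sites
        else:
            site_positions[r] = sites
        # offsets of the (canonical-orientation) sites within the extracted
        # '+' strand window; for mirrored regions these are the mirrored spots
        site_window_offsets[r] = site_positions[r] - win_start

    for name, rate in [(n, truth.genome_background_rate) for n in truth.experiments] + [
        ("__control__", truth.control_genome_rate)
    ]:
        if rate > 0:
            nb = rng.poisson(rate * chrom_len)
            pos = rng.integers(1, chrom_len + 1, size=nb)
            _push(tag_buffers[name], pos, rng.integers(0, 2, size=nb))

    libraries: dict[str, TagLibrary] = {}
    for name in truth.experiments:
        libraries[name] = _to_library(name, truth.chrom, chrom_len, tag_buffers[name])
    control = None
    cp, cm = tag_buffers["__control__"]
    if cp or cm:
        control = _to_library("control", truth.chrom, chrom_len, tag_buffers["__control__"])

    record = {
        "experiments": truth.experiments,
        "spacers": spacers,
        "orientations": orients,
        "jitters": jitters,
        "anchors": [r.anchor for r in regions],
        "site_positions": site_positions.tolist(),
        "site_window_offsets": site_window_offsets.tolist(),
        "strengths": strengths.tolist(),
        "window": L,
        "chrom_length": chrom_len,
        "seed": truth.seed,
    }
    return libraries, control, RegionSet(regions=regions, window_size=L), record


def _push(buffer, pos, strands):
    pos = np.asarray(pos)
    strands = np.asarray(strands)
    buffer[0].extend(pos[strands == 0].tolist())
    buffer[1].extend(pos[strands == 1].tolist())


def _to_library(name, chrom, chrom_len, buffer) -> TagLibrary:
    plus = np.clip(np.asarray(buffer[0], dtype=np.int64), 1, chrom_len)
    minus = np.clip(np.asarray(buffer[1], dtype=np.int64), 1, chrom_len)
    lib = TagLibrary(name=name, chrom_lengths={chrom: chrom_len})
    lib.add(chrom, plus, minus)
    return lib


def sample_composite(
    rng: np.random.Generator,
    L: int,
    mus: list[int],
    strengths: np.ndarray | list[float],
    n_tags: int,
    model: TagDistributionModel | None = None,
    background_rate: float = 0.0,
) -> np.ndarray:
    """Draw a (2, L) strand-separated tag-count array for one experiment
    directly in alignment space: ``n_tags`` tags split over the sites in
    ``mus`` by ``strengths``, plus uniform background. Used to test the
    deconvolution stage in isolation."""
    model = model or TagDistributionModel()
    strengths = np.asarray(strengths, dtype=np.float64)
    out = np.zeros((2, L))
    counts = rng.multinomial(n_tags, strengths / strengths.sum())
    half = model.strand_offset / 2.0
    for mu, n in zip(mus, counts):
        pos, strands = _draw_site_tags(rng, n, mu, model.sigma, half)
        pos = np.clip(pos, 0, L - 1)
        np.add.at(out[0], pos[strands == 0], 1.0)
        np.add.at(out[1], pos[strands == 1], 1.0)
    if background_rate > 0:
        nb = rng.poisson(background_rate * L)
        pos = rng.integers(0, L, size=nb)
        strands = rng.integers(0, 2, size=nb)
        np.add.at(out[0], pos[strands == 0], 1.0)
        np.add.at(out[1], pos[strands == 1], 1.0)
    return out


def write_bundle(
    out_dir: str | os.PathLike,
    libraries: dict[str, TagLibrary],
    control: TagLibrary | None,
    regions: RegionSet,
    record: dict,
    fmt: str = "sam",
) -> dict[str, str]:
    """Write a generated dataset as mapped-read SAM (or tag TSV) files, a
    BED region list and a truth JSON. Returns the paths written."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    chrom = regions.regions[0].chrom
    chrom_lengths = {chrom: record["chrom_length"]}
    paths: dict[str, str] = {}
    for name, lib in list(libraries.items()) + ([("control", control)] if control else []):
        if fmt == "sam":
            path = os.path.join(out_dir, f"{name}.sam")
            write_tags_sam(lib, path, chrom_lengths)
        else:
            path = os.path.join(out_dir, f"{name}.tags.tsv")
            write_tags_tsv(lib, path)
        paths[name] = path
    bed = os.path.join(out_dir, "regions.bed")
    L = regions.window_size
    with open(bed, "w") as fh:
        for region in regions:
            start0 = region.anchor - L // 2 - 1  # 0-based window start
            fh.write(f"{region.chrom}\t{start0}\t{start0 + L}\t{region.id}\t0\t{region.strand}\n")
    paths["regions"] = bed
    truth_path = os.path.join(out_dir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
    paths["truth"] = truth_path
    return paths
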