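"""End-to-end orchestration: profiles -> multiple alignment -> background
subtraction -> EM deconvolution -> quantification -> PCA."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .align_multi import (
    ControlScaling,
    estimate_control_scale,
    progressive_align,
    subtract_background,
)
from .align_pair import GapPenaltyConfig
from .analyze import pca_crosslinks
from .deconvolve import EMConfig, TagDistributionModel, em_fit, quantify
from .profiles import build_profile
from .tagio import TagLibrary, read_regions, read_tags

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    experiments: dict[str, str]  # name -> tag file path
    regions_path: str
    out_dir: str
    control_path: str | None = None
    window: int = 1400
    gap_open: float = 100.0
    gap_ext: float | None = None  # default 0.1 * gap_open
    alpha: float | None = None  # absolute; None -> alpha_frac of tags/expt
    alpha_frac: float = 0.01
    sigma: float = 6.0
    strand_offset: float = 12.0
    init_spacing: int = 5
    mu_search_halfwidth: int = 50
    min_mapq: int = 5
    ctrl_scale: float | None = None  # override estimated control scaling
    subtract: bool = True
    seed: int = 1
    n_pca_components: int = 2
    deconvolve: bool = True  # False: stop after alignment + subtraction

    def __post_init__(self):
        if not self.experiments:
            raise ValueError("at least one experiment is required")
        if self.window < 2 * self.mu_search_halfwidth:
            raise ValueError("window must be at least twice the position search halfwidth")


def run(config: RunConfig) -> dict[str, str]:
    """Run the full pipeline; returns the map of artifact names to paths."""
    os.makedirs(config.out_dir, exist_ok=True)
    artifacts: dict[str, str] = {}

    libraries = {
        name: read_tags(path, min_mapq=config.min_mapq, name=name)
        for name, path in config.experiments.items()
    }
    control: TagLibrary | None = None
    if config.control_path:
        control = read_tags(config.control_path, min_mapq=config.min_mapq, name="control")
    regions = read_regions(config.regions_path, config.window)
    log.info("loaded %d experiments, %d regions", len(libraries), len(regions))

    profiles = [build_profile(libraries, region, config.window) for region in regions]
    cfg = GapPenaltyConfig(d=config.gap_open, e=config.gap_ext)
    ma = progressive_align(profiles, cfg)

    if control is not None and config.subtract:
        if config.ctrl_scale is not None:
            scaling = {n: ControlScaling(config.ctrl_scale, "user") for n in libraries}
        else:
            scaling = {n: estimate_control_scale(lib, control) for n, lib in libraries.items()}
        ma = subtract_background(ma, control, scaling, regions)
    else:
        scaling = {}

    artifacts["alignment"] = _write_alignment(ma, config.out_dir)
    artifacts["composite"] = os.path.join(config.out_dir, "composite.tsv")
    ma.composite.to_tsv(artifacts["composite"])
    artifacts["gap_counts"] = os.path.join(config.out_dir, "gap_counts.tsv")
    pd.DataFrame({"column": np.arange(len(ma.gap_counts)), "gapped_regions": ma.gap_counts}
                 ).to_csv(artifacts["gap_counts"], sep="\t", index=False)
    artifacts["merge_tree"] = os.path.join(config.out_dir, "merge_tree.nwk")
    with open(artifacts["merge_tree"], "w") as fh:
        fh.write(ma.merge_tree + "\n")

    alpha = None
    components = []
    if config.deconvolve:
        alpha, components, matrix = _deconvolve_stage(config, ma, artifacts)
    run_log = {
        "version": __version__,
        "config": asdict(config),
        "effective_alpha": alpha,
        "effective_gap_ext": cfg.e,
        "control_scaling": {n: s.scale_factor for n, s in scaling.items()},
        "n_regions": len(regions),
        "alignment_length": ma.composite.L,
        "n_components": len(components),
        "component_positions": [c.mu for c in components],
    }
    artifacts["run_log"] = os.path.join(config.out_dir, "run_log.json")
    with open(artifacts["run_log"], "w") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True)
    return artifacts


def _deconvolve_stage(config: RunConfig, ma, artifacts: dict):
    weights = {
        name: ma.composite.values[2 * k : 2 * k + 2]
        for k, name in enumerate(ma.composite.experiments)
    }
    if config.alpha is not None:
        alpha = config.alpha
    else:
        per_expt = [w.sum() for w in weights.values()]
        alpha = max(1.0, config.alpha_frac * float(np.mean(per_expt)))
    model = TagDistributionModel(sigma=config.sigma, strand_offset=config.strand_offset)
    em_cfg = EMConfig(alpha=alpha, init_spacing=config.init_spacing,
                      mu_search_halfwidth=config.mu_search_halfwidth)
    components = em_fit(weights, em_cfg, model)
    matrix = quantify(components, weights, model)
    artifacts["crosslinks"] = os.path.join(config.out_dir, "crosslinks.tsv")
    matrix.to_tsv(artifacts["crosslinks"])

    if len(matrix.experiments) >= 2:
        pca = pca_crosslinks(matrix, config.n_pca_components)
        artifacts["pca"] = os.path.join(config.out_dir, "pca.tsv")
        pca.to_frame().to_csv(artifacts["pca"], sep="\t")
        artifacts["pca_variance"] = os.path.join(config.out_dir, "pca_variance.tsv")
        pd.DataFrame({
            "component": [f"PC{i + 1}" for i in range(len(pca.explained_variance_ratio))],
            "explained_variance_ratio": pca.explained_variance_ratio,
        }).to_csv(artifacts["pca_variance"], sep="\t", index=False)
    return alpha, components, matrix


def _write_alignment(ma, out_dir: str) -> str:
    path = os.path.join(out_dir, "alignment.tsv")
    rows = []
    for rid in ma.region_order:
        cmap = ma.region_maps[rid]
        for offset, col in enumerate(cmap):
            rows.append((rid, offset, int(col), ma.orientations[rid]))
    pd.DataFrame(rows, columns=["region_id", "window_offset", "alignment_column", "orientation"]
                 ).to_csv(path, sep="\t", index=False)
    return path
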