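import numpy as np
import pytest

from exoalign.align_multi import (
    ControlScaling,
    estimate_control_scale,
    merge_pair,
    progressive_align,
    project_library,
    subtract_background,
)
from exoalign.align_pair import GapPenaltyConfig, align_overlap
from exoalign.profiles import ProfileMatrix, build_profile, normalize_per_region
from exoalign.synthgen import generate
from exoalign.tagio import TagLibrary

from .conftest import two_block_truth

CFG = GapPenaltyConfig(d=1.0, e=0.1)


def single_tag_profile(col, L=12, rid="r"):
    values = np.zeros((2, L))
    values[0, col] = 1.0
    return ProfileMatrix(values, ["e0"], [rid])


def block_profile(rid, gap_at=None, gap_len=0, L=40, seed=0):
    """Deterministic structured K=2 profile, optionally with zero columns
    spliced in at ``gap_at``."""
    rng = np.random.default_rng(seed)
    values = rng.poisson(4.0, size=(4, L)).astype(float)
    if gap_at is not None:
        values = np.concatenate(
            [values[:, :gap_at], np.zeros((4, gap_len)), values[:, gap_at:]], axis=1
        )
    return ProfileMatrix(values, ["x", "y"], [rid])


class TestMergePair:
    def test_matched_single_tags_sum(self):
        a = single_tag_profile(5, rid="a")
        b = single_tag_profile(5, rid="b")
        aln = align_overlap(normalize_per_region(a), normalize_per_region(b), CFG)
        node = merge_pair(a, b, aln)
        assert node.raw.total() == 2.0
        col = int(node.maps["a"][5])
        assert node.raw.values[0, col] == 2.0

    def test_gap_columns_counted(self):
        a = block_profile("a")
        b = block_profile("b", gap_at=20, gap_len=5)  # same signal, 5 extra columns
        aln = align_overlap(normalize_per_region(a), normalize_per_region(b), CFG)
        node = merge_pair(a, b, aln)
        assert (node.gap_counts == 1).sum() == 5
        assert node.raw.L == 45

    def test_tag_conservation(self):
        a = block_profile("a", seed=1)
        b = block_profile("b", gap_at=10, gap_len=7, seed=2)
        aln = align_overlap(normalize_per_region(a), normalize_per_region(b), CFG)
        node = merge_pair(a, b, aln)
        assert node.raw.total() == pytest.approx(a.total() + b.total())


class TestProgressiveAlign:
    def test_identical_regions_stack_without_gaps(self):
        profiles = [block_profile(f"r{i}", seed=3) for i in range(3)]
        ma = progressive_align(profiles, CFG)
        assert ma.composite.L == 40
        assert np.array_equal(ma.composite.values, 3 * profiles[0].values)
        assert ma.gap_counts.sum() == 0
        for rid in ("r0", "r1", "r2"):
            assert np.array_equal(ma.region_maps[rid], np.arange(40))

    def test_needs_two_regions(self):
        with pytest.raises(ValueError, match="at least 2"):
            progressive_align([block_profile("a")], CFG)

    def test_tag_conservation(self, small_bundle):
        libs, _, regions, _ = small_bundle
        profiles = [build_profile(libs, r, regions.window_size) for r in regions]
        ma = progressive_align(profiles, CFG)
        assert ma.composite.total() == pytest.approx(sum(p.total() for p in profiles))

    def test_region_maps_monotone(self, small_bundle):
        libs, _, regions, _ = small_bundle
        profiles = [build_profile(libs, r, regions.window_size) for r in regions]
        ma = progressive_align(profiles, CFG)
        for rid, cmap in ma.region_maps.items():
            diffs = np.diff(cmap)
            if ma.orientations[rid] == "+":
                assert np.all(diffs >= 1)
            else:
                assert np.all(diffs <= -1)

    def test_determinism(self, small_bundle):
        libs, _, regions, _ = small_bundle
        profiles = [build_profile(libs, r, regions.window_size) for r in regions]
        ma1 = progressive_align(profiles, CFG)
        ma2 = progressive_align(profiles, CFG)
        assert ma1.merge_tree == ma2.merge_tree
        assert ma1.region_order == ma2.region_order
        assert np.array_equal(ma1.composite.values, ma2.composite.values)
        assert np.array_equal(ma1.gap_counts, ma2.gap_counts)

    def test_planted_spacers_recovered(self, small_bundle):
        libs, _, regions, record = small_bundle
        profiles = [build_profile(libs, r, regions.window_size) for r in regions]
        ma = progressive_align(profiles, CFG)
        offsets = np.array(record["site_window_offsets"])
        R, J = offsets.shape
        cols = np.array(
            [[ma.region_maps[regions.regions[r].id][offsets[r, j]] for j in range(J)]
             for r in range(R)]
        )
        # homologous planted sites coincide in alignment space
        for j in range(J):
            assert len(set(cols[:, j])) == 1
        # per-region inserted gap equals (max spacer - own spacer)
        spacers = np.array(record["spacers"])
        gaps = (cols[:, -1] - cols[:, 0]) - (offsets[:, -1] - offsets[:, 0])
        assert np.array_equal(gaps, spacers.max() - spacers)

    def test_orientations_recovered(self):
        truth = two_block_truth(n_regions=10, reversed_fraction=0.5, seed=21,
                               shared_noise=False)
        libs, _, regions, record = generate(truth)
        profiles = [build_profile(libs, r, regions.window_size) for r in regions]
        ma = progressive_align(profiles, CFG)
        got = [ma.orientations[r.id] for r in regions]
        agree = np.mean([g == t for g, t in zip(got, record["orientations"])])
        assert max(agree, 1 - agree) == 1.0


class TestControlScale:
    def make_library(self, rng, n, name="sig", chrom_len=500_000):
        lib = TagLibrary(name=name, chrom_lengths={"chrS": chrom_len})
        lib.add("chrS", rng.integers(1, chrom_len, n), rng.integers(1, chrom_len, n))
        return lib

    def test_identical_libraries_scale_one(self, rng):
        sig = self.make_library(rng, 5000)
        ctl = TagLibrary(name="ctl", chrom_lengths=sig.chrom_lengths)
        ctl.tags = dict(sig.tags)
        assert estimate_control_scale(sig, ctl).scale_factor == pytest.approx(1.0)

    def test_thinned_control_scale_two(self, rng):
        sig = self.make_library(rng, 20000)
        ctl = TagLibrary(name="ctl", chrom_lengths=sig.chrom_lengths)
        plus, minus = sig.tags["chrS"]
        ctl.add("chrS", plus[rng.random(len(plus)) < 0.5], minus[rng.random(len(minus)) < 0.5])
        scale = estimate_control_scale(sig, ctl).scale_factor
        assert scale == pytest.approx(2.0, rel=0.10)

    def test_empty_control_errors(self, rng):
        sig = self.make_library(rng, 100)
        with pytest.raises(ValueError, match="control"):
            estimate_control_scale(sig, TagLibrary(name="ctl"))

    def test_scaling_validation(self):
        with pytest.raises(ValueError):
            ControlScaling(0.0)
        with pytest.raises(ValueError):
            ControlScaling(float("nan"))


class TestSubtractBackground:
    def build_ma(self, small_bundle):
        libs, ctrl, regions, _ = small_bundle
        profiles = [build_profile(libs, r, regions.window_size) for r in regions]
        return libs, ctrl, regions, progressive_align(profiles, CFG)

    def test_no_control_is_identity(self, small_bundle):
        _, _, regions, ma = self.build_ma(small_bundle)
        out = subtract_background(ma, None, None, regions)
        assert out is ma

    def test_projection_conserves_control_tags_in_windows(self, small_bundle):
        libs, _, regions, ma = self.build_ma(small_bundle)
        name = next(iter(libs))
        proj = project_library(ma, libs[name], regions)
        # every window tag lands in exactly one alignment cell
        assert proj.sum() == pytest.approx(
            sum(build_profile({name: libs[name]}, r, regions.window_size).total()
                for r in regions)
        )

    def test_subtraction_matches_manual_formula_and_floors(self, small_bundle):
        libs, _, regions, ma = self.build_ma(small_bundle)
        # use the first experiment's own library as "control" with scale 2:
        # guarantees columns where signal < scaled control
        name = next(iter(libs))
        ctrl = libs[name]
        out = subtract_background(ma, ctrl, 2.0, regions)
        proj = project_library(ma, ctrl, regions)
        for k in range(ma.composite.K):
            expect = np.maximum(ma.composite.values[2 * k : 2 * k + 2] - 2.0 * proj, 0.0)
            assert np.allclose(out.composite.values[2 * k : 2 * k + 2], expect)
        assert out.composite.values.min() >= 0
        assert out.background_subtracted
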